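# ctnoise

Global-noise (GN) metrics for CT image quality assessment.

The CMS CT quality measure asks institutions to report, per exam category,
whether image noise stays below a category-specific threshold — but it does
not define *how* to compute the noise, referencing instead two automated
methods from the literature (commonly called the Duke and Wisconsin
methods). The two families, and the mean-vs-mode summary choice inside the
Wisconsin family, yield systematically different numbers on the same scan,
which directly affects whether an exam "passes". This package implements
all five resulting GN metrics as a tested library and CLI, together with
the statistics needed to compare them across a cohort and a synthetic
phantom generator that makes every number verifiable against ground truth
without patient data. It is aimed at clinical medical physicists and
imaging researchers who need a transparent, auditable GN implementation.

## The five metrics

For an axial slice with HU values $I(x,y)$:

- **Duke_tissue_mode** — a square sliding window (7 mm by default) runs
  over the *unsegmented* slice; the sample standard deviation of each
  window is assigned to its central pixel, forming a noise map
  $\sigma_\mathrm{loc}(x,y)$. The soft-tissue mask
  $\{0 \le I \le 100\ \mathrm{HU}\}$ (thresholded on the raw slice) selects
  noise-map pixels, and the slice GN is the mode of their histogram.
- **Wisconsin_{tissue,air}_{mean,mode}** — each slice is subtracted from
  its adjacent neighbor, cancelling anatomy shared by both; the difference
  image is tiled with a uniform grid of 7×7 mm ROIs. Tissue
  ($[0,100]$ HU) and air ($[-1024,-950]$ HU) masks are thresholded on the
  median-filtered original slice, and every ROI wholly inside a mask
  contributes one sample SD. Because subtracting two equally noisy slices
  doubles the variance, each SD is divided by $\sqrt{2}$ (configurable).
  The slice GN is the mean or the histogram mode of the ROI SDs, in tissue
  or in air — four metrics.

Slice values are averaged into an exam-level GN; exams with several
reconstructed scans take the *best* (minimum) value across scans; the exam
value is compared with the CMS threshold for its category (strictly above
= exceeds). The statistics suite provides the Friedman omnibus test across
metrics, pairwise Wilcoxon signed-rank tests with Holm–Bonferroni
adjustment, Pearson correlation matrices with strength labels, and
linkage-preserving sign-flip permutation tests on slice-level values.

## Worked example

```python
from ctnoise import METRICS, PhantomSpec, compute_scan, make_phantom

spec = PhantomSpec(shape=(8, 256, 256), pixel_spacing_mm=1.0,
                   body_semi_axes_mm=(80.0, 100.0), sigma_hu=10.0, seed=1)
volume, truth = make_phantom(spec)
scan = compute_scan(volume)
for metric in METRICS:
    print(f"{metric:<24s} {scan.scan_values[metric]:6.2f} HU")
```

prints

```
Duke_tissue_mode           9.94 HU
Wisconsin_tissue_mean      9.94 HU
Wisconsin_tissue_mode     10.00 HU
Wisconsin_air_mean         9.95 HU
Wisconsin_air_mode         9.75 HU
```

— every metric recovers the simulated 10 HU noise to within a few percent.
On clinical data the metrics diverge (anatomy, reconstruction kernel and
dose affect each estimator differently); `examples/` walks through kernel
dependence, best-scan/CMS compliance, and the cohort statistics.

## Command line

```bash
ctnoise simulate spec.yaml --out cohort/          # phantom DICOM + ground truth
ctnoise compute cohort/ --category abd_pelvis_wo \
        --out-csv exams.csv --out-json exams.json # five metrics per exam
ctnoise compare exams.csv --out-dir report/       # Friedman/Wilcoxon/Pearson + figures
```

Every output embeds the fully resolved configuration (thresholds, window
and ROI sizes, binning, √2 flag), and fixed-seed runs are byte-identical.

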