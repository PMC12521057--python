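# Methods

## Scope and model

The package estimates a single scalar "global noise" (GN, in HU) per CT
exam from the random pixel noise of its reconstructed slices, without
manual ROI placement, and compares the five published variants of that
estimate. GN here means the standard deviation of the zero-mean stochastic
component of the image in a reference compartment (soft tissue or air);
anatomy, beam hardening and texture are not part of the estimand. Both
estimator families assume noise that is roughly stationary within a slice
and uncorrelated between adjacent slices; the Wisconsin family additionally
assumes that anatomy is identical in adjacent slices at the ROI scale, so
that subtraction cancels structure and leaves noise with variance doubled.

## Estimators

**Duke (tissue mode).** Local sample SD (n−1 denominator) of a square
sliding window over the unsegmented slice, assigned to the central pixel.
Windows that would leave the slice are not evaluated (no padding — padded
windows would fabricate data; on 512² clinical slices the lost border is
negligible). The soft-tissue mask is thresholded on the raw slice; the
noise-map values under the mask are histogrammed and the modal bin center
is the slice value. Boundary windows mix compartments and inflate the SD
tail; the mode ignores that tail, which is the method's point.

**Wisconsin (tissue/air × mean/mode).** Difference of index-adjacent
slices (the last slice, lacking a later neighbor, pairs with the previous
one so every slice yields a value). A uniform ROI grid is anchored at
pixel (0,0) with trailing partial tiles discarded — "uniform grid" admits
any phase, and a fixed anchor is deterministic. Masks come from the
median-filtered *minuend* slice only (the method segments the original
slice, singular). An ROI contributes only if every pixel is inside the
mask. Per-ROI sample SDs are divided by √2 by default to undo the variance
doubling of the subtraction; published practice varies on this point, so
it is a recorded flag rather than a hard-coded choice, and both readings
are first-class.

## Parameters, defaults, rationale

| parameter | default | why |
|---|---|---|
| tissue window | [0, 100] HU, inclusive | standard soft-tissue range; inclusivity is the least-surprise reading of "between" |
| air window | [−1024, −950] HU, inclusive | standard air range for CT storage with a −1024 floor |
| Duke window / Wisconsin ROI | 7 mm | the two methods are compared at matched spatial scale; Duke GN is insensitive to window sizes 6–20 mm (verified in the tests) |
| window px from mm | nearest odd, ties up, min 3 | a window needs a central pixel; 7 mm at 0.7 mm/px gives 11 px |
| ROI px from mm | round, min 2 | an SD needs ≥ 2 px per axis |
| median kernel | 3×3 px | smallest standard kernel; masks should be stabilized, not distorted |
| histogram bin | 0.5 HU | resolves the clinical GN range (~5–100 HU) while keeping bins populated |
| histogram scheme | bins centered at k·0.5 HU, ties to the lowest bin | a degenerate (all-equal) input reports that value exactly: a noiseless scan reads 0.0 HU, and ties are deterministic |
| min mask pixels (Duke) | 100 | below this the mode is histogram noise; the slice reports "no-value" |
| min valid ROIs (Wisconsin) | 5 | same reasoning at ROI granularity |
| sample SD | n−1 everywhere | the standard noise estimator; recorded in output metadata |

Slices without a value are excluded from (and counted against) the
exam-level mean; an exam where no slice has a value is reported as
"no-value" — the measure document defines no fallback for, e.g., scans
with no in-FOV air, and the package does not invent one.

Segmentation clamps HU below −1024 to −1024 *before thresholding only*
(field-of-view padding such as −2048, and deep noise excursions in air,
would otherwise read as ultra-dense non-air). The noise measurements
themselves — the Duke noise map and the Wisconsin difference image — see
the unclamped HU values, so the clamp cannot bias an SD. Keeping the clamp
out of the DICOM reader preserves bit-exact write→load round trips.

## Aggregation and compliance

Exam GN = arithmetic mean over slices with a value. Multi-scan exams take
the minimum GN across scans per metric (the "best"/highest-quality scan
rule of the measure); ties keep the first series, logged. Compliance is
strict exceedance: GN equal to the threshold is "within". Seven exam
categories ship as an editable YAML (renal stone 64 HU; routine and
high-dose abdomen 29 HU; chest 49 HU); the remaining categories of the
measure are user-supplied.

## Statistics

- **Friedman omnibus** across the metric columns, exams as blocks;
  within-row average ranks, tie-corrected chi-square, k−1 df. When every
  row is fully tied the tie correction degenerates (0/0); identical
  columns carry no ordering signal, so the implementation returns
  statistic 0, p 1 rather than NaN.
- **Pairwise Wilcoxon signed-rank**, two-sided, zeros discarded. For ≤ 25
  remaining pairs the exact null of W⁺ is built by dynamic programming on
  doubled (hence integer, tie-tolerant) average ranks; above that, the
  normal approximation with continuity and tie corrections. Both branches
  reproduce scipy's p-values to < 1e−8 on tie-free data (asserted in the
  tests against scipy as an independent reference — scipy is never the
  implementation).
- **Holm–Bonferroni** step-down with running-max monotonicity, capped at 1.
- **Pearson r** per metric pair with strength labels: r ≥ 0.8 very strong,
  [0.6, 0.8) strong, [0.4, 0.6) moderate, [0.2, 0.4) weak, < 0.2 very
  weak/none; zero-variance columns are labeled undefined.
- **Paired permutation test** per exam between two metrics: the statistic
  is |mean slice-wise difference| — chosen to match the exam-level GN
  definition, itself a slice mean; the measure-defining property is that
  the (A,B) labels are swapped *within* each slice, preserving slice
  linkage, i.e. a sign flip of each per-slice difference. Exhaustive
  enumeration of all 2ⁿ sign patterns for ≤ 20 slices; otherwise seeded
  Monte Carlo with the add-one estimator (1 + #{null ≥ obs})/(1 + n_perm),
  which is never anti-conservative.

## Phantom generator

The generator emulates the reconstructed-image properties the metrics
actually consume: an elliptical soft-tissue body (50 HU) in air
(−1000 HU), optional internal structures replicated on every slice, and
zero-mean Gaussian noise drawn independently per slice. Smooth
reconstruction kernels are emulated by filtering the white field with an
isotropic Gaussian (FWHM in mm); the filter is applied circularly (wrap
mode) so its variance gain is uniform across the slice, and by default the
field is rescaled so the marginal per-pixel SD equals `sigma_hu` exactly —
one unambiguous ground truth. Rescaling can be switched off to compare
kernels at equal pre-filter amplitude, where smoothing genuinely lowers
measured noise. Output is rounded to integer HU, as real CT storage is;
the rounding adds variance 1/12 HU² (≤ 0.04 % of SD at σ = 5 HU) and makes
write→load DICOM round trips bit-exact with slope 1 / intercept 0 signed
16-bit storage.

What the phantom does *not* emulate: projection-domain physics (beam
hardening, photon starvation), measured kernel noise-power spectra,
inter-slice noise correlation (off by default; Wisconsin subtraction
assumes none), anthropomorphic anatomy, or dose modulation. Passing the
recovery tests therefore shows the estimators are correct *given* their
stationarity assumptions, not that those assumptions hold on any
particular clinical protocol.

Cohorts draw per-exam σ from a constant or lognormal (median, geometric
SD) law with per-exam child seeds, and can be written as DICOM series plus
a ground-truth CSV so the full CLI path is exercised.

## Numerical choices

- The noise map uses an exact two-pass SD (window mean, then squared
  deviations) over explicit strided window views, chunked by rows. The
  one-pass identity E[x²]−E[x]² via box filters is faster but loses ~6
  digits to cancellation at CT magnitudes; the two-pass form matches a
  brute-force nested-loop oracle to ~1e−13 HU.
- Histogram bin indices come from `rint` (ties to even at half-bin edges),
  and the modal bin tie-break is toward the lowest bin — both deterministic.
- Permutation and MC comparisons use a relative 1e−12 tolerance when
  counting `null ≥ observed` so ties of identical floating-point sums are
  counted as ties.
- All UIDs in written DICOM derive from the exam/series identifiers, and
  no output embeds timestamps, so fixed-seed pipelines are byte-identical.

## Problem sizes

The validation suite recovers σ ∈ {5, 10, 20, 50} HU on 512×512×20
phantoms (clinical in-plane size), and uses 256–320 px phantoms with 5–6
slices for window-robustness, kernel-direction and structure-suppression
checks, 200 simulated exams of 30 slices for permutation type-I error, and
10 random 10×5 tables for the reference cross-checks. These sizes give
sampling error comfortably below the asserted tolerances.

## Known limitations

- At σ = 50 HU the air window retains only ~24 HU of headroom below the
  −1000 HU air mean; air segmentation then relies on the −1024 clamp and
  median filtering, and ROI selection trims a small upper tail of the
  noise (an ~1–2 % downward bias, measured on phantoms). Tissue metrics are
  unaffected.
- The Duke mode inherits a half-bin (0.25 HU) quantization; at very low
  GN (< 3 HU) this is a visible fraction of the value.
- Multi-frame enhanced-CT DICOM, non-axial reformats and RDSR dose objects
  are out of scope; the reader rejects non-axial-CT objects.
- The 3 mm slice-thickness standardization mentioned by the measure is
  not implemented (it is not defined operationally anywhere); thickness is
  carried as metadata only.
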