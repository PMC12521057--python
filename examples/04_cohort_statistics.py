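"""Cohort-level comparison of the five global-noise metrics.

Simulates a small protocol cohort (per-exam noise drawn lognormally),
computes the exam x metric table, and runs the comparison suite: Friedman
omnibus, pairwise Wilcoxon + Holm, Pearson correlations with strength
labels, and per-exam linkage-preserving permutation tests between the
tissue metrics.
"""

import pandas as pd

from ctnoise import METRICS, PhantomSpec, compare_cohort, compute_scan, make_cohort

template = PhantomSpec(shape=(6, 192, 192), pixel_spacing_mm=1.0,
                       body_semi_axes_mm=(60.0, 75.0))
exams, truth = make_cohort(template, n_exams=12, sigma_distribution=("lognormal", 10.0, 1.3),
                           seed=7)

rows, slice_rows = [], []
for volume, _ in exams:
    scan = compute_scan(volume)
    rows.append({"exam_id": volume.exam_id, **{m: scan.scan_values[m] for m in METRICS}})
    for m in METRICS[:3]:  # tissue metrics feed the permutation tier
        for s, v in enumerate(scan.slice_values[m]):
            slice_rows.append({"exam": volume.exam_id, "slice": s, "metric": m, "value": v})

table = pd.DataFrame(rows).set_index("exam_id")
report = compare_cohort(table, pd.DataFrame(slice_rows), n_perm=2000, seed=7)

print(f"exams: {report.n_exams}; per-exam sigma range "
      f"{truth.sigma_hu.min():.1f}-{truth.sigma_hu.max():.1f} HU")
print(f"Friedman chi2 = {report.friedman_statistic:.2f}, p = {report.friedman_p:.2g}")
sig = report.pairwise[report.pairwise.significant]
print(f"significant metric pairs after Holm: {len(sig)}/10")
print("Pearson r (tissue metrics):")
print(report.pearson_r.iloc[:3, :3].round(3).to_string())
n_sig = int(report.permutation_p.significant.sum())
print(f"slice-level permutation tests: {n_sig}/{len(report.permutation_p)} "
      "exam-pairs significantly different")
print("On identical-sigma white noise the metrics track each other (high r);")
print("pairwise differences reflect each estimator's small, systematic bias.")
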