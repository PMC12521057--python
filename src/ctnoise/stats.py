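"""Statistical comparison of global-noise metrics.

Two tiers, mirroring how GN metrics are compared across a cohort:

1. Protocol level — a Friedman omnibus test across the metric columns
   (each exam is a block), followed when significant by pairwise Wilcoxon
   signed-rank tests with Holm step-down adjustment, plus a Pearson
   correlation matrix with strength labels.
2. Patient level — for each exam, a linkage-preserving paired permutation
   test between two metrics' slice-level values: the per-slice pairing is
   kept and only the (A, B) labels are swapped within each slice, i.e. the
   per-slice differences are sign-flipped.  The statistic is the absolute
   mean slice-wise difference, matching the exam-level GN definition
   (a slice mean); the absolute value makes the test two-sided.

The Friedman, Wilcoxon (exact enumeration for small n, normal
approximation with continuity and tie corrections above) and Holm
procedures are implemented here in full so their behavior is transparent
and testable against independent references.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata

__all__ = [
    "friedman_omnibus",
    "wilcoxon_signed_rank",
    "holm_adjust",
    "pairwise_wilcoxon_holm",
    "strength_label",
    "pearson_matrix_with_strength",
    "paired_permutation_exam",
    "ComparisonReport",
    "compare_cohort",
]

EXACT_WILCOXON_MAX_N = 25
EXHAUSTIVE_PERMUTATION_MAX_N = 20

#: Correlation-strength bins (lower inclusive bound -> label).
STRENGTH_BINS = (
    (0.8, "very strong"),
    (0.6, "strong"),
    (0.4, "moderate"),
    (0.2, "weak"),
)


def _as_matrix(table) -> np.ndarray:
    m = np.asarray(table, dtype=np.float64)
    if m.ndim != 2:
        raise ValueError("table must be 2-D (exams x metrics)")
    return m


def friedman_omnibus(table) -> tuple[float, float]:
    """Friedman chi-square test across metric columns (exams are blocks).

    Within-exam ranks (average ranks for ties), tie-corrected chi-square
    with k-1 degrees of freedom.  Fully tied rows everywhere (identical
    columns) carry no ordering information: statistic 0, p 1.

    Raises
    ------
    ValueError
        On missing cells (exclude those rows first) or fewer than 3 exams
        / 2 metrics.
    """
    m = _as_matrix(table)
    n, k = m.shape
    if np.isnan(m).any():
        raise ValueError("table has missing cells; exclude incomplete rows first")
    if k < 2 or n < 3:
        raise ValueError(f"need >= 3 exams and >= 2 metrics, got {m.shape}")
    ranks = np.apply_along_axis(rankdata, 1, m)
    ties = 0.0
    for row in m:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    c = 1.0 - ties / (n * k * (k * k - 1))
    if c == 0.0:  # every row fully tied: no ordering signal at all
        return 0.0, 1.0
    ssbn = float(np.sum(ranks.sum(axis=0) ** 2))
    stat = (12.0 / (n * k * (k + 1)) * ssbn - 3.0 * n * (k + 1)) / c
    return stat, float(chi2.sf(stat, k - 1))


def _signed_rank_distribution(doubled_ranks: np.ndarray) -> np.ndarray:
    """Counts of the null W+ distribution on the doubled-rank lattice.

    Doubling average ranks makes them integers even under ties; entry w of
    the returned array counts sign assignments with doubled W+ equal to w.
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for dr in doubled_ranks:
        shifted = np.zeros_like(counts)
        shifted[dr:] = counts[:-dr] if dr > 0 else counts
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(a, b) -> tuple[float, float, bool]:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are discarded (classic signed-rank).  Exact
    enumeration of the W+ null for n <= 25 remaining pairs; otherwise the
    normal approximation with continuity and tie corrections.

    Returns
    -------
    (w_plus, p, degenerate)
        ``degenerate`` is True when every difference is zero (p = 1).
    """
    d = np.asarray(a, dtype=np.float64) - np.asarray(b, dtype=np.float64)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0, True
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_WILCOXON_MAX_N:
        doubled = np.rint(2 * ranks).astype(np.int64)
        counts = _signed_rank_distribution(doubled)
        total = counts.sum()
        w2 = int(round(2 * w_plus))
        cdf = counts[: w2 + 1].sum() / total
        sf = counts[w2:].sum() / total
        p = min(1.0, 2.0 * min(cdf, sf))
    else:
        mn = n * (n + 1) / 4.0
        tie_term = 0.0
        _, t_counts = np.unique(np.abs(d), return_counts=True)
        tie_term = float(np.sum(t_counts**3 - t_counts))
        se = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term / 48.0)
        corr = 0.5 * np.sign(w_plus - mn)
        z = (w_plus - mn - corr) / se
        p = min(1.0, 2.0 * float(norm.sf(abs(z))))
    return w_plus, p, False


def holm_adjust(pvalues) -> np.ndarray:
    """Holm–Bonferroni step-down adjustment with monotonicity enforcement."""
    p = np.asarray(pvalues, dtype=np.float64)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        running = max(running, (m - i) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def pairwise_wilcoxon_holm(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """All-pairs Wilcoxon signed-rank tests with Holm adjustment.

    Returns one row per metric pair with raw p, Holm-adjusted p, the W+
    statistic, a degeneracy flag (all differences zero) and a significance
    flag at ``alpha``.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.DataFrame(np.asarray(table))
    cols = list(table.columns)
    if len(cols) < 2:
        raise ValueError("need at least two metric columns")
    rows = []
    for a, b in itertools.combinations(cols, 2):
        w, p, degen = wilcoxon_signed_rank(table[a].to_numpy(), table[b].to_numpy())
        rows.append({"metric_a": a, "metric_b": b, "w_plus": w, "p_raw": p, "degenerate": degen})
    out = pd.DataFrame(rows)
    out["p_holm"] = holm_adjust(out["p_raw"].to_numpy())
    out["significant"] = out["p_holm"] < alpha
    return out


def strength_label(r: float) -> str:
    """Correlation strength bin of an r value ('undefined' for NaN)."""
    if np.isnan(r):
        return "undefined"
    for lo, label in STRENGTH_BINS:
        if r >= lo:
            return label
    return "very weak/none"


def pearson_matrix_with_strength(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r matrix across metric columns plus strength labels.

    Zero-variance columns yield NaN correlations labeled "undefined".
    Needs >= 3 exams.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.DataFrame(np.asarray(table))
    m = table.to_numpy(dtype=np.float64)
    if m.shape[0] < 3:
        raise ValueError("need at least 3 exams for correlations")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(m, rowvar=False)
    # corrcoef leaves the diagonal of a zero-variance column NaN too; keep
    # r[i,i] = 1 only where the column varies.
    cols = list(table.columns)
    rdf = pd.DataFrame(r, index=cols, columns=cols)
    labels = rdf.map(strength_label)
    return rdf, labels


def paired_permutation_exam(
    slice_values_a,
    slice_values_b,
    n_perm: int = 10_000,
    seed: int | None = 0,
) -> float:
    """Linkage-preserving sign-flip permutation test for one exam.

    Observed statistic: ``|mean(A - B)|`` over slices.  The null swaps the
    (A, B) labels independently within each slice — a sign flip of each
    per-slice difference — preserving slice linkage.  Exhaustive
    enumeration of all 2^n sign patterns when n <= 20; otherwise seeded
    Monte Carlo with the add-one estimator ``(1 + #{null >= obs}) / (1 +
    n_perm)``.  All-zero differences give p = 1.
    """
    a = np.asarray(slice_values_a, dtype=np.float64)
    b = np.asarray(slice_values_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("slice value sequences must be 1-D and slice-aligned")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    d = a - b
    if np.all(d == 0):
        return 1.0
    obs = abs(d.mean())
    tol = 1e-12 * max(1.0, obs)
    n = d.size
    if n <= EXHAUSTIVE_PERMUTATION_MAX_N:
        sums = np.zeros(1)
        for di in d:
            sums = np.concatenate([sums + di, sums - di])
        null = np.abs(sums) / n
        return float(np.count_nonzero(null >= obs - tol) / null.size)
    rng = np.random.default_rng(seed)
    count = 0
    chunk = 200_000 // n + 1
    remaining = n_perm
    while remaining > 0:
        take = min(chunk, remaining)
        signs = rng.integers(0, 2, size=(take, n)) * 2 - 1
        null = np.abs((signs * d).mean(axis=1))
        count += int(np.count_nonzero(null >= obs - tol))
        remaining -= take
    return float((1 + count) / (1 + n_perm))


@dataclass
class ComparisonReport:
    """Bundle of the cohort-level comparison outputs."""

    protocol: str
    n_exams: int
    friedman_statistic: float
    friedman_p: float
    pairwise: pd.DataFrame
    pearson_r: pd.DataFrame
    strength: pd.DataFrame
    permutation_p: pd.DataFrame | None = None
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "protocol": self.protocol,
            "n_exams": self.n_exams,
            "friedman": {"statistic": self.friedman_statistic, "p": self.friedman_p},
            "pairwise_wilcoxon": self.pairwise.to_dict(orient="records"),
            "pearson_r": self.pearson_r.round(10).to_dict(),
            "strength": self.strength.to_dict(),
            "notes": self.notes,
        }
        if self.permutation_p is not None:
            d["paired_permutation"] = self.permutation_p.to_dict(orient="records")
        return d


def compare_cohort(
    table: pd.DataFrame,
    slice_records: pd.DataFrame | None = None,
    *,
    protocol: str = "cohort",
    alpha: float = 0.05,
    tissue_metrics: tuple[str, ...] = (
        "Duke_tissue_mode",
        "Wisconsin_tissue_mean",
        "Wisconsin_tissue_mode",
    ),
    n_perm: int = 10_000,
    seed: int = 0,
) -> ComparisonReport:
    """Full two-tier comparison of a cohort table.

    Parameters
    ----------
    table : DataFrame
        Exam-level GN values, rows = exams (index = exam id), columns =
        metrics; rows with missing cells are dropped with a note.
    slice_records : DataFrame, optional
        Long-format slice-level values with columns ``exam``, ``slice``,
        ``metric``, ``value``; enables the patient-level permutation tests
        between the tissue metrics.
    """
    notes: list[str] = []
    clean = table.dropna()
    if len(clean) < len(table):
        notes.append(f"dropped {len(table) - len(clean)} exams with missing metric values")
    stat, p = friedman_omnibus(clean.to_numpy())
    pairwise = pairwise_wilcoxon_holm(clean, alpha=alpha)
    r, labels = pearson_matrix_with_strength(clean)

    perm = None
    if slice_records is not None:
        wide = slice_records.pivot_table(
            index=["exam", "slice"], columns="metric", values="value"
        )
        rows = []
        pairs = list(itertools.combinations(tissue_metrics, 2))
        for i, (exam, grp) in enumerate(wide.groupby(level="exam")):
            for j, (ma, mb) in enumerate(pairs):
                if ma not in grp.columns or mb not in grp.columns:
                    continue
                sub = grp[[ma, mb]].dropna()
                pp = paired_permutation_exam(
                    sub[ma].to_numpy(), sub[mb].to_numpy(), n_perm=n_perm,
                    seed=seed + 1000 * i + j,
                )
                rows.append(
                    {"exam": exam, "metric_a": ma, "metric_b": mb,
                     "n_slices": len(sub), "p": pp, "significant": pp < alpha}
                )
        perm = pd.DataFrame(rows)
    else:
        notes.append("no slice-level records; patient-level permutation tests omitted")

    return ComparisonReport(
        protocol=protocol, n_exams=len(clean), friedman_statistic=stat, friedman_p=p,
        pairwise=pairwise, pearson_r=r, strength=labels, permutation_p=perm, notes=notes,
    )
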