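"""Exam-level aggregation, best-scan selection and CMS compliance.

Slice-level global-noise values are averaged over the slices that produced
a value to give one exam-level number per metric.  When an exam contains
several reconstructed scans, the measure assigns the exam the "best"
(lowest) global-noise value across scans — the highest-quality scan.  The
exam value is then compared against the CMS noise threshold for the exam's
category: strictly above the threshold is "exceeds", at or below is
"within".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "METRICS",
    "NO_VALUE",
    "CmsCategory",
    "bundled_cms_categories",
    "load_cms_categories",
    "exam_gn",
    "best_scan_gn",
    "classify_compliance",
]

logger = logging.getLogger(__name__)

#: The five global-noise metrics, in canonical column order.
METRICS = (
    "Duke_tissue_mode",
    "Wisconsin_tissue_mean",
    "Wisconsin_tissue_mode",
    "Wisconsin_air_mean",
    "Wisconsin_air_mode",
)

#: Sentinel string used in tabular output for slices/exams without a value.
NO_VALUE = "no-value"


@dataclass(frozen=True)
class CmsCategory:
    """One CMS exam category with its noise threshold."""

    name: str
    body_region: str
    dose_category: str
    noise_threshold_hu: float

    def __post_init__(self) -> None:
        if self.noise_threshold_hu <= 0:
            raise ValueError("noise_threshold_hu must be positive")


def _categories_from_mapping(data: dict) -> dict[str, CmsCategory]:
    return {
        name: CmsCategory(
            name=name,
            body_region=entry["body_region"],
            dose_category=entry["dose_category"],
            noise_threshold_hu=float(entry["noise_threshold_hu"]),
        )
        for name, entry in data.items()
    }


def bundled_cms_categories() -> dict[str, CmsCategory]:
    """The CMS categories shipped with the package (editable via user file)."""
    text = resources.files("ctnoise").joinpath("data/cms_thresholds.yaml").read_text()
    return _categories_from_mapping(yaml.safe_load(text))


def load_cms_categories(path: str | Path) -> dict[str, CmsCategory]:
    """Load CMS categories from a user YAML file (same layout as bundled)."""
    with open(path) as fh:
        return _categories_from_mapping(yaml.safe_load(fh))


def exam_gn(slice_values) -> tuple[float | None, int]:
    """Exam-level GN: arithmetic mean over slices that produced a value.

    Returns ``(value, n_slices_used)``; ``(None, 0)`` when no slice has a
    value (the measure document does not define a fallback, so none is
    invented).
    """
    usable = [float(v) for v in slice_values if v is not None]
    if not usable:
        logger.info("exam GN: no slice produced a value")
        return None, 0
    return sum(usable) / len(usable), len(usable)


def best_scan_gn(per_scan_values: dict[str, float]) -> tuple[str, float]:
    """Best (minimum-noise) scan of an exam: ``(scan_id, gn)``.

    Ties keep the first scan in insertion (series) order.
    """
    if not per_scan_values:
        raise ValueError("best_scan_gn needs at least one scan value")
    best_id = min(per_scan_values, key=lambda k: (per_scan_values[k],))
    ties = [k for k, v in per_scan_values.items() if v == per_scan_values[best_id]]
    if len(ties) > 1:
        logger.info("best-scan tie between %s; keeping %s", ties, ties[0])
        best_id = ties[0]
    return best_id, float(per_scan_values[best_id])


def classify_compliance(exam_gn_hu: float, category: CmsCategory | str,
                        categories: dict[str, CmsCategory] | None = None) -> str:
    """Classify an exam GN against its category threshold.

    Strict exceedance: equality with the threshold is "within".
    """
    if isinstance(category, str):
        categories = categories or bundled_cms_categories()
        if category not in categories:
            raise KeyError(
                f"unknown CMS category {category!r}; configured: {sorted(categories)}"
            )
        category = categories[category]
    return "exceeds" if exam_gn_hu > category.noise_threshold_hu else "within"
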