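"""High-level pipeline: volume(s) -> five GN metrics -> exam report rows.

Ties the per-slice noise methods to exam-level aggregation and best-scan
selection, and renders per-exam results as pandas DataFrames for CSV
output.  All functions are pure given a :class:`~ctnoise.config.RunConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .aggregate import METRICS, NO_VALUE, CmsCategory, best_scan_gn, classify_compliance, exam_gn
from .config import RunConfig
from .duke import duke_slice_gn
from .segmentation import make_mask
from .volume import CTVolume
from .wisconsin import wisconsin_volume_gn

__all__ = ["ScanNoiseResult", "ExamNoiseResult", "compute_scan", "compute_exam", "exams_to_frame"]


@dataclass
class ScanNoiseResult:
    """Per-slice and scan-level GN values of one reconstructed series."""

    exam_id: str
    scan_id: str
    slice_values: dict[str, list[float | None]]
    scan_values: dict[str, float | None] = field(init=False)
    n_slices_used: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.scan_values, self.n_slices_used = {}, {}
        for metric, values in self.slice_values.items():
            self.scan_values[metric], self.n_slices_used[metric] = exam_gn(values)


@dataclass
class ExamNoiseResult:
    """Exam-level GN per metric after best-scan selection, plus compliance."""

    exam_id: str
    values: dict[str, float | None]
    scan_ids: dict[str, str | None]
    n_slices_used: dict[str, int]
    category: str | None = None
    compliance: dict[str, str] = field(default_factory=dict)


def compute_scan(volume: CTVolume, config: RunConfig | None = None) -> ScanNoiseResult:
    """All five GN metrics, slice by slice, for one series."""
    cfg = config or RunConfig()
    spacing = volume.pixel_spacing_mm[0]
    duke_masks = [
        make_mask(
            volume.slice_hu(i),
            "tissue",
            use_median_filter=False,
            tissue_hu_range=cfg.tissue_hu_range,
        ).mask
        for i in range(volume.n_slices)
    ]
    duke = [
        duke_slice_gn(
            volume.slice_hu(i),
            spacing,
            window_mm=cfg.duke_window_mm,
            tissue_mask=duke_masks[i],
            bin_width_hu=cfg.histogram_bin_hu,
            min_mask_pixels=cfg.min_mask_pixels,
        )
        for i in range(volume.n_slices)
    ]
    wi_kwargs = dict(
        roi_mm=cfg.wisconsin_roi_mm,
        bin_width_hu=cfg.histogram_bin_hu,
        sqrt2_correction=cfg.sqrt2_correction,
        median_kernel_px=cfg.median_kernel_px,
        min_valid_rois=cfg.min_valid_rois,
        background_air_only=cfg.background_air_only,
        tissue_hu_range=cfg.tissue_hu_range,
        air_hu_range=cfg.air_hu_range,
    )
    tissue = wisconsin_volume_gn(volume, "tissue", **wi_kwargs)
    air = wisconsin_volume_gn(volume, "air", **wi_kwargs)

    slice_values = {
        "Duke_tissue_mode": duke,
        "Wisconsin_tissue_mean": [r.mean_gn if r else None for r in tissue],
        "Wisconsin_tissue_mode": [r.mode_gn if r else None for r in tissue],
        "Wisconsin_air_mean": [r.mean_gn if r else None for r in air],
        "Wisconsin_air_mode": [r.mode_gn if r else None for r in air],
    }
    return ScanNoiseResult(exam_id=volume.exam_id, scan_id=volume.series_id, slice_values=slice_values)


def compute_exam(
    volumes: list[CTVolume],
    config: RunConfig | None = None,
    category: CmsCategory | None = None,
    category_name: str | None = None,
) -> ExamNoiseResult:
    """Compute an exam's GN per metric, selecting the best scan per metric.

    With several scans, each metric takes the minimum (best-quality) scan
    value per the measure's best-scan rule; metrics with no value on any
    scan stay "no-value".
    """
    if not volumes:
        raise ValueError("compute_exam needs at least one volume")
    cfg = config or RunConfig()
    scans = [compute_scan(v, cfg) for v in volumes]
    exam_id = scans[0].exam_id
    values: dict[str, float | None] = {}
    scan_ids: dict[str, str | None] = {}
    n_used: dict[str, int] = {}
    for metric in METRICS:
        per_scan = {s.scan_id: s.scan_values[metric] for s in scans if s.scan_values[metric] is not None}
        if not per_scan:
            values[metric], scan_ids[metric], n_used[metric] = None, None, 0
            continue
        sid, val = best_scan_gn(per_scan)
        values[metric], scan_ids[metric] = val, sid
        n_used[metric] = next(s.n_slices_used[metric] for s in scans if s.scan_id == sid)
    result = ExamNoiseResult(
        exam_id=exam_id, values=values, scan_ids=scan_ids, n_slices_used=n_used,
        category=category.name if category else category_name,
    )
    if category is not None:
        for metric, val in values.items():
            result.compliance[metric] = (
                classify_compliance(val, category) if val is not None else NO_VALUE
            )
    elif category_name is not None:
        result.compliance = {m: "unknown" for m in METRICS}
    return result


def exams_to_frame(exams: list[ExamNoiseResult]) -> pd.DataFrame:
    """Render exam results as a flat table (one row per exam)."""
    rows = []
    for e in exams:
        row: dict[str, object] = {"exam_id": e.exam_id, "category": e.category or ""}
        for metric in METRICS:
            v = e.values.get(metric)
            row[metric] = round(v, 6) if v is not None else NO_VALUE
            row[f"{metric}_scan"] = e.scan_ids.get(metric) or ""
            row[f"{metric}_n_slices"] = e.n_slices_used.get(metric, 0)
            row[f"{metric}_compliance"] = e.compliance.get(metric, "unknown")
        rows.append(row)
    return pd.DataFrame(rows)
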