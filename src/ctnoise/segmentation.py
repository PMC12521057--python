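"""HU-threshold segmentation of soft tissue and air.

Soft tissue is the HU window [0, 100]; air is [-1024, -950] (both ends
inclusive).  The Wisconsin noise path thresholds a median-filtered copy of
the slice to stabilize the masks; the Duke path thresholds the raw slice.
Stored values that calibrate below -1024 HU (field-of-view padding, or deep
noise excursions in air) are clamped to -1024 before thresholding so they
cannot masquerade as ultra-dense non-air; the clamp applies only to
segmentation, never to the noise measurements themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "TISSUE_HU_RANGE",
    "AIR_HU_RANGE",
    "SegmentationMask",
    "median_filter_slice",
    "make_mask",
]

TISSUE_HU_RANGE: tuple[float, float] = (0.0, 100.0)
AIR_HU_RANGE: tuple[float, float] = (-1024.0, -950.0)

#: Floor applied to HU values before thresholding (12-bit CT storage floor).
SEGMENTATION_FLOOR_HU: float = -1024.0


@dataclass(frozen=True)
class SegmentationMask:
    """Boolean compartment mask for one slice."""

    mask: np.ndarray
    compartment: str  # "tissue" or "air"
    source_filtered: bool

    def __post_init__(self) -> None:
        if self.compartment not in ("tissue", "air"):
            raise ValueError(f"compartment must be 'tissue' or 'air', got {self.compartment!r}")
        if self.mask.dtype != bool or self.mask.ndim != 2:
            raise ValueError("mask must be a 2-D boolean array")


def median_filter_slice(slice_hu: np.ndarray, kernel_px: int = 3) -> np.ndarray:
    """Median-filter a slice with a square kernel (noise-robust masking).

    ``kernel_px`` must be odd and >= 3 so the kernel has a central pixel.
    Returns a filtered copy; the input is untouched.
    """
    if kernel_px < 3 or kernel_px % 2 == 0:
        raise ValueError(f"kernel_px must be odd and >= 3, got {kernel_px}")
    return ndimage.median_filter(np.asarray(slice_hu, dtype=np.float64), size=kernel_px)


def _threshold(slice_hu: np.ndarray, hu_range: tuple[float, float]) -> np.ndarray:
    lo, hi = hu_range
    clamped = np.maximum(slice_hu, SEGMENTATION_FLOOR_HU)
    return (clamped >= lo) & (clamped <= hi)


def _background_component(air: np.ndarray) -> np.ndarray:
    """Keep only air connected to the image border (outside the patient)."""
    labels, n = ndimage.label(air)
    if n == 0:
        return air
    border = np.unique(
        np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
    )
    border = border[border != 0]
    return np.isin(labels, border)


def make_mask(
    slice_hu: np.ndarray,
    compartment: str,
    *,
    use_median_filter: bool = False,
    kernel_px: int = 3,
    tissue_hu_range: tuple[float, float] = TISSUE_HU_RANGE,
    air_hu_range: tuple[float, float] = AIR_HU_RANGE,
    background_air_only: bool = False,
) -> SegmentationMask:
    """Build a tissue or air mask for one slice by inclusive HU thresholding.

    Parameters
    ----------
    slice_hu : ndarray
        One axial slice in HU.
    compartment : {"tissue", "air"}
    use_median_filter : bool
        Threshold the median-filtered slice (Wisconsin path) instead of the
        raw slice (Duke path).
    kernel_px : int
        Median kernel side; odd, >= 3.
    background_air_only : bool
        Restrict the air mask to air connected to the image border,
        excluding internal gas/lung.  Off by default: all in-FOV air counts.

    Notes
    -----
    Tissue and air windows are disjoint, so tissue and air masks of the same
    slice never overlap.
    """
    if compartment not in ("tissue", "air"):
        raise ValueError(f"compartment must be 'tissue' or 'air', got {compartment!r}")
    src = np.asarray(slice_hu, dtype=np.float64)
    if use_median_filter:
        src = median_filter_slice(src, kernel_px)
    if compartment == "tissue":
        mask = _threshold(src, tissue_hu_range)
    else:
        mask = _threshold(src, air_hu_range)
        if background_air_only:
            mask = _background_component(mask)
    return SegmentationMask(mask=mask, compartment=compartment, source_filtered=use_median_filter)
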