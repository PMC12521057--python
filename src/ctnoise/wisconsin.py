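"""Wisconsin global-noise method.

Anatomy is suppressed by subtracting each slice from its adjacent neighbor;
random noise survives the subtraction (with its variance doubled) while
structure shared by both slices cancels exactly.  The difference image is
tiled with a uniform grid of square ROIs (default 7x7 mm, anchored at the
top-left pixel, partial edge tiles discarded).  Tissue and air masks are
thresholded on the median-filtered *original* (minuend) slice, and only
ROIs wholly inside a mask contribute.  Each valid ROI yields one sample SD;
a slice is summarized by the mean and by the histogram mode of those SDs,
giving the four Wisconsin metrics (tissue/air x mean/mode).

By default each ROI SD is divided by sqrt(2) to undo the variance doubling
of the subtraction, making the reported value an estimate of the
single-image noise; the correction is a flag because published practice
varies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .histogram import DEFAULT_BIN_WIDTH_HU, build_histogram
from .segmentation import make_mask
from .volume import CTVolume

__all__ = [
    "ROIGrid",
    "WisconsinSliceResult",
    "subtract_adjacent",
    "build_roi_grid",
    "roi_sds",
    "wisconsin_slice_gn",
    "wisconsin_volume_gn",
]

logger = logging.getLogger(__name__)

DEFAULT_ROI_MM = 7.0
DEFAULT_MIN_VALID_ROIS = 5


@dataclass(frozen=True)
class ROIGrid:
    """Uniform grid of disjoint square ROIs fully inside a slice."""

    roi_px: int
    n_rows: int
    n_cols: int
    slice_shape: tuple[int, int]

    @property
    def n_rois(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def origins(self) -> list[tuple[int, int]]:
        """Upper-left corner of every ROI (row-major order)."""
        return [
            (r * self.roi_px, c * self.roi_px)
            for r in range(self.n_rows)
            for c in range(self.n_cols)
        ]


@dataclass(frozen=True)
class WisconsinSliceResult:
    """Per-slice Wisconsin noise summary for one compartment."""

    compartment: str
    roi_sds: np.ndarray  # HU, after optional sqrt(2) correction
    mean_gn: float
    mode_gn: float
    n_rois: int
    sqrt2_corrected: bool


def subtract_adjacent(volume: CTVolume, slice_index: int) -> np.ndarray:
    """Difference of a slice and its adjacent neighbor.

    Slice ``i`` pairs with ``i+1``; the last slice, having no later
    neighbor, pairs with the previous one.  Returns ``minuend - neighbor``.
    """
    n = volume.n_slices
    if not 0 <= slice_index < n:
        raise IndexError(f"slice_index {slice_index} out of range for {n} slices")
    neighbor = slice_index + 1 if slice_index < n - 1 else slice_index - 1
    return volume.slice_hu(slice_index) - volume.slice_hu(neighbor)


def build_roi_grid(
    slice_shape: tuple[int, int], roi_mm: float, pixel_spacing_mm: float
) -> ROIGrid:
    """Tile a slice with square ROIs of physical size ``roi_mm``.

    ROI side in pixels is ``round(roi_mm / spacing)`` with a floor of 2
    (an SD needs at least two pixels per axis to be meaningful); the grid
    is anchored at pixel (0, 0) and trailing partial tiles are discarded.
    """
    if roi_mm <= 0 or pixel_spacing_mm <= 0:
        raise ValueError("roi_mm and pixel_spacing_mm must be positive")
    roi_px = int(round(roi_mm / pixel_spacing_mm))
    if roi_px < 2:
        raise ValueError(
            f"ROI of {roi_mm} mm at {pixel_spacing_mm} mm/px spans {roi_px} px (< 2)"
        )
    rows, cols = slice_shape
    n_rows, n_cols = rows // roi_px, cols // roi_px
    if n_rows < 1 or n_cols < 1:
        raise ValueError(f"ROI of {roi_px} px exceeds slice {slice_shape}")
    return ROIGrid(roi_px=roi_px, n_rows=n_rows, n_cols=n_cols, slice_shape=(rows, cols))


def _tile(arr: np.ndarray, grid: ROIGrid) -> np.ndarray:
    """Reshape the grid-covered part of a slice to (n_rois, roi_px*roi_px)."""
    p = grid.roi_px
    cropped = arr[: grid.n_rows * p, : grid.n_cols * p]
    return (
        cropped.reshape(grid.n_rows, p, grid.n_cols, p)
        .transpose(0, 2, 1, 3)
        .reshape(grid.n_rois, p * p)
    )


def roi_sds(diff: np.ndarray, mask: np.ndarray, grid: ROIGrid) -> np.ndarray:
    """Sample SD of the difference image in every ROI fully inside the mask."""
    valid = _tile(mask, grid).all(axis=1)
    tiles = _tile(diff, grid)[valid]
    if tiles.size == 0:
        return np.empty(0)
    return tiles.std(axis=1, ddof=1)


def wisconsin_slice_gn(
    volume: CTVolume,
    slice_index: int,
    compartment: str,
    *,
    roi_mm: float = DEFAULT_ROI_MM,
    bin_width_hu: float = DEFAULT_BIN_WIDTH_HU,
    sqrt2_correction: bool = True,
    median_kernel_px: int = 3,
    min_valid_rois: int = DEFAULT_MIN_VALID_ROIS,
    background_air_only: bool = False,
    tissue_hu_range: tuple[float, float] = (0.0, 100.0),
    air_hu_range: tuple[float, float] = (-1024.0, -950.0),
) -> WisconsinSliceResult | None:
    """Wisconsin noise summary for one slice and compartment, or None.

    The mask comes from the median-filtered minuend slice (never the
    difference image); slices with fewer than ``min_valid_rois`` valid ROIs
    return None ("no-value").
    """
    diff = subtract_adjacent(volume, slice_index)
    grid = build_roi_grid(diff.shape, roi_mm, volume.pixel_spacing_mm[0])
    mask = make_mask(
        volume.slice_hu(slice_index),
        compartment,
        use_median_filter=True,
        kernel_px=median_kernel_px,
        background_air_only=background_air_only,
        tissue_hu_range=tissue_hu_range,
        air_hu_range=air_hu_range,
    ).mask
    sds = roi_sds(diff, mask, grid)
    if sds.size < min_valid_rois:
        logger.info(
            "Wisconsin %s: %d valid ROIs (< %d) on slice %d; no value",
            compartment,
            sds.size,
            min_valid_rois,
            slice_index,
        )
        return None
    if sqrt2_correction:
        sds = sds / np.sqrt(2.0)
    return WisconsinSliceResult(
        compartment=compartment,
        roi_sds=sds,
        mean_gn=float(sds.mean()),
        mode_gn=build_histogram(sds, bin_width_hu).mode,
        n_rois=int(sds.size),
        sqrt2_corrected=sqrt2_correction,
    )


def wisconsin_volume_gn(
    volume: CTVolume,
    compartment: str,
    *,
    roi_mm: float = DEFAULT_ROI_MM,
    bin_width_hu: float = DEFAULT_BIN_WIDTH_HU,
    sqrt2_correction: bool = True,
    median_kernel_px: int = 3,
    min_valid_rois: int = DEFAULT_MIN_VALID_ROIS,
    background_air_only: bool = False,
    tissue_hu_range: tuple[float, float] = (0.0, 100.0),
    air_hu_range: tuple[float, float] = (-1024.0, -950.0),
) -> list[WisconsinSliceResult | None]:
    """Per-slice Wisconsin results for a whole volume."""
    return [
        wisconsin_slice_gn(
            volume,
            i,
            compartment,
            roi_mm=roi_mm,
            bin_width_hu=bin_width_hu,
            sqrt2_correction=sqrt2_correction,
            median_kernel_px=median_kernel_px,
            min_valid_rois=min_valid_rois,
            background_air_only=background_air_only,
            tissue_hu_range=tissue_hu_range,
            air_hu_range=air_hu_range,
        )
        for i in range(volume.n_slices)
    ]
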