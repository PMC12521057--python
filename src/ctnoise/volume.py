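"""In-memory representation of a reconstructed CT series.

A :class:`CTVolume` is an ordered stack of HU-calibrated axial slices with
its in-plane pixel spacing and slice geometry.  All noise metrics in this
package consume this container; DICOM parsing lives in
:mod:`ctnoise.dicom_io` and the phantom generator in :mod:`ctnoise.phantom`
builds the same container directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CTVolume"]


@dataclass
class CTVolume:
    """An axial CT series calibrated to Hounsfield units.

    Parameters
    ----------
    slices : ndarray, shape (n_slices, rows, cols)
        HU values, indexed ``(slice, row, col)``.  Slice index 0 is the most
        inferior position after sorting.
    pixel_spacing_mm : tuple of float
        In-plane (row, col) spacing in mm; both positive.
    slice_thickness_mm : float
        Nominal reconstructed slice thickness in mm.
    slice_positions_mm : ndarray, shape (n_slices,)
        Axial (table) position of each slice, strictly ascending.
    series_id, exam_id : str
        Opaque identifiers (DICOM series / study UIDs for clinical data).

    Notes
    -----
    At least two slices are required: the Wisconsin noise method subtracts
    each slice from an adjacent neighbor, which is undefined for a
    single-slice series.
    """

    slices: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    slice_thickness_mm: float
    slice_positions_mm: np.ndarray = field(default=None)  # type: ignore[assignment]
    series_id: str = "series-0"
    exam_id: str = "exam-0"

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices, dtype=np.float64)
        if self.slices.ndim != 3:
            raise ValueError(
                f"slices must be 3-D (slice, row, col); got shape {self.slices.shape}"
            )
        if self.n_slices < 2:
            raise ValueError(
                "a CT volume needs at least 2 slices: the Wisconsin method "
                "subtracts adjacent slices and has no neighbor otherwise"
            )
        rs, cs = (float(self.pixel_spacing_mm[0]), float(self.pixel_spacing_mm[1]))
        if rs <= 0 or cs <= 0:
            raise ValueError(f"pixel spacing must be positive, got {self.pixel_spacing_mm}")
        self.pixel_spacing_mm = (rs, cs)
        if self.slice_thickness_mm is not None and self.slice_thickness_mm <= 0:
            raise ValueError("slice_thickness_mm must be positive")
        if self.slice_positions_mm is None:
            self.slice_positions_mm = np.arange(self.n_slices, dtype=np.float64) * float(
                self.slice_thickness_mm or 1.0
            )
        self.slice_positions_mm = np.asarray(self.slice_positions_mm, dtype=np.float64)
        if self.slice_positions_mm.shape != (self.n_slices,):
            raise ValueError("slice_positions_mm length must match number of slices")
        if not np.all(np.diff(self.slice_positions_mm) > 0):
            raise ValueError("slice_positions_mm must be strictly ascending")

    @property
    def n_slices(self) -> int:
        return int(self.slices.shape[0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.slices.shape)  # type: ignore[return-value]

    def slice_hu(self, index: int) -> np.ndarray:
        """Return one axial slice (HU, float64)."""
        return self.slices[index]
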