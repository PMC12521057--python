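"""Synthetic CT phantoms with known noise ground truth.

A phantom is an elliptical soft-tissue body (default 50 HU) on an air
background (default -1000 HU), optionally carrying internal structures
(anatomy surrogates), plus zero-mean Gaussian noise of known magnitude
drawn independently per slice.  Spatially correlated noise — the signature
of a smooth reconstruction kernel — is emulated by filtering the white
field with an isotropic Gaussian of a given FWHM; a sharp kernel
corresponds to FWHM 0 (white noise).

By default the post-filter field is rescaled so the marginal per-pixel SD
equals ``sigma_hu`` exactly, making sigma a single unambiguous ground
truth.  Switch rescaling off to compare kernels at equal *pre-filter*
noise amplitude, where the smooth kernel genuinely lowers the measured
noise.

The final volume is rounded to integer HU, as real CT storage is, so
phantoms round-trip bit-exactly through the DICOM writer/reader.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .dicom_io import write_ct_series
from .volume import CTVolume

__all__ = ["Insert", "PhantomSpec", "PhantomTruth", "make_phantom", "make_cohort"]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class Insert:
    """An anatomy surrogate replicated on every slice.

    ``center_mm`` is (row, col) offset from the image center; ``size_mm``
    is the (row, col) semi-axis pair for an ellipse or half-size pair for
    a rectangle.
    """

    shape: str  # "ellipse" or "rect"
    hu: float
    center_mm: tuple[float, float]
    size_mm: tuple[float, float]


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic CT volume.

    Defaults emulate a routine adult abdominal reconstruction: 512x512
    pixels at 0.7 mm, 3 mm slices, a 130x100 mm semi-axis soft-tissue
    ellipse, and white noise.
    """

    shape: tuple[int, int, int] = (20, 512, 512)  # (slices, rows, cols)
    pixel_spacing_mm: float = 0.7
    slice_thickness_mm: float = 3.0
    body_semi_axes_mm: tuple[float, float] = (100.0, 130.0)  # (row, col)
    body_center_mm: tuple[float, float] = (0.0, 0.0)
    tissue_hu: float = 50.0
    air_hu: float = -1000.0
    sigma_hu: float = 10.0
    kernel_fwhm_mm: float = 0.0
    inserts: tuple[Insert, ...] = ()
    seed: int = 0
    rescale_to_sigma: bool = True
    quantize: bool = True
    exam_id: str = "phantom-exam"
    series_id: str = "phantom-series"

    def __post_init__(self) -> None:
        if self.sigma_hu < 0:
            raise ValueError("sigma_hu must be >= 0")
        if self.kernel_fwhm_mm < 0:
            raise ValueError("kernel_fwhm_mm must be >= 0")
        if len(self.shape) != 3 or min(self.shape) < 1:
            raise ValueError(f"invalid shape {self.shape}")


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth accompanying a generated phantom."""

    sigma_hu: float
    tissue_mask: np.ndarray  # noiseless tissue compartment (body + tissue-HU inserts)
    air_mask: np.ndarray  # noiseless air compartment
    seed: int
    spec: PhantomSpec = field(repr=False, default=None)  # type: ignore[assignment]


def _grids_mm(rows: int, cols: int, spacing: float) -> tuple[np.ndarray, np.ndarray]:
    y = (np.arange(rows) - (rows - 1) / 2.0) * spacing
    x = (np.arange(cols) - (cols - 1) / 2.0) * spacing
    return np.meshgrid(y, x, indexing="ij")


def _noiseless_slice(spec: PhantomSpec) -> np.ndarray:
    _, rows, cols = spec.shape
    yy, xx = _grids_mm(rows, cols, spec.pixel_spacing_mm)
    ar, ac = spec.body_semi_axes_mm
    cr, cc = spec.body_center_mm
    half_r = rows * spec.pixel_spacing_mm / 2.0
    half_c = cols * spec.pixel_spacing_mm / 2.0
    if abs(cr) + ar > half_r or abs(cc) + ac > half_c:
        raise ValueError("body ellipse exceeds the field of view")
    body = ((yy - cr) / ar) ** 2 + ((xx - cc) / ac) ** 2 <= 1.0
    img = np.full((rows, cols), spec.air_hu, dtype=np.float64)
    img[body] = spec.tissue_hu
    for ins in spec.inserts:
        icr, icc = ins.center_mm
        sr, sc = ins.size_mm
        if ins.shape == "ellipse":
            region = ((yy - icr) / sr) ** 2 + ((xx - icc) / sc) ** 2 <= 1.0
        elif ins.shape == "rect":
            region = (np.abs(yy - icr) <= sr) & (np.abs(xx - icc) <= sc)
        else:
            raise ValueError(f"unknown insert shape {ins.shape!r}")
        if not region.any():
            raise ValueError("insert lies outside the field of view")
        img[region] = ins.hu
    return img


def _kernel_ssq(sigma_px: float, truncate: float = 4.0) -> float:
    """Sum of squared 2-D Gaussian kernel weights (variance gain of white noise)."""
    radius = int(truncate * sigma_px + 0.5)
    x = np.arange(-radius, radius + 1)
    w = np.exp(-0.5 * (x / sigma_px) ** 2)
    w /= w.sum()
    return float(np.sum(w**2) ** 2)


def make_phantom(spec: PhantomSpec) -> tuple[CTVolume, PhantomTruth]:
    """Generate a phantom volume and its ground truth.

    Noise is drawn independently per slice (the adjacent-slice subtraction
    of the Wisconsin method then cancels structure but not noise, exactly
    as for uncorrelated clinical reconstructions).
    """
    structure = _noiseless_slice(spec)
    tissue_mask = structure == spec.tissue_hu
    for ins in spec.inserts:  # inserts within the tissue window still count as tissue
        if 0.0 <= ins.hu <= 100.0:
            tissue_mask |= structure == ins.hu
    air_mask = structure == spec.air_hu
    n_slices, rows, cols = spec.shape

    rng = np.random.default_rng(spec.seed)
    vol = np.empty(spec.shape, dtype=np.float64)
    sigma_px = spec.kernel_fwhm_mm * FWHM_TO_SIGMA / spec.pixel_spacing_mm
    for i in range(n_slices):
        if spec.sigma_hu == 0:
            noise = 0.0
        else:
            z = rng.standard_normal((rows, cols))
            if sigma_px > 0:
                # wrap mode keeps the filter circulant, so the variance gain
                # is uniform across the slice
                z = gaussian_filter(z, sigma_px, mode="wrap")
                if spec.rescale_to_sigma:
                    z = z / np.sqrt(_kernel_ssq(sigma_px))
            noise = z * spec.sigma_hu
        vol[i] = structure + noise
    if spec.quantize:
        vol = np.rint(vol)

    volume = CTVolume(
        slices=vol,
        pixel_spacing_mm=(spec.pixel_spacing_mm, spec.pixel_spacing_mm),
        slice_thickness_mm=spec.slice_thickness_mm,
        slice_positions_mm=np.arange(n_slices) * spec.slice_thickness_mm,
        series_id=spec.series_id,
        exam_id=spec.exam_id,
    )
    truth = PhantomTruth(
        sigma_hu=spec.sigma_hu, tissue_mask=tissue_mask, air_mask=air_mask,
        seed=spec.seed, spec=spec,
    )
    return volume, truth


def make_cohort(
    spec_template: PhantomSpec,
    n_exams: int,
    sigma_distribution: tuple,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[list[tuple[CTVolume, PhantomTruth]], pd.DataFrame]:
    """Generate a cohort of phantom exams with per-exam noise magnitudes.

    Parameters
    ----------
    sigma_distribution : tuple
        ``("constant", sigma)`` or ``("lognormal", median, gsd)`` where
        ``gsd`` is the geometric standard deviation (> 1).
    out_dir : path-like, optional
        When given, each exam is written as a DICOM series under
        ``out_dir/<exam_id>/<series>/`` with a ground-truth CSV alongside.

    Returns
    -------
    (exams, truth_table)
        ``exams`` is a list of (volume, truth); ``truth_table`` has one row
        per exam (exam_id, sigma_hu, seed).
    """
    if n_exams < 1:
        raise ValueError("n_exams must be >= 1")
    kind = sigma_distribution[0]
    rng = np.random.default_rng(seed)
    if kind == "constant":
        sigmas = np.full(n_exams, float(sigma_distribution[1]))
    elif kind == "lognormal":
        median, gsd = float(sigma_distribution[1]), float(sigma_distribution[2])
        if median <= 0 or gsd <= 1:
            raise ValueError("lognormal needs median > 0 and gsd > 1")
        sigmas = np.exp(rng.normal(np.log(median), np.log(gsd), size=n_exams))
    else:
        raise ValueError(f"unknown sigma distribution {kind!r}")
    exam_seeds = rng.integers(0, 2**31 - 1, size=n_exams)

    exams = []
    records = []
    for i in range(n_exams):
        spec = replace(
            spec_template,
            sigma_hu=float(sigmas[i]),
            seed=int(exam_seeds[i]),
            exam_id=f"exam-{i:03d}",
            series_id=f"exam-{i:03d}-series-0",
        )
        vol, truth = make_phantom(spec)
        exams.append((vol, truth))
        records.append({"exam_id": spec.exam_id, "sigma_hu": spec.sigma_hu, "seed": spec.seed})
    truth_table = pd.DataFrame(records)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for vol, _ in exams:
            write_ct_series(vol, out / vol.exam_id / "series_0")
        truth_table.to_csv(out / "ground_truth.csv", index=False)
    return exams, truth_table
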