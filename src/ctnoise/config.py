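"""Run configuration shared by the CLI and the high-level pipeline.

Every output file embeds the fully resolved configuration so a reported
global-noise value can always be traced to the exact thresholds, window
sizes, binning and flags that produced it.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """All tunable parameters of the noise metrics, with field defaults.

    Units: HU for thresholds and bin widths, mm for physical sizes,
    pixels for the median kernel.
    """

    tissue_hu_range: tuple[float, float] = (0.0, 100.0)
    air_hu_range: tuple[float, float] = (-1024.0, -950.0)
    median_kernel_px: int = 3
    duke_window_mm: float = 7.0
    wisconsin_roi_mm: float = 7.0
    histogram_bin_hu: float = 0.5
    sqrt2_correction: bool = True
    min_mask_pixels: int = 100
    min_valid_rois: int = 5
    background_air_only: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tissue_hu_range"] = list(d["tissue_hu_range"])
        d["air_hu_range"] = list(d["air_hu_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(d)
        for key in ("tissue_hu_range", "air_hu_range"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML config file, or return defaults when path is None."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)
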