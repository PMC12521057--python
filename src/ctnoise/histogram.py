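"""Shared histogram-mode estimator for noise summaries.

Both noise methods summarize a collection of standard deviations by the
mode of a fixed-width histogram.  Bins are centered on integer multiples of
the bin width (edges at half-multiples), so a degenerate collection of
identical values reports that value exactly: a noiseless input yields a
mode of 0 HU, not the center of a [0, width) bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NoiseHistogram", "build_histogram", "histogram_mode"]

DEFAULT_BIN_WIDTH_HU = 0.5


@dataclass(frozen=True)
class NoiseHistogram:
    """Uniform-width histogram of noise values (HU)."""

    bin_edges: np.ndarray  # ascending, length n_bins + 1
    counts: np.ndarray  # non-negative ints, length n_bins
    bin_width_hu: float

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def mode(self) -> float:
        """Center of the maximal-count bin; ties break toward the lowest bin."""
        return float(self.bin_centers[int(np.argmax(self.counts))])


def build_histogram(values: np.ndarray, bin_width_hu: float = DEFAULT_BIN_WIDTH_HU) -> NoiseHistogram:
    """Histogram non-negative noise values into bins centered at k*width."""
    if bin_width_hu <= 0:
        raise ValueError("bin_width_hu must be positive")
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("cannot histogram an empty value set")
    idx = np.rint(values / bin_width_hu).astype(np.int64)
    idx = np.maximum(idx, 0)
    counts = np.bincount(idx)
    edges = (np.arange(counts.size + 1) - 0.5) * bin_width_hu
    return NoiseHistogram(bin_edges=edges, counts=counts, bin_width_hu=float(bin_width_hu))


def histogram_mode(values: np.ndarray, bin_width_hu: float = DEFAULT_BIN_WIDTH_HU) -> float:
    """Modal bin center of a value collection (lowest bin wins ties)."""
    return build_histogram(values, bin_width_hu).mode
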