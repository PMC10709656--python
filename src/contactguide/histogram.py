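"""Normalized angular occurrence histograms shared by the static and
dynamic analyses (2-degree alignment bins, 15-degree turning-angle bins)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class OccurrenceHistogram:
    """A binned angular distribution normalized to fractions summing to 1.

    Bins are half-open ``[lo, hi)`` except the last, which also includes the
    top edge (so 90 deg lands in the [88, 90] alignment bin and 180 deg in
    the [165, 180] turning bin).
    """

    bin_edges_deg: np.ndarray
    fractions: np.ndarray
    n_samples: int
    bin_deg: float
    delta_min: float | None = None

    @property
    def cdf(self) -> np.ndarray:
        """Nondecreasing cumulative fractions, ending at 1."""
        return np.cumsum(self.fractions)


def occurrence_histogram(
    values_deg,
    bin_deg: float,
    range_deg: tuple[float, float],
    delta_min: float | None = None,
) -> OccurrenceHistogram:
    """Bin angles into equal-width bins over ``range_deg`` and normalize.

    Raises on empty input or values outside the range.
    """
    values = np.asarray(values_deg, dtype=float)
    if values.size == 0:
        raise ValueError("cannot build an occurrence histogram from no samples")
    lo, hi = range_deg
    if np.any(values < lo) or np.any(values > hi):
        bad = values[(values < lo) | (values > hi)]
        raise ValueError(f"angles outside [{lo}, {hi}] deg: {bad[:5]}")
    n_bins = int(round((hi - lo) / bin_deg))
    if not np.isclose(n_bins * bin_deg, hi - lo):
        raise ValueError(f"bin width {bin_deg} does not tile [{lo}, {hi}]")
    edges = lo + bin_deg * np.arange(n_bins + 1)
    counts, _ = np.histogram(values, bins=edges)  # top edge falls in last bin
    return OccurrenceHistogram(
        bin_edges_deg=edges,
        fractions=counts / values.size,
        n_samples=int(values.size),
        bin_deg=float(bin_deg),
        delta_min=delta_min,
    )
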