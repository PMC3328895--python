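"""Uniform histograms with nonequidistant (quantile) bins.

Bin edges are placed at empirical quantiles of a calibration sample, so
the calibration histogram is flat and resolution concentrates where the
calibration values do (typically near zero for filter-response magnitudes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class NonEquidistantBinning:
    """Strictly increasing bin edges; ``n_bins + 1`` values."""

    edges: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=np.float64)
        if e.ndim != 1 or e.size < 2:
            raise ValueError("need at least two edges")
        if not np.all(np.diff(e) > 0):
            raise ValueError("edges must be strictly increasing")
        object.__setattr__(self, "edges", e)

    @property
    def n_bins(self) -> int:
        return self.edges.size - 1


def fit_nonequidistant_bins(values: np.ndarray, n_bins: int) -> NonEquidistantBinning:
    """Quantile bin edges from a calibration sample.

    Edges sit at the k/n_bins empirical quantiles, k = 0..n_bins, with
    duplicate edges (heavy ties) nudged apart to keep them strictly
    increasing.  Requires at least ``n_bins`` distinct values.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if np.unique(v).size < n_bins:
        raise ValueError(
            f"need at least {n_bins} distinct calibration values, got {np.unique(v).size}"
        )
    q = np.linspace(0.0, 1.0, n_bins + 1)
    edges = np.quantile(v, q)
    # de-duplicate edges produced by heavy ties
    for i in range(1, edges.size):
        if edges[i] <= edges[i - 1]:
            edges[i] = np.nextafter(edges[i - 1], np.inf)
    return NonEquidistantBinning(edges)


def histogram_descriptor(values: np.ndarray, binning: NonEquidistantBinning) -> np.ndarray:
    """Relative-frequency histogram over the given bins; sums to one.

    Values outside the edge range are clamped into the end bins.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size == 0:
        raise ValueError("empty input")
    clamped = np.clip(v, binning.edges[0], binning.edges[-1])
    counts, _ = np.histogram(clamped, bins=binning.edges)
    return counts / v.size
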