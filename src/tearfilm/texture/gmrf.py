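"""Gaussian Markov random field texture model and directional variances.

Each (zero-mean) pixel is modelled as a linear function of its symmetric
neighbour-pair sums within Chebyshev distance ``d``:

    X(c) = β' Q(c) + e(c),     Q_i(c) = X(c + t_i) + X(c - t_i)

with one direction offset ``t_i`` per orientation on the Chebyshev ring
of radius d (4d directions, the same set used for co-occurrence
orientations).  β is estimated by least squares over the interior region
(margin d).  The descriptor holds the per-direction residual variances

    f_i = mean over interior of (X(c) - β_i Q_i(c))²

giving 4d features for a distance-d model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..image import ChannelImage
from .glcm import offsets_for_distance


class DegenerateModelError(ValueError):
    """Raised when the least-squares design is rank deficient."""


@dataclass(frozen=True)
class GMRFModel:
    d: int
    beta: np.ndarray          # 4d coefficients, one per direction pair
    offsets: tuple[tuple[int, int], ...]
    residual_variance: float

    def __post_init__(self) -> None:
        if len(self.beta) != 4 * self.d:
            raise ValueError("beta must have 4d entries")


def _design(x: np.ndarray, d: int) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """Interior response vector and neighbour-sum design matrix."""
    H, W = x.shape
    if H <= 2 * d or W <= 2 * d:
        raise ValueError(f"image {x.shape} too small for margin {d}")
    offsets = offsets_for_distance(d)
    interior = x[d:H - d, d:W - d]
    cols = []
    for dr, dc in offsets:
        plus = x[d + dr:H - d + dr, d + dc:W - d + dc]
        minus = x[d - dr:H - d - dr, d - dc:W - d - dc]
        cols.append((plus + minus).ravel())
    return interior.ravel(), np.column_stack(cols), offsets


def gmrf_fit(img: ChannelImage, d: int) -> GMRFModel:
    """Least-squares fit of the distance-d model on the mean-centred image."""
    x = img.pixels - img.pixels.mean()
    y, Q, offsets = _design(x, d)
    if np.linalg.matrix_rank(Q) < Q.shape[1]:
        raise DegenerateModelError(
            f"rank-deficient design for d={d} (constant or near-constant image)"
        )
    beta, _, _, _ = np.linalg.lstsq(Q, y, rcond=None)
    resid = y - Q @ beta
    return GMRFModel(d, beta, tuple(offsets), float((resid ** 2).mean()))


def gmrf_directional_variances(img: ChannelImage, model: GMRFModel) -> np.ndarray:
    """Per-direction residual variances f_i; length 4d."""
    x = img.pixels - img.pixels.mean()
    y, Q, _ = _design(x, model.d)
    resid = y[:, None] - Q * model.beta[None, :]
    return (resid ** 2).mean(axis=0)


def gmrf_descriptor(img: ChannelImage, d: int) -> np.ndarray:
    """Fit the model and return the 4d directional variances."""
    return gmrf_directional_variances(img, gmrf_fit(img, d))
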