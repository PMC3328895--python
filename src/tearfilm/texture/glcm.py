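"""Grey-level co-occurrence matrices and the 14 Haralick statistics.

For an interpixel distance ``d`` the orientations are the 4d displacement
offsets on the Chebyshev ring of radius ``d`` (unique up to sign), e.g.
0°, 45°, 90°, 135° for d = 1 and 8 orientations for d = 2.  Counting is
symmetric (each pair counted in both directions) and matrices are
normalised to sum to one.  The image descriptor is the mean and range of
each statistic across the 4d matrices: 28 features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..image import ChannelImage

DEFAULT_GREY_LEVELS = 32
N_STATISTICS = 14

#: Fixed order of the 14 statistics.
STAT_NAMES = (
    "asm", "contrast", "correlation", "variance", "idm", "sum_average",
    "sum_variance", "sum_entropy", "entropy", "difference_variance",
    "difference_entropy", "imc1", "imc2", "mcc",
)


@dataclass(frozen=True)
class GLCMatrix:
    """A normalised G×G co-occurrence matrix for one (distance, offset)."""

    P: np.ndarray
    distance: int
    offset: tuple[int, int]

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=np.float64)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError("co-occurrence matrix must be square")
        if abs(P.sum() - 1.0) > 1e-9:
            raise ValueError("co-occurrence matrix must sum to 1")
        object.__setattr__(self, "P", P)

    @property
    def levels(self) -> int:
        return self.P.shape[0]


def offsets_for_distance(d: int) -> list[tuple[int, int]]:
    """The 4d (row, col) offsets on the Chebyshev ring of radius d.

    One offset per orientation in [0°, 180°), ordered by increasing angle
    measured counterclockwise from the +col axis (rows grow downward).
    """
    if d < 1:
        raise ValueError("distance must be >= 1")
    ring = [
        (dr, dc)
        for dr in range(-d, d + 1)
        for dc in range(-d, d + 1)
        if max(abs(dr), abs(dc)) == d and (dr < 0 or (dr == 0 and dc > 0))
    ]
    ring.sort(key=lambda o: np.arctan2(-o[0], o[1]) % np.pi)
    assert len(ring) == 4 * d
    return ring


def quantise(img: ChannelImage, levels: int = DEFAULT_GREY_LEVELS) -> np.ndarray:
    """Uniform-range quantisation of a channel to integer grey levels."""
    x = img.pixels
    lo, hi = x.min(), x.max()
    if hi - lo < 1e-12:
        return np.zeros(x.shape, dtype=np.intp)
    q = np.floor((x - lo) / (hi - lo) * levels).astype(np.intp)
    return np.minimum(q, levels - 1)


def glcm(quantised: np.ndarray, offset: tuple[int, int], levels: int) -> GLCMatrix:
    """Symmetric, normalised co-occurrence matrix for one offset."""
    dr, dc = offset
    H, W = quantised.shape
    r0, r1 = max(0, -dr), min(H, H - dr)
    c0, c1 = max(0, -dc), min(W, W - dc)
    if r0 >= r1 or c0 >= c1:
        raise ValueError(f"offset {offset} leaves no valid pixel pairs in {quantised.shape}")
    a = quantised[r0:r1, c0:c1].ravel()
    b = quantised[r0 + dr:r1 + dr, c0 + dc:c1 + dc].ravel()
    counts = np.zeros((levels, levels), dtype=np.float64)
    np.add.at(counts, (a, b), 1.0)
    counts += counts.T  # symmetric counting
    d = int(max(abs(dr), abs(dc)))
    return GLCMatrix(counts / counts.sum(), d, (dr, dc))


def _entropy2(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def haralick_features(M: GLCMatrix, return_flags: bool = False):
    """The 14 Haralick statistics of a normalised GLCM, in STAT_NAMES order.

    Entropies use log base 2 with 0·log 0 := 0.  Statistics that are
    undefined for degenerate matrices (zero marginal variance) are
    returned as 0 and flagged.
    """
    P = M.P
    G = M.levels
    i = np.arange(G, dtype=np.float64)
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float(i @ px)
    mu_y = float(i @ py)
    var_x = float(((i - mu_x) ** 2) @ px)
    var_y = float(((i - mu_y) ** 2) @ py)
    degenerate = var_x < 1e-12 or var_y < 1e-12

    # p_{x+y}(k), k = 0..2G-2 and p_{x-y}(k), k = 0..G-1
    ii, jj = np.meshgrid(i, i, indexing="ij")
    p_sum = np.zeros(2 * G - 1)
    np.add.at(p_sum, (ii + jj).astype(np.intp), P)
    p_diff = np.zeros(G)
    np.add.at(p_diff, np.abs(ii - jj).astype(np.intp), P)

    asm = float((P ** 2).sum())
    k_diff = np.arange(G, dtype=np.float64)
    contrast = float((k_diff ** 2) @ p_diff)
    if degenerate:
        correlation = 0.0
    else:
        correlation = float(((ii - mu_x) * (jj - mu_y) * P).sum() / np.sqrt(var_x * var_y))
    variance = float((((ii - mu_x) ** 2) * P).sum())
    idm = float((P / (1.0 + (ii - jj) ** 2)).sum())
    k_sum = np.arange(2 * G - 1, dtype=np.float64)
    sum_average = float(k_sum @ p_sum)
    sum_variance = float(((k_sum - sum_average) ** 2) @ p_sum)
    sum_entropy = _entropy2(p_sum)
    entropy = _entropy2(P.ravel())
    diff_mean = float(k_diff @ p_diff)
    difference_variance = float(((k_diff - diff_mean) ** 2) @ p_diff)
    difference_entropy = _entropy2(p_diff)

    hx = _entropy2(px)
    hy = _entropy2(py)
    outer = np.outer(px, py)
    mask = (P > 0) & (outer > 0)
    hxy1 = float(-(P[mask] * np.log2(outer[mask])).sum())
    mask2 = outer > 0
    hxy2 = float(-(outer[mask2] * np.log2(outer[mask2])).sum())
    if max(hx, hy) < 1e-12:
        imc1 = 0.0
    else:
        imc1 = (entropy - hxy1) / max(hx, hy)
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    if degenerate:
        mcc = 0.0
    else:
        nz = px > 0
        Psub = P[np.ix_(nz, nz)]
        Q = (Psub / px[nz, None]) @ (Psub / py[nz][None, :]).T
        eig = np.sort(np.real(np.linalg.eigvals(Q)))[::-1]
        mcc = float(np.sqrt(max(0.0, eig[1]))) if eig.size > 1 else 0.0

    vec = np.array([
        asm, contrast, correlation, variance, idm, sum_average, sum_variance,
        sum_entropy, entropy, difference_variance, difference_entropy,
        imc1, imc2, mcc,
    ])
    if return_flags:
        return vec, {"degenerate_marginals": degenerate}
    return vec


def cooccurrence_descriptor(
    img: ChannelImage, d: int, levels: int = DEFAULT_GREY_LEVELS
) -> np.ndarray:
    """Mean and range of the 14 statistics across the 4d matrices (28 features)."""
    q = quantise(img, levels)
    stats = np.stack(
        [haralick_features(glcm(q, off, levels)) for off in offsets_for_distance(d)]
    )
    return np.concatenate([stats.mean(axis=0), stats.max(axis=0) - stats.min(axis=0)])
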