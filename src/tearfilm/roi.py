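"""Region-of-interest extraction by normalised cross-correlation.

The ROI (the most illuminated area, at the bottom of the iris) is found
by sliding a set of illumination-profile templates over the luminance
channel L and taking the placement with globally maximum Pearson-type
normalised cross-correlation.  The crop returned is the subtemplate
region of the winning template at the winning placement.

Coordinates are 0-based (row, col); crop windows are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .colour import rgb_to_lab
from .image import ChannelImage, RGBImage


class NoROIError(ValueError):
    """Raised when no placement yields a defined correlation score."""


@dataclass(frozen=True)
class ROITemplate:
    """An illumination profile plus the crop mask used once it is matched."""

    weights: np.ndarray
    subtemplate_mask: np.ndarray
    template_id: str

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        m = np.asarray(self.subtemplate_mask, dtype=bool)
        if w.ndim != 2:
            raise ValueError("template weights must be 2-D")
        if m.shape != w.shape:
            raise ValueError("mask shape must match template shape")
        if w.std() < 1e-12:
            raise ValueError("template must have nonzero variance")
        if not m.any():
            raise ValueError("subtemplate mask must be nonempty")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "subtemplate_mask", m)

    @property
    def shape(self) -> tuple[int, int]:
        return self.weights.shape

    def mask_bbox(self) -> tuple[int, int, int, int]:
        """(r0, c0, r1, c1) half-open bounding box of the mask."""
        rows = np.flatnonzero(self.subtemplate_mask.any(axis=1))
        cols = np.flatnonzero(self.subtemplate_mask.any(axis=0))
        return int(rows[0]), int(cols[0]), int(rows[-1] + 1), int(cols[-1] + 1)


@dataclass(frozen=True)
class ROIResult:
    """Winning placement: ``top_left`` is where the template was placed
    (the NCC map attains ``score`` there); ``crop_top_left`` locates the
    returned subtemplate crop inside the source image."""

    crop: RGBImage | ChannelImage
    top_left: tuple[int, int]
    crop_top_left: tuple[int, int]
    score: float
    template_id: str


def normalised_cross_correlation(image: ChannelImage, template: ROITemplate) -> np.ndarray:
    """Valid-mode map of Pearson correlations between template and windows.

    Output shape is (H-h+1, W-w+1).  Placements where the image window
    has zero variance get score 0.  Scores lie in [-1, 1].
    """
    x = image.pixels
    t = template.weights
    h, w = t.shape
    H, W = x.shape
    if h > H or w > W:
        raise ValueError(f"template {t.shape} larger than image {x.shape}")
    n = h * w
    t0 = t - t.mean()
    t_ss = float((t0 ** 2).sum())

    # window sums via an integral image (exact enough at these scales)
    ones = np.ones((h, w))
    from scipy.signal import fftconvolve

    win_sum = fftconvolve(x, ones[::-1, ::-1], mode="valid")
    win_sq = fftconvolve(x ** 2, ones[::-1, ::-1], mode="valid")
    cross = fftconvolve(x, t0[::-1, ::-1], mode="valid")

    win_var_n = win_sq - win_sum ** 2 / n  # Σ(x-mean)² per window
    denom = np.sqrt(np.maximum(win_var_n, 0.0) * t_ss)
    with np.errstate(invalid="ignore", divide="ignore"):
        ncc = cross / denom
    ncc[~np.isfinite(ncc)] = 0.0
    ncc[win_var_n <= 1e-9 * n] = 0.0
    return np.clip(ncc, -1.0, 1.0)


def band_profile(h: int, w: int, band_frac: float = 0.35) -> np.ndarray:
    """Bright horizontal band: Gaussian vertical profile with a gentle
    horizontal falloff (shared with the synthetic eye generator)."""
    rows = np.arange(h, dtype=np.float64)
    cols = np.arange(w, dtype=np.float64)
    r_centre, c_centre = (h - 1) / 2.0, (w - 1) / 2.0
    sigma_r = band_frac * h / 2.0
    sigma_c = w / 3.0
    v = np.exp(-0.5 * ((rows - r_centre) / sigma_r) ** 2)
    u = np.exp(-0.5 * ((cols - c_centre) / sigma_c) ** 2)
    return v[:, None] * u[None, :]


def _band_template(h: int, w: int, band_frac: float, template_id: str) -> ROITemplate:
    """Bright horizontal band with a Gaussian vertical profile."""
    centre = (h - 1) / 2.0
    sigma = band_frac * h / 2.0
    weights = band_profile(h, w, band_frac)
    mask = np.zeros((h, w), dtype=bool)
    r0 = int(np.floor(centre - sigma))
    r1 = int(np.ceil(centre + sigma)) + 1
    c0, c1 = w // 8, w - w // 8
    mask[max(0, r0):min(h, r1), c0:c1] = True
    return ROITemplate(weights, mask, template_id)


def _crescent_template(h: int, w: int, template_id: str) -> ROITemplate:
    """Bright downward-curving crescent (band bent along a parabola)."""
    rows = np.arange(h, dtype=np.float64)[:, None]
    cols = np.arange(w, dtype=np.float64)[None, :]
    centre_row = (h - 1) / 2.0 + 0.15 * h * ((2 * cols / (w - 1) - 1.0) ** 2)
    sigma = h / 6.0
    weights = np.exp(-0.5 * ((rows - centre_row) / sigma) ** 2)
    mask = np.abs(rows - centre_row) <= sigma
    c0, c1 = w // 8, w - w // 8
    keep = np.zeros((h, w), dtype=bool)
    keep[:, c0:c1] = True
    return ROITemplate(weights, mask & keep, template_id)


def generate_templates(config: dict | None = None) -> list[ROITemplate]:
    """Deterministic builtin template set: bands and crescents at 3 scales.

    ``config`` may override ``sizes`` (list of (h, w)) and ``band_frac``.
    The builtin geometry is a stand-in for the unpublished clinical set;
    its contract is recovering a planted bright region.
    """
    if config is not None and len(config) == 0:
        raise ValueError("empty template config")
    config = {} if config is None else dict(config)
    sizes = config.get("sizes", [(32, 96), (48, 144), (64, 192)])
    band_frac = config.get("band_frac", 0.35)
    if not sizes:
        raise ValueError("template config must define at least one size")
    out: list[ROITemplate] = []
    for i, (h, w) in enumerate(sizes):
        out.append(_band_template(h, w, band_frac, f"band_{i}"))
        out.append(_crescent_template(h, w, f"crescent_{i}"))
    return out


def extract_roi(img: RGBImage, templates: list[ROITemplate]) -> ROIResult:
    """Best (template, placement) by NCC on L; returns the masked subcrop.

    Ties are broken by template order, then row-major placement.  A
    constant image (every window score undefined) raises NoROIError.
    """
    if not templates:
        raise ValueError("template list is empty")
    L, _, _ = rgb_to_lab(img)
    best: tuple[float, int, int, int] | None = None  # (score, t_idx, r, c)
    for t_idx, tpl in enumerate(templates):
        if tpl.shape[0] > img.height or tpl.shape[1] > img.width:
            raise ValueError(
                f"template {tpl.template_id} {tpl.shape} exceeds image {img.shape}"
            )
        ncc = normalised_cross_correlation(L, tpl)
        r, c = np.unravel_index(np.argmax(ncc), ncc.shape)
        score = float(ncc[r, c])
        if best is None or score > best[0] + 1e-12:
            best = (score, t_idx, int(r), int(c))
    assert best is not None
    score, t_idx, r, c = best
    if abs(score) < 1e-12 and L.pixels.std() < 1e-9:
        raise NoROIError("constant image: correlation undefined everywhere")
    tpl = templates[t_idx]
    r0, c0, r1, c1 = tpl.mask_bbox()
    crop = RGBImage(img.pixels[r + r0:r + r1, c + c0:c + c1])
    return ROIResult(crop, (r, c), (r + r0, c + c0), score, tpl.template_id)
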