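"""Seeded synthetic imagery emulating the four lipid-layer categories.

The four texture classes:

* ``open_meshwork`` — sparse, low-contrast grey meshwork (thresholded
  band-limited noise ridges at low density),
* ``closed_meshwork`` — denser, higher-contrast grey meshwork,
* ``wave`` — oriented grey sinusoid (horizontal or vertical) with a
  smooth phase-noise field,
* ``colour_fringe`` — smooth fringe field oscillating between brown and
  blue on a whitish background.

All generators are deterministic given a seed.  A full synthetic "eye"
frame embeds a bright band-shaped textured region in a dark surround at a
known location, for end-to-end ROI testing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .colour import lab_to_rgb
from .image import RGBImage

GUILLON_LABELS = ("open_meshwork", "closed_meshwork", "wave", "colour_fringe")

#: Class counts of the reference clinical dataset (open, closed, wave, fringe).
DEFAULT_CLASS_COUNTS = (29, 29, 25, 22)

# Fringe endpoint colours in Lab: brown and blue.
_BROWN_LAB = (55.0, 15.0, 30.0)
_BLUE_LAB = (55.0, 5.0, -35.0)


@dataclass(frozen=True)
class CategorySpec:
    label: str
    pattern: str                  # sparse_mesh | dense_mesh | wave | colour_fringe
    base_grey: float = 0.5
    contrast: float = 0.2
    spatial_scale: float = 8.0    # pixels
    noise_sd: float = 0.02
    mesh_density: float = 0.25    # fraction of pixels on ridges (mesh patterns)
    orientation: float = 0.0      # radians (wave pattern)

    def __post_init__(self) -> None:
        if self.contrast < 0:
            raise ValueError("contrast must be >= 0")
        if self.spatial_scale < 2:
            raise ValueError("spatial scale must be >= 2 pixels")


DEFAULT_SPECS = {
    "open_meshwork": CategorySpec(
        "open_meshwork", "sparse_mesh", base_grey=0.35, contrast=0.10,
        spatial_scale=11.0, mesh_density=0.18,
    ),
    "closed_meshwork": CategorySpec(
        "closed_meshwork", "dense_mesh", base_grey=0.50, contrast=0.22,
        spatial_scale=5.0, mesh_density=0.45,
    ),
    "wave": CategorySpec(
        "wave", "wave", base_grey=0.50, contrast=0.20, spatial_scale=14.0,
    ),
    "colour_fringe": CategorySpec(
        "colour_fringe", "colour_fringe", base_grey=0.72, contrast=0.5,
        spatial_scale=16.0,
    ),
}


@dataclass(frozen=True)
class SyntheticDataset:
    images: tuple[RGBImage, ...]
    labels: tuple[str, ...]
    seed: int

    @property
    def class_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for lbl in self.labels:
            out[lbl] = out.get(lbl, 0) + 1
        return out


def _smooth_noise(rng: np.random.Generator, shape, scale: float) -> np.ndarray:
    """Band-limited unit-variance noise field."""
    g = ndimage.gaussian_filter(rng.standard_normal(shape), scale / 2.0, mode="wrap")
    sd = g.std()
    return g / (sd if sd > 1e-12 else 1.0)


def _mesh_pattern(rng, shape, scale: float, density: float) -> np.ndarray:
    """Web of ridges: pixels where a smooth field is near its zero level."""
    field = _smooth_noise(rng, shape, scale)
    # threshold chosen so ~`density` of pixels land on ridges
    from scipy.stats import norm

    t = norm.ppf(0.5 + density / 2.0)
    return (np.abs(field) < t).astype(np.float64)


def generate_category_image(
    spec: CategorySpec, size: tuple[int, int] = (128, 128), seed: int = 0
) -> RGBImage:
    """One synthetic texture patch of the given category; seeded."""
    H, W = size
    if H < 64 or W < 64:
        raise ValueError("size must be at least 64×64")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)

    if spec.pattern in ("sparse_mesh", "dense_mesh"):
        pattern = _mesh_pattern(rng, size, spec.spatial_scale, spec.mesh_density)
        grey = spec.base_grey + spec.contrast * (pattern - pattern.mean())
        grey = grey + spec.noise_sd * rng.standard_normal(size)
        px = np.repeat(np.clip(grey, 0, 1)[..., None], 3, axis=2)
    elif spec.pattern == "wave":
        u = xx * np.cos(spec.orientation) + yy * np.sin(spec.orientation)
        phase = 1.5 * _smooth_noise(rng, size, 4 * spec.spatial_scale)
        grey = spec.base_grey + spec.contrast * np.sin(
            2 * np.pi * u / spec.spatial_scale + phase
        )
        grey = grey + spec.noise_sd * rng.standard_normal(size)
        px = np.repeat(np.clip(grey, 0, 1)[..., None], 3, axis=2)
    elif spec.pattern == "colour_fringe":
        u = xx * np.cos(spec.orientation) + yy * np.sin(spec.orientation)
        phase = 2.0 * _smooth_noise(rng, size, 2 * spec.spatial_scale)
        w = 0.5 * (1.0 + np.sin(2 * np.pi * u / spec.spatial_scale + phase))
        strength = spec.contrast  # fringe saturation
        L = 100.0 * spec.base_grey + 6.0 * _smooth_noise(rng, size, spec.spatial_scale)
        a = strength * (w * _BROWN_LAB[1] + (1 - w) * _BLUE_LAB[1])
        b = strength * (w * _BROWN_LAB[2] + (1 - w) * _BLUE_LAB[2])
        px = lab_to_rgb(L, a, b)
        px = np.clip(px + spec.noise_sd * rng.standard_normal(px.shape), 0, 1)
    else:
        raise ValueError(f"unknown pattern {spec.pattern!r}")
    return RGBImage(px)


def _jitter(spec: CategorySpec, rng: np.random.Generator) -> CategorySpec:
    """Per-image variation of contrast, scale and orientation."""
    kw = dict(
        contrast=spec.contrast * rng.uniform(0.8, 1.2),
        spatial_scale=max(2.0, spec.spatial_scale * rng.uniform(0.85, 1.15)),
    )
    if spec.pattern in ("wave", "colour_fringe"):
        base = rng.choice([0.0, np.pi / 2])  # horizontal or vertical waves
        kw["orientation"] = float(base + np.deg2rad(rng.uniform(-10, 10)))
    return replace(spec, **kw)


def generate_dataset(
    counts: tuple[int, int, int, int] = DEFAULT_CLASS_COUNTS,
    size: tuple[int, int] = (128, 128),
    seed: int = 0,
    specs: dict[str, CategorySpec] | None = None,
) -> SyntheticDataset:
    """Class-stratified dataset with per-image jitter; labels in fixed order."""
    if any(c < 1 for c in counts):
        raise ValueError("class counts must be >= 1")
    specs = specs or DEFAULT_SPECS
    rng = np.random.default_rng(seed)
    images: list[RGBImage] = []
    labels: list[str] = []
    for label, n in zip(GUILLON_LABELS, counts):
        for _ in range(n):
            jspec = _jitter(specs[label], rng)
            img_seed = int(rng.integers(0, 2**31 - 1))
            images.append(generate_category_image(jspec, size, img_seed))
            labels.append(label)
    return SyntheticDataset(tuple(images), tuple(labels), seed)


def generate_eye_image(
    roi_spec: dict | None = None,
    size: tuple[int, int] = (240, 320),
    seed: int = 0,
) -> tuple[RGBImage, tuple[int, int]]:
    """Synthetic eye frame: dark surround + bright textured band.

    ``roi_spec`` keys: ``shape`` (h, w) of the planted region, ``top_left``
    (row, col) or None to centre it low in the frame, ``category`` label,
    ``band_frac`` vertical Gaussian width fraction, ``peak`` brightness.
    Returns the frame and the ground-truth top-left of the planted region.
    """
    roi_spec = dict(roi_spec or {})
    H, W = size
    h, w = roi_spec.get("shape", (48, 144))
    top_left = roi_spec.get("top_left")
    if top_left is None:
        top_left = (int(H * 0.55), (W - w) // 2)
    r0, c0 = top_left
    if r0 < 0 or c0 < 0 or r0 + h > H or c0 + w > W:
        raise ValueError(f"planted region {h}×{w} at {top_left} out of bounds for {size}")
    category = roi_spec.get("category", "wave")
    band_frac = roi_spec.get("band_frac", 0.35)
    peak = roi_spec.get("peak", 0.85)

    rng = np.random.default_rng(seed)
    frame = 0.08 + 0.02 * rng.standard_normal((H, W, 3))
    frame = np.clip(frame, 0, 1)

    tex_h = max(64, h)
    tex = generate_category_image(
        replace(DEFAULT_SPECS[category], contrast=DEFAULT_SPECS[category].contrast * 0.6),
        (tex_h, max(64, w)),
        seed=int(rng.integers(0, 2**31 - 1)),
    ).pixels[:h, :w]

    from .roi import band_profile

    profile = band_profile(h, w, band_frac)[:, :, None]
    region = frame[r0:r0 + h, c0:c0 + w, :]
    lit = np.clip(peak * profile * (0.6 + 0.5 * tex), 0, 1)
    frame[r0:r0 + h, c0:c0 + w, :] = np.clip(
        region * (1 - profile) + lit * profile, 0, 1
    )
    return RGBImage(np.clip(frame, 0, 1)), (int(r0), int(c0))
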