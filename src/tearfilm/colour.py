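"""Colour-space transforms and per-space descriptor assembly.

Three analysis spaces are supported: plain grayscale, CIE 1976 L*a*b*
(D65, sRGB primaries) and the Hering opponent channels

    RG = R - p*G,   GR = G - p*R,   BY = B - p*(R+G)

where ``p`` is a unit-DC-gain spatial lowpass and ``*`` denotes 2-D
convolution.  Multichannel descriptors are the concatenation of the three
per-channel descriptors in fixed order (L, a, b) / (RG, GR, BY).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import color as skcolor

from .image import ChannelImage, RGBImage

#: ITU-R BT.601 luma weights used for the grayscale conversion.
GRAY_WEIGHTS = (0.299, 0.587, 0.114)

SPACES = ("gray", "lab", "opponent")


def to_grayscale(img: RGBImage) -> ChannelImage:
    """Luma-weighted grayscale conversion, output in [0, 1]."""
    w = np.asarray(GRAY_WEIGHTS)
    return ChannelImage(img.pixels @ w, "gray")


def rgb_to_lab(img: RGBImage) -> tuple[ChannelImage, ChannelImage, ChannelImage]:
    """Convert sRGB (D65) to CIE 1976 L*a*b*; returns (L, a, b) channels.

    L is in [0, 100]; a and b are signed chromatic differences.
    """
    lab = skcolor.rgb2lab(img.pixels)
    return (
        ChannelImage(lab[..., 0], "L"),
        ChannelImage(lab[..., 1], "a"),
        ChannelImage(lab[..., 2], "b"),
    )


def lab_to_rgb(L: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Inverse Lab transform (used for round-trip checks and synthesis)."""
    lab = np.stack([L, a, b], axis=-1)
    return np.clip(skcolor.lab2rgb(lab), 0.0, 1.0)


@dataclass(frozen=True)
class OpponentTransformSpec:
    """Lowpass used inside the opponent-colour transform.

    The kernel is a truncated, renormalised Gaussian, so a constant image
    is mapped exactly to itself (unit DC gain).
    """

    lowpass_kind: str = "gaussian"
    lowpass_width: float = 2.0  # sigma, pixels
    truncate: float = 4.0

    def kernel(self) -> np.ndarray:
        if self.lowpass_kind != "gaussian":
            raise ValueError(f"unknown lowpass kind {self.lowpass_kind!r}")
        if self.lowpass_width <= 0:
            raise ValueError("lowpass width must be positive")
        r = int(np.ceil(self.truncate * self.lowpass_width))
        x = np.arange(-r, r + 1, dtype=np.float64)
        g = np.exp(-0.5 * (x / self.lowpass_width) ** 2)
        g /= g.sum()
        return np.outer(g, g)


def _lowpass(channel: np.ndarray, spec: OpponentTransformSpec) -> np.ndarray:
    return ndimage.convolve(channel, spec.kernel(), mode="reflect")


def rgb_to_opponent(
    img: RGBImage, spec: OpponentTransformSpec | None = None
) -> tuple[ChannelImage, ChannelImage, ChannelImage]:
    """Compute the opponent channels RG, GR, BY of an RGB image."""
    spec = spec or OpponentTransformSpec()
    R, G, B = img.pixels[..., 0], img.pixels[..., 1], img.pixels[..., 2]
    rg = R - _lowpass(G, spec)
    gr = G - _lowpass(R, spec)
    by = B - _lowpass(R + G, spec)
    return (ChannelImage(rg, "RG"), ChannelImage(gr, "GR"), ChannelImage(by, "BY"))


def channels_in_space(
    img: RGBImage, space: str, opponent_spec: OpponentTransformSpec | None = None
) -> list[ChannelImage]:
    """The ordered analysis channels of ``img`` in the named space."""
    if space == "gray":
        return [to_grayscale(img)]
    if space == "lab":
        return list(rgb_to_lab(img))
    if space == "opponent":
        return list(rgb_to_opponent(img, opponent_spec))
    raise ValueError(f"unknown colour space {space!r}")


def descriptor_in_space(
    img: RGBImage,
    method: str,
    space: str,
    opponent_spec: OpponentTransformSpec | None = None,
    **params,
) -> np.ndarray:
    """Texture descriptor of an RGB image computed in one analysis space.

    For ``space='gray'`` this is the single-channel descriptor; for
    ``'lab'``/``'opponent'`` it is the concatenation of the three
    per-channel descriptors, so its length is three times the grayscale
    length.
    """
    from .texture import compute_descriptor  # deferred: avoids import cycle

    if space not in SPACES:
        raise ValueError(f"unknown colour space {space!r}")
    chans = channels_in_space(img, space, opponent_spec)
    parts = [compute_descriptor(ch, method, **params) for ch in chans]
    return np.concatenate(parts)
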