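"""Two-scale orthonormal Haar pyramid and its 12-component descriptor.

The 2-D analysis step maps non-overlapping 2×2 blocks [[p, q], [r, s]] to

    LL = (p + q + r + s) / 2      HL = (p + q - r - s) / 2
    LH = (p - q + r - s) / 2      HH = (p - q - r + s) / 2

which is orthonormal, so total squared-coefficient energy is conserved.
The step is repeated on LL, giving 8 subimages over 2 scales.  The
descriptor holds the mean and absolute average deviation of the input and
the two LL images, plus the energy (mean squared coefficient) of the six
detail subimages: 12 components.
"""

from __future__ import annotations

import logging

import numpy as np

from ..image import ChannelImage

log = logging.getLogger(__name__)

DESCRIPTOR_LENGTH = 12


def _haar_step(x: np.ndarray) -> dict[str, np.ndarray]:
    p = x[0::2, 0::2]
    q = x[0::2, 1::2]
    r = x[1::2, 0::2]
    s = x[1::2, 1::2]
    return {
        "LL": (p + q + r + s) / 2.0,
        "LH": (p - q + r - s) / 2.0,
        "HL": (p + q - r - s) / 2.0,
        "HH": (p - q - r + s) / 2.0,
    }


def haar_pyramid(img: ChannelImage, n_scales: int = 2) -> dict[str, np.ndarray]:
    """Orthonormal Haar subbands {LL1, LH1, HL1, HH1, LL2, ...}.

    Odd dimensions are trimmed by one row/column (logged) at each scale.
    """
    x = img.pixels
    if x.shape[0] < 4 or x.shape[1] < 4:
        raise ValueError("image must be at least 4×4 for a 2-scale pyramid")
    out: dict[str, np.ndarray] = {}
    for scale in range(1, n_scales + 1):
        if x.shape[0] % 2 or x.shape[1] % 2:
            log.warning("trimming odd dimension %s before Haar scale %d", x.shape, scale)
            x = x[: x.shape[0] - x.shape[0] % 2, : x.shape[1] - x.shape[1] % 2]
        bands = _haar_step(x)
        for k, v in bands.items():
            out[f"{k}{scale}"] = v
        x = bands["LL"]
    return out


def _aad(x: np.ndarray) -> float:
    return float(np.abs(x - x.mean()).mean())


def wavelet_descriptor(img: ChannelImage) -> np.ndarray:
    """[μ, aad](input, LL1, LL2) + energy(LH, HL, HH at both scales)."""
    bands = haar_pyramid(img, n_scales=2)
    x = img.pixels
    vec = [
        x.mean(), _aad(x),
        bands["LL1"].mean(), _aad(bands["LL1"]),
        bands["LL2"].mean(), _aad(bands["LL2"]),
    ]
    for name in ("LH1", "HL1", "HH1", "LH2", "HL2", "HH2"):
        vec.append(float((bands[name] ** 2).mean()))
    return np.asarray(vec, dtype=np.float64)
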