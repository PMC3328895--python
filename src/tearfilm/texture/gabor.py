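"""Bank of 16 complex Gabor filters (4 frequencies × 4 orientations).

A single filter is a complex exponential modulated by an oriented
Gaussian envelope:

    g(x, y) = exp{i [2π f0 (x cosθ0 + y sinθ0) + φ]} · gauss(x, y)
    gauss(x, y) = a · exp{-π [a² (x cosθ0 + y sinθ0)² + b² (x sinθ0 - y cosθ0)²]}

The default bank uses frequencies {1/16, 1/8, 1/4, 3/8} cycles/pixel and
orientations {0°, 45°, 90°, 135°}, with a = b chosen for a one-octave
half-magnitude bandwidth.  The descriptor of each of the 16 magnitude
responses is its nonequidistant histogram with 3, 5, 7 or 9 bins,
concatenated frequency-major.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from ..image import ChannelImage
from .histogram import NonEquidistantBinning, fit_nonequidistant_bins, histogram_descriptor

DEFAULT_FREQUENCIES = (1 / 16, 1 / 8, 1 / 4, 3 / 8)
DEFAULT_ORIENTATIONS = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
VALID_N_BINS = (3, 5, 7, 9)

#: a = f0/3 · sqrt(π / ln 2) gives half-magnitude bandwidth of one octave.
_OCTAVE_SHAPE = np.sqrt(np.pi / np.log(2)) / 3.0


@dataclass(frozen=True)
class GaborBankSpec:
    frequencies: tuple[float, ...] = DEFAULT_FREQUENCIES
    orientations: tuple[float, ...] = DEFAULT_ORIENTATIONS  # radians
    phase: float = 0.0

    @property
    def n_filters(self) -> int:
        return len(self.frequencies) * len(self.orientations)


def gabor_kernel(
    f0: float,
    theta0: float,
    a: float | None = None,
    b: float | None = None,
    phase: float = 0.0,
    half_size: int | None = None,
) -> np.ndarray:
    """Complex Gabor kernel sampled on a centred integer grid.

    ``a``/``b`` default to the one-octave shape for frequency ``f0``; the
    support radius defaults to three envelope standard widths.
    """
    if f0 <= 0:
        raise ValueError("frequency must be positive")
    a = f0 * _OCTAVE_SHAPE if a is None else a
    b = a if b is None else b
    if a <= 0 or b <= 0:
        raise ValueError("shape parameters must be positive")
    if half_size is None:
        half_size = int(np.ceil(3.0 / (np.sqrt(np.pi) * min(a, b))))
    y, x = np.mgrid[-half_size:half_size + 1, -half_size:half_size + 1].astype(np.float64)
    u = x * np.cos(theta0) + y * np.sin(theta0)
    v = x * np.sin(theta0) - y * np.cos(theta0)
    envelope = a * np.exp(-np.pi * (a ** 2 * u ** 2 + b ** 2 * v ** 2))
    carrier = np.exp(1j * (2 * np.pi * f0 * u + phase))
    return carrier * envelope


def gabor_magnitude_responses(
    img: ChannelImage, spec: GaborBankSpec | None = None
) -> list[np.ndarray]:
    """|response| of the 16 filters, frequency-major, orientation-minor."""
    spec = spec or GaborBankSpec()
    out = []
    for f0 in spec.frequencies:
        for th in spec.orientations:
            k = gabor_kernel(f0, th, phase=spec.phase)
            resp = signal.fftconvolve(img.pixels, k, mode="same")
            out.append(np.abs(resp))
    return out


def gabor_descriptor(
    img: ChannelImage,
    n_bins: int,
    spec: GaborBankSpec | None = None,
    binnings: list[NonEquidistantBinning] | None = None,
) -> np.ndarray:
    """Concatenated per-filter histograms: 16 × n_bins components.

    One binning per filter; if not supplied, each is calibrated on the
    filter's own magnitude response (the cross-validated pipeline fits
    them on training images only).
    """
    if n_bins not in VALID_N_BINS:
        raise ValueError(f"n_bins must be one of {VALID_N_BINS}")
    spec = spec or GaborBankSpec()
    responses = gabor_magnitude_responses(img, spec)
    if binnings is None:
        binnings = [fit_nonequidistant_bins(r, n_bins) for r in responses]
    if len(binnings) != len(responses):
        raise ValueError("need one binning per filter")
    return np.concatenate(
        [histogram_descriptor(r, bn) for r, bn in zip(responses, binnings)]
    )
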