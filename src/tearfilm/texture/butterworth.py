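"""Bank of 9 second-order Butterworth bandpass filters.

Each filter has radially symmetric frequency response

    f(w) = 1 / (1 + ((w - w_c) / w_0)^(2n))

with centre frequency ``w_c`` and scale ``w_0`` in cycles/pixel.  The
default bank tiles (0, 0.5] with 9 uniformly spaced centres and
``w_0`` equal to half the band spacing, so the bands jointly cover the
whole spectrum up to Nyquist.  The per-band descriptor is a 16-bin
nonequidistant histogram of the band image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..image import ChannelImage
from .histogram import NonEquidistantBinning, fit_nonequidistant_bins, histogram_descriptor

N_BANDS = 9
DEFAULT_N_BINS = 16


def butterworth_gain(omega, omega_c: float, omega_0: float, n: int = 2):
    """Scalar bandpass gain; 1 at the centre, 1/2 at ``omega_c ± omega_0``."""
    if omega_0 <= 0:
        raise ValueError("omega_0 must be positive")
    if n < 1:
        raise ValueError("filter order must be >= 1")
    omega = np.asarray(omega, dtype=np.float64)
    return 1.0 / (1.0 + ((omega - omega_c) / omega_0) ** (2 * n))


@dataclass(frozen=True)
class ButterworthBankSpec:
    n_filters: int = N_BANDS
    order: int = 2
    centres: tuple[float, ...] = field(default=None)  # cycles/pixel
    widths: tuple[float, ...] = field(default=None)

    def __post_init__(self) -> None:
        if self.centres is None:
            spacing = 0.5 / self.n_filters
            object.__setattr__(
                self, "centres", tuple(spacing * (k + 1) for k in range(self.n_filters))
            )
        if self.widths is None:
            spacing = 0.5 / self.n_filters
            object.__setattr__(self, "widths", tuple([spacing / 2.0] * self.n_filters))
        if len(self.centres) != self.n_filters or len(self.widths) != self.n_filters:
            raise ValueError("centres/widths length must equal n_filters")


def radial_frequency_grid(shape: tuple[int, int]) -> np.ndarray:
    """|frequency| in cycles/pixel at every DFT sample of an H×W image."""
    fy = np.fft.fftfreq(shape[0])
    fx = np.fft.fftfreq(shape[1])
    return np.hypot(fy[:, None], fx[None, :])


def butterworth_band_image(
    img: ChannelImage,
    band: int,
    spec: ButterworthBankSpec | None = None,
    normalise: bool = True,
) -> ChannelImage:
    """Apply one bandpass filter of the bank in the frequency domain.

    ``band`` is 1-based.  With ``normalise=True`` the result is min-max
    scaled to [0, 1] (each band is normalised separately before
    histogramming); a constant band image maps to zeros.
    """
    spec = spec or ButterworthBankSpec()
    if not 1 <= band <= spec.n_filters:
        raise ValueError(f"band must be in 1..{spec.n_filters}")
    wc = spec.centres[band - 1]
    w0 = spec.widths[band - 1]
    gain = butterworth_gain(radial_frequency_grid(img.shape), wc, w0, spec.order)
    out = np.fft.ifft2(np.fft.fft2(img.pixels) * gain).real
    if normalise:
        lo, hi = out.min(), out.max()
        out = np.zeros_like(out) if hi - lo < 1e-12 else (out - lo) / (hi - lo)
    return ChannelImage(out, img.space_tag)


def butterworth_descriptor(
    img: ChannelImage,
    band: int,
    spec: ButterworthBankSpec | None = None,
    n_bins: int = DEFAULT_N_BINS,
    binning: NonEquidistantBinning | None = None,
) -> np.ndarray:
    """16-component histogram descriptor of one frequency band.

    If no fitted ``binning`` is supplied, edges are calibrated on the band
    image itself (self-calibration; in the cross-validated pipeline the
    binning is fitted on the training images only).
    """
    band_img = butterworth_band_image(img, band, spec, normalise=True)
    if binning is None:
        binning = fit_nonequidistant_bins(band_img.pixels, n_bins)
    return histogram_descriptor(band_img.pixels, binning)
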