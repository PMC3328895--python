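"""Five single-channel texture descriptor families.

================  ==========================  =================
method id         parameters                  grayscale length
================  ==========================  =================
``butterworth``   band 1..9, n_bins (16)      n_bins
``wavelet``       —                           12
``cooccurrence``  distance d ≥ 1              28
``gmrf``          distance d ≥ 1              4d
``gabor``         n_bins ∈ {3, 5, 7, 9}       16·n_bins
================  ==========================  =================
"""

from __future__ import annotations

import numpy as np

from ..image import ChannelImage
from .butterworth import (
    ButterworthBankSpec,
    butterworth_band_image,
    butterworth_descriptor,
    butterworth_gain,
)
from .gabor import GaborBankSpec, gabor_descriptor, gabor_kernel, gabor_magnitude_responses
from .glcm import (
    GLCMatrix,
    cooccurrence_descriptor,
    glcm,
    haralick_features,
    offsets_for_distance,
    quantise,
)
from .gmrf import DegenerateModelError, GMRFModel, gmrf_descriptor, gmrf_directional_variances, gmrf_fit
from .histogram import NonEquidistantBinning, fit_nonequidistant_bins, histogram_descriptor
from .wavelet import haar_pyramid, wavelet_descriptor

METHODS = ("butterworth", "wavelet", "cooccurrence", "gmrf", "gabor")

__all__ = [
    "METHODS",
    "ButterworthBankSpec", "butterworth_band_image", "butterworth_descriptor",
    "butterworth_gain",
    "GaborBankSpec", "gabor_descriptor", "gabor_kernel", "gabor_magnitude_responses",
    "GLCMatrix", "cooccurrence_descriptor", "glcm", "haralick_features",
    "offsets_for_distance", "quantise",
    "DegenerateModelError", "GMRFModel", "gmrf_descriptor",
    "gmrf_directional_variances", "gmrf_fit",
    "NonEquidistantBinning", "fit_nonequidistant_bins", "histogram_descriptor",
    "haar_pyramid", "wavelet_descriptor",
    "compute_descriptor", "descriptor_length",
]


def compute_descriptor(channel: ChannelImage, method: str, **params) -> np.ndarray:
    """Dispatch a single-channel image to the named descriptor family."""
    if method == "butterworth":
        return butterworth_descriptor(channel, **params)
    if method == "wavelet":
        return wavelet_descriptor(channel, **params)
    if method == "cooccurrence":
        return cooccurrence_descriptor(channel, **params)
    if method == "gmrf":
        return gmrf_descriptor(channel, **params)
    if method == "gabor":
        return gabor_descriptor(channel, **params)
    raise ValueError(f"unknown texture method {method!r}")


def descriptor_length(method: str, **params) -> int:
    """Expected grayscale descriptor length for a method/parameter pair."""
    if method == "butterworth":
        return params.get("n_bins", 16)
    if method == "wavelet":
        return 12
    if method == "cooccurrence":
        return 28
    if method == "gmrf":
        return 4 * params["d"]
    if method == "gabor":
        return 16 * params["n_bins"]
    raise ValueError(f"unknown texture method {method!r}")
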