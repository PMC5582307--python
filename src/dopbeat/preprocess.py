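"""Background-noise removal via Haar-wavelet thresholding.

Raw Doppler audio carries broadband electronic and tissue noise on top
of the cardiac bursts.  Before decomposition the record is denoised
with a 15-level Haar discrete wavelet transform: every detail band is
hard-thresholded at the universal level ``sigma * sqrt(2 ln N)``.  Hard
(keep-or-kill) thresholding is used because soft shrinkage biases every
surviving burst coefficient toward zero and measurably distorts the
waveform the detector depends on; hard thresholding leaves detected
bursts untouched.

The noise scale sigma is estimated from a low quantile of the finest
detail band: burst transients contaminate the upper half of that band's
coefficient distribution (the usual median/0.6745 rule overestimates
sigma by ~2x on clean records), while the 20th percentile is determined
by the noise floor alone.
"""

from __future__ import annotations

import logging

import numpy as np
import pywt
from scipy.stats import norm

from .core import DopbeatError, SampledSignal

logger = logging.getLogger(__name__)

DEFAULT_LEVELS = 15
_SIGMA_QUANTILE = 0.2


def denoise_wavelet(x: SampledSignal, levels: int = DEFAULT_LEVELS) -> SampledSignal:
    """Wavelet-threshold a signal, preserving length and sampling rate.

    Parameters
    ----------
    x : SampledSignal
        Finite input signal.
    levels : int
        Decomposition depth.  If the signal is shorter than ``2**levels``
        the depth is reduced to the maximum feasible value and a warning
        is logged.

    Returns
    -------
    SampledSignal
        Same length and rate; output energy never exceeds input energy
        (thresholding only removes coefficients).
    """
    data = x.samples
    max_level = pywt.dwt_max_level(data.size, pywt.Wavelet("haar").dec_len)
    if levels > max_level:
        logger.warning(
            "signal of length %d supports only %d Haar levels; reducing from %d",
            data.size, max_level, levels,
        )
        levels = max_level
    if levels < 1:
        raise DopbeatError("signal too short for wavelet denoising")

    coeffs = pywt.wavedec(data, "haar", level=levels, mode="symmetric")
    finest = np.abs(coeffs[-1])
    sigma = (
        float(np.quantile(finest, _SIGMA_QUANTILE)) / norm.ppf(0.5 + _SIGMA_QUANTILE / 2)
        if finest.size
        else 0.0
    )
    threshold = sigma * np.sqrt(2.0 * np.log(data.size))

    out = [coeffs[0]]
    if threshold > 0.0:
        out.extend(pywt.threshold(c, threshold, mode="hard") for c in coeffs[1:])
    else:
        out.extend(coeffs[1:])
    rec = pywt.waverec(out, "haar", mode="symmetric")[: data.size]
    return x.with_samples(rec, label=(x.label + " [denoised]").strip())
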