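"""Wavelet de-noising: out-of-band zeroing plus hard thresholding.

The record is decomposed with a multi-level DWT (db5, periodized) deep
enough for the coarsest band to fall below the low cut-off.  Detail levels
whose dyadic band lies predominantly outside the 30 Hz–8 kHz EMG window
are zeroed outright (as is the final approximation when its band sits
below the low cut-off); the surviving detail coefficients are
hard-thresholded at the universal threshold T = σ̂·sqrt(2·ln N) with the
noise scale σ̂ estimated from the finest detail level by the robust
median rule.  An optional second-order IIR notch removes residual
power-line interference.
"""

from __future__ import annotations

import math

import numpy as np
import pywt
from scipy.signal import filtfilt, iirnotch

from .io import EMGRecord


def _band_zero_mask(fs: float, n_levels: int, low_hz: float, high_hz: float) -> list[bool]:
    """Which detail levels (1 = finest .. n_levels = coarsest) to zero.

    Level j covers the dyadic band [fs/2^(j+1), fs/2^j].  The level is
    zeroed when the center of that band falls outside [low_hz, high_hz],
    i.e. when the majority of the band is out-of-band; a level merely
    straddling a cut-off edge with most of its energy in-band is kept.
    """
    zero = []
    for j in range(1, n_levels + 1):
        hi = fs / 2.0**j
        center = 0.75 * hi
        zero.append(not (low_hz <= center <= high_hz))
    return zero


def denoise(
    record: EMGRecord,
    wavelet_name: str = "db5",
    low_hz: float = 30.0,
    high_hz: float = 8000.0,
    notch_hz: float | None = None,
    hard_threshold: bool = True,
) -> EMGRecord:
    """De-noise an EMG record; returns a new record of the same length.

    Parameters
    ----------
    record : EMGRecord
        Input signal.
    wavelet_name : str
        Wavelet base; db5 by default, matching the feature-extraction
        wavelet so the de-noised signal and the features live in a
        coherent basis.
    low_hz, high_hz : float
        Pass window; sub-bands predominantly outside it are zeroed.
    notch_hz : float, optional
        Power-line notch frequency (Q = 30), applied after reconstruction.
    hard_threshold : bool
        Apply the universal hard threshold to retained detail levels.
        Disable to get the pure band-zeroing projection (idempotent).
    """
    x = record.samples
    fs = record.fs
    if high_hz >= fs / 2:
        raise ValueError("high_hz must be below the Nyquist frequency")
    wavelet = pywt.Wavelet(wavelet_name)
    if len(x) < 2 * wavelet.dec_len:
        raise ValueError("record too short for one DWT level")

    # depth such that the approximation band [0, fs/2^L] falls below low_hz
    want = math.ceil(math.log2(fs / low_hz))
    max_level = pywt.dwt_max_level(len(x), wavelet.dec_len)
    level = min(want, max_level)

    coeffs = pywt.wavedec(x, wavelet, mode="periodization", level=level)
    # coeffs = [cA_L, cD_L, ..., cD_1]; finest detail level is coeffs[-1]
    zero = _band_zero_mask(fs, level, low_hz, high_hz)

    if hard_threshold:
        d1 = coeffs[-1]
        sigma = float(np.median(np.abs(d1))) / 0.6745 if d1.size else 0.0
        thr = sigma * math.sqrt(2.0 * math.log(max(len(x), 2)))
    else:
        thr = 0.0

    for j in range(1, level + 1):  # j = 1 finest
        c = coeffs[-j]
        if zero[j - 1]:
            coeffs[-j] = np.zeros_like(c)
        elif thr > 0:
            coeffs[-j] = np.where(np.abs(c) > thr, c, 0.0)
    if fs / 2.0**level <= low_hz:
        coeffs[0] = np.zeros_like(coeffs[0])

    y = pywt.waverec(coeffs, wavelet, mode="periodization")[: len(x)]
    if notch_hz is not None:
        b, a = iirnotch(notch_hz, Q=30.0, fs=fs)
        y = filtfilt(b, a, y)
    return EMGRecord(y, fs)
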