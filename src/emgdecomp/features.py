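"""Peak alignment, wavelet-domain features, and the normalized distance.

Isolated MUAP segments are aligned with their main peak — positive or
negative — at the center of a shared power-of-two buffer, zero padded on
both sides.  Features are the level 3–6 detail coefficients of a 6-level
db5 DWT of the aligned waveform; baseline drift stays in the discarded
approximation band and high-frequency noise in the discarded fine levels.
The dissimilarity between two feature vectors s1, s2 is the variance of
their error signal normalized by the sum of their mean-square amplitudes:

    d(s1, s2) = (E[e²] − E[e]²) / (E[s1²] + E[s2²]),   e = s1 − s2,

a scale-invariant measure that is zero for identical shapes (and for
shapes differing only by a constant offset).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt

from .segment import Segment

DWT_LEVELS = 6
FEATURE_LEVELS = (3, 4, 5, 6)
_MIN_ALIGN_LEN = 2**DWT_LEVELS


@dataclass
class AlignedSegment:
    """A fixed-length, peak-centered copy of a segment's samples."""

    samples: np.ndarray
    source: Segment | None = None

    @property
    def peak_at_center(self) -> bool:
        return int(np.argmax(np.abs(self.samples))) == len(self.samples) // 2


def align(segments: list) -> list[AlignedSegment]:
    """Center each segment's main |peak| in a shared power-of-two buffer.

    ``segments`` may be Segment objects or raw sample arrays.  The buffer
    length L is the smallest power of two that is at least the longest
    segment length (and at least 64 so a 6-level DWT is well defined).
    Samples that would fall outside the buffer when an extreme,
    edge-peaked segment is centered are clipped.
    """
    if not segments:
        return []
    arrays = [
        np.asarray(s.samples if isinstance(s, Segment) else s, dtype=np.float64)
        for s in segments
    ]
    sources = [s if isinstance(s, Segment) else None for s in segments]
    longest = max(len(a) for a in arrays)
    L = _MIN_ALIGN_LEN
    while L < longest:
        L *= 2
    out = []
    for arr, src in zip(arrays, sources):
        buf = np.zeros(L)
        peak = int(np.argmax(np.abs(arr)))
        start = L // 2 - peak
        lo = max(0, start)
        hi = min(L, start + len(arr))
        buf[lo:hi] = arr[lo - start : hi - start]
        out.append(AlignedSegment(buf, src))
    return out


def extract_features(aligned: AlignedSegment | np.ndarray, wavelet_name: str = "db5") -> np.ndarray:
    """Concatenated detail coefficients of DWT levels 3–6."""
    x = aligned.samples if isinstance(aligned, AlignedSegment) else np.asarray(aligned)
    if len(x) < _MIN_ALIGN_LEN:
        raise ValueError(f"aligned length {len(x)} too short for a {DWT_LEVELS}-level DWT")
    with warnings.catch_warnings():
        # a fixed 6-level decomposition of a short aligned buffer trips
        # pywt's boundary-effect warning; the periodized transform is exact
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(x, wavelet_name, mode="periodization", level=DWT_LEVELS)
    # coeffs = [cA6, cD6, cD5, cD4, cD3, cD2, cD1]
    details = {DWT_LEVELS - i + 1: c for i, c in enumerate(coeffs[1:], start=1)}
    return np.concatenate([details[lv] for lv in FEATURE_LEVELS])


def feature_matrix(aligned: list, wavelet_name: str = "db5") -> np.ndarray:
    """Stack feature vectors of a batch of aligned segments, row-wise."""
    return np.vstack([extract_features(a, wavelet_name) for a in aligned])


def distance(f1: np.ndarray, f2: np.ndarray) -> float:
    """Error-variance distance normalized by the summed mean squares."""
    f1 = np.asarray(f1, dtype=np.float64)
    f2 = np.asarray(f2, dtype=np.float64)
    if f1.shape != f2.shape:
        raise ValueError("feature vectors must have equal dimension")
    den = float(np.mean(f1 * f1) + np.mean(f2 * f2))
    if den == 0.0:
        raise ValueError("distance undefined for two zero vectors")
    e = f1 - f2
    num = float(np.mean(e * e) - np.mean(e) ** 2)
    return max(num, 0.0) / den


def distance_matrix(features: np.ndarray) -> np.ndarray:
    """Symmetric matrix of pairwise distances, zero diagonal.

    Vectorized: with G = F·Fᵀ/p, m the row means and S the row mean
    squares, E[e²] = S_i + S_j − 2G_ij and E[e] = m_i − m_j.
    """
    F = np.asarray(features, dtype=np.float64)
    if F.ndim != 2 or F.shape[0] < 2:
        raise ValueError("need at least two feature vectors")
    p = F.shape[1]
    S = np.mean(F * F, axis=1)
    m = np.mean(F, axis=1)
    den = S[:, None] + S[None, :]
    if np.any(den == 0.0):
        raise ValueError("distance undefined for two zero vectors")
    G = (F @ F.T) / p
    num = S[:, None] + S[None, :] - 2.0 * G - (m[:, None] - m[None, :]) ** 2
    D = np.maximum(num, 0.0) / den
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2.0
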