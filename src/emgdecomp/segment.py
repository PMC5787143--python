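"""MUAP segment detection by resting-epoch recognition.

A sliding detection window (default 1.25 ms) estimates the noise power as
the minimum windowed mean-square of the raw signal; the amplitude threshold
is ``k`` times the noise RMS.  Resting epochs are maximal runs of at least
one window length whose absolute amplitude stays below the threshold; the
spans between them that contain at least one supra-threshold sample are the
active MUAP segments.  Valid segments are then split into isolated and
superimposed sets by their phase count against a phase template (4 phases
for healthy muscle, 6 after neurogenic remodeling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: label for segments not (yet) assigned a kind
KIND_UNSET = "unset"
KIND_ISOLATED = "isolated"
KIND_SUPERIMPOSED = "superimposed"
KIND_INVALID = "invalid"

MIN_VALID_DURATION_MS = 1.5

#: the detection threshold never drops below this fraction of the signal
#: peak: on (near-)noise-free records the windowed noise estimate goes to
#: zero while de-noising leaves sub-µV baseline wander everywhere, and a
#: floor well under any MUAP's main lobes keeps low-level waveform tails
#: from chaining neighbouring discharges into one long segment
THRESHOLD_FLOOR_FRAC = 0.03


@dataclass
class NoiseEstimate:
    """Windowed noise-power estimate.

    ``sigma_n_sq`` is the minimum over all window positions of the windowed
    mean-square amplitude (µV²); ``window_len`` is the window length L_R in
    samples.
    """

    sigma_n_sq: float
    window_len: int
    per_window: np.ndarray

    @property
    def sigma_n(self) -> float:
        """Noise RMS (µV)."""
        return float(np.sqrt(self.sigma_n_sq))


@dataclass
class Segment:
    """A contiguous active span of the record.

    ``start`` (inclusive) and ``end`` (exclusive) are 0-based sample
    indices into the record the segment was detected on.
    """

    start: int
    end: int
    samples: np.ndarray
    fs: float
    kind: str = KIND_UNSET
    n_phases: int | None = None

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValueError("segment must contain at least one sample")

    @property
    def onset_s(self) -> float:
        return self.start / self.fs

    @property
    def duration_ms(self) -> float:
        return (self.end - self.start) / self.fs * 1000.0


def estimate_noise_power(
    signal: np.ndarray, fs: float, window_ms: float = 1.25
) -> NoiseEstimate:
    """Estimate the noise power σn² of a signal.

    σi² is the mean of squared samples in the window starting at sample i
    (step one sample); σn² is the minimum over all i.  The estimate is
    intended to run on the original, pre-de-noising signal so that the
    quiet epochs reflect the true noise floor.
    """
    signal = np.asarray(signal, dtype=np.float64)
    if signal.size == 0:
        raise ValueError("cannot estimate noise power of an empty signal")
    window_len = max(1, int(round(window_ms * 1e-3 * fs)))
    if signal.size < window_len:
        raise ValueError(
            f"signal length {signal.size} shorter than one window ({window_len})"
        )
    sq = signal * signal
    csum = np.concatenate(([0.0], np.cumsum(sq)))
    per_window = (csum[window_len:] - csum[:-window_len]) / window_len
    # cumulative sums can go infinitesimally negative on cancellation
    per_window = np.maximum(per_window, 0.0)
    return NoiseEstimate(float(per_window.min()), window_len, per_window)


def _active_mask(signal: np.ndarray, threshold: float) -> np.ndarray:
    if threshold > 0:
        return np.abs(signal) >= threshold
    return np.abs(signal) > 0


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end) runs of True in a boolean mask."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def detect_segments(
    signal: np.ndarray,
    fs: float,
    k: float = 6.0,
    window_ms: float = 1.25,
    expand_ms: float = 0.2,
    noise_power: float | None = None,
) -> list[Segment]:
    """Detect all active MUAP segments of a record.

    Parameters
    ----------
    signal : ndarray
        The (typically de-noised) signal to segment, in µV.
    fs : float
        Sampling rate in Hz.
    k : float
        Threshold multiplier; the amplitude threshold is ``k`` times the
        noise RMS.  Typical values 5–8, larger at higher force levels.
    window_ms : float
        Detection-window (resting-epoch) length, default 1.25 ms.
    expand_ms : float
        Expansion applied to each segment boundary so that the full MUAP
        waveform, including its low-amplitude onset, is preserved.
    noise_power : float, optional
        Externally estimated σn² (µV²), e.g. computed on the raw record
        before de-noising.  When omitted it is estimated from ``signal``.

    Returns
    -------
    list of Segment with ``kind`` unset.
    """
    signal = np.asarray(signal, dtype=np.float64)
    if noise_power is None:
        noise_power = estimate_noise_power(signal, fs, window_ms).sigma_n_sq
    if noise_power < 0:
        raise ValueError("noise power must be non-negative")
    window_len = max(1, int(round(window_ms * 1e-3 * fs)))
    threshold = k * float(np.sqrt(noise_power))
    if signal.size:
        threshold = max(threshold, THRESHOLD_FLOOR_FRAC * float(np.abs(signal).max()))

    active = _active_mask(signal, threshold)
    if not active.any():
        return []

    resting = [
        (s, e) for (s, e) in _runs(~active) if e - s >= window_len
    ]
    # spans between consecutive resting epochs (record edges act as
    # boundaries too, so leading/trailing activity is not lost)
    boundaries = [(0, 0)] + resting + [(signal.size, signal.size)]
    if not resting and active.any():
        raise ValueError(
            "no resting epoch found (signal saturated); try a larger k"
        )

    expand = int(round(expand_ms * 1e-3 * fs))
    cores: list[tuple[int, int]] = []
    for (_, gap_start), (gap_end, _) in zip(boundaries[:-1], boundaries[1:]):
        if gap_end <= gap_start:
            continue
        if active[gap_start:gap_end].any():
            cores.append((gap_start, gap_end))

    segments: list[Segment] = []
    for idx, (cs, ce) in enumerate(cores):
        start = max(0, cs - expand)
        end = min(signal.size, ce + expand)
        # truncate at the midpoint of the shared resting gap so expanded
        # neighbours never overlap
        if idx > 0:
            prev_ce = cores[idx - 1][1]
            start = max(start, (prev_ce + cs) // 2)
        if idx < len(cores) - 1:
            next_cs = cores[idx + 1][0]
            end = min(end, (ce + next_cs + 1) // 2)
        segments.append(Segment(start, end, signal[start:end].copy(), fs))
    return segments


def count_phases(samples: np.ndarray, threshold: float) -> int:
    """Count MUAP phases: baseline-crossing excursions exceeding ``threshold``.

    The baseline is the sample median.  A phase is a maximal interval
    between consecutive baseline crossings whose extremum magnitude
    reaches the detection threshold — the clinical phase-counting
    convention.
    """
    x = np.asarray(samples, dtype=np.float64)
    if x.size == 0:
        return 0
    x = x - np.median(x)
    pos = x >= 0
    # boundaries where the sign flips
    flips = np.flatnonzero(pos[1:] != pos[:-1]) + 1
    edges = np.concatenate(([0], flips, [x.size]))
    n = 0
    for a, b in zip(edges[:-1], edges[1:]):
        if np.abs(x[a:b]).max() >= threshold and threshold > 0:
            n += 1
        elif threshold <= 0 and np.abs(x[a:b]).max() > 0:
            n += 1
    return n


def classify_segments(
    segments: list[Segment],
    phase_template: int = 4,
    threshold: float | None = None,
    phase_rel_floor: float = 0.0,
) -> tuple[list[Segment], list[Segment], list[Segment]]:
    """Partition detected segments into (isolated, superimposed, invalid).

    A segment is invalid if it has at most one phase or is shorter than
    1.5 ms; a valid segment with more phases than the phase template is
    flagged as containing superimposed MUAPs.  ``threshold`` is the
    amplitude detection threshold used for phase counting; it must be the
    same T = k·σn the segments were detected with.  ``phase_rel_floor``
    additionally requires a phase deflection to reach that fraction of
    the segment's own peak — the clinical convention that a phase is a
    deflection commensurate with the main spike, which keeps low-level
    tail ripple of large MUAPs from inflating the count.
    """
    if threshold is None:
        raise ValueError("phase counting requires the detection threshold")
    isolated, superimposed, invalid = [], [], []
    for seg in segments:
        t_seg = max(threshold, phase_rel_floor * float(np.abs(seg.samples).max()))
        seg.n_phases = count_phases(seg.samples, t_seg)
        if seg.n_phases <= 1 or seg.duration_ms < MIN_VALID_DURATION_MS:
            seg.kind = KIND_INVALID
            invalid.append(seg)
        elif seg.n_phases > phase_template:
            seg.kind = KIND_SUPERIMPOSED
            superimposed.append(seg)
        else:
            seg.kind = KIND_ISOLATED
            isolated.append(seg)
    return isolated, superimposed, invalid


def firing_onsets(segments: list[Segment]) -> np.ndarray:
    """Onset times (s) of valid segments, as a 1-D array."""
    return np.array(
        [s.onset_s for s in segments if s.kind in (KIND_ISOLATED, KIND_SUPERIMPOSED)]
    )
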