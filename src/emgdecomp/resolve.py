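"""Superposition resolution: pseudo-correlation peel-off.

The pseudo-correlation (PsC) between a template x (support m) and a
window of the superimposed segment y starting at offset k is

    PsC_k = Σ_j ( x_j·y_{k+j} − |x_j − y_{k+j}|·max{|x_j|, |y_{k+j}|} )
            ─────────────────────────────────────────────────────────
                      Σ_j ( max{|x_j|, |y_{k+j}|} )²

PsC equals 1 only on an exact match and, unlike plain cross-correlation,
actively penalizes pointwise amplitude discrepancy, so it can be scanned
over all offsets without prior alignment.  Peel-off repeatedly subtracts
the best-scoring template at its best offset, stopping on a non-positive
score, a residual-energy increase, or after three templates — the most
MUAPs a superimposed segment is assumed to contain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

COMPLETE = "complete"
PARTIAL = "partial"


@dataclass
class PscMatch:
    mu_id: int
    offset: int  # index, in unpadded segment coordinates, of the template's first sample
    psc: float


@dataclass
class Resolution:
    matches: list[PscMatch]
    residual: np.ndarray
    status: str


def trim_support(waveform: np.ndarray, rel_threshold: float = 0.02) -> tuple[np.ndarray, int]:
    """Strip near-zero padding from a template.

    Returns the contiguous span where |x| reaches ``rel_threshold`` of the
    peak, and the start index of that span in the original waveform.
    Mean templates of aligned segments carry long zero flanks which would
    otherwise dominate the PsC denominator.
    """
    x = np.asarray(waveform, dtype=np.float64)
    peak = np.abs(x).max()
    if peak <= 0:
        raise ValueError("cannot trim an all-zero template")
    above = np.flatnonzero(np.abs(x) >= rel_threshold * peak)
    lo, hi = int(above[0]), int(above[-1]) + 1
    return x[lo:hi].copy(), lo


def _psc_terms(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    mx = np.maximum(np.abs(x), np.abs(w))
    num = float(np.sum(x * w - np.abs(x - w) * mx))
    den = float(np.sum(mx * mx))
    return num, den


def psc(template: np.ndarray, segment: np.ndarray, k: int) -> float:
    """PsC of ``template`` against the padded segment window at offset k.

    The segment is zero-padded by m−1 samples on each side so that every
    partial-overlap offset k = 0 … n+m−2 is evaluable.  A zero denominator
    (both windows all-zero) yields −inf, never selectable.
    """
    x = np.asarray(template, dtype=np.float64)
    y = np.asarray(segment, dtype=np.float64)
    m = x.size
    if not 0 <= k <= y.size + m - 2:
        raise ValueError(f"offset {k} outside [0, {y.size + m - 2}]")
    ypad = np.concatenate([np.zeros(m - 1), y, np.zeros(m - 1)])
    num, den = _psc_terms(x, ypad[k : k + m])
    return num / den if den > 0 else -np.inf


def psc_scan(template: np.ndarray, segment: np.ndarray, mu_id: int = -1) -> PscMatch:
    """Best PsC over all offsets; ties broken toward the smaller offset.

    The returned ``offset`` is expressed in unpadded segment coordinates
    (it can be negative when the best overlap is partial on the left).
    """
    scores = _psc_all(np.asarray(template, float), np.asarray(segment, float))
    k = int(np.argmax(scores))  # argmax returns the first maximum
    m = len(template)
    return PscMatch(mu_id, k - (m - 1), float(scores[k]))


def _psc_all(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized PsC at every offset of the padded segment."""
    m = x.size
    ypad = np.concatenate([np.zeros(m - 1), y, np.zeros(m - 1)])
    return _psc_windows(x, ypad)


def _psc_windows(x: np.ndarray, buf: np.ndarray) -> np.ndarray:
    """PsC of x against every length-m window of ``buf`` (no extra padding)."""
    m = x.size
    W = np.lib.stride_tricks.sliding_window_view(buf, m)
    mx = np.maximum(np.abs(x)[None, :], np.abs(W))
    num = (x[None, :] * W - np.abs(x[None, :] - W) * mx).sum(axis=1)
    den = (mx * mx).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(den > 0, num / den, -np.inf)
    return scores


def peel_off(
    segment: np.ndarray,
    templates: list[tuple[int, np.ndarray]],
    max_iterations: int = 3,
    energy_tol: float = 0.01,
    first_unconditional: bool = True,
) -> Resolution:
    """Iteratively subtract best-matching templates from a superimposed segment.

    ``templates`` is a list of (mu_id, waveform) pairs; pass
    support-trimmed waveforms (see :func:`trim_support`) so zero flanks do
    not dilute the score.  Each iteration picks the template/offset with
    the highest PsC (ties: larger template energy first, then smaller
    offset) and reverts-and-stops when subtraction fails to strictly
    decrease the residual energy.  The first, top-ranked subtraction is
    attempted even at a non-positive score — in a dense superposition the
    other constituents depress the PsC of the correct template below
    zero, and the energy criterion alone rejects spurious peels — but
    once a MUAP has been peeled a non-positive best score stops the
    process.  Pass ``first_unconditional=False`` when the segment is not
    presumed to contain a MUAP at all (e.g. a leftover after template
    subtraction), so that every peel needs a positive score.  The
    resolution is ``complete`` when the final residual retains at most
    ``energy_tol`` of the original segment energy.
    """
    if not templates:
        raise ValueError("peel_off requires at least one template")
    y = np.asarray(segment, dtype=np.float64)
    pad = max(len(w) for _, w in templates) - 1
    residual = np.concatenate([np.zeros(pad), y, np.zeros(pad)])
    e0 = float(np.sum(y * y))
    energies = [float(np.sum(w * w)) for _, w in templates]

    matches: list[PscMatch] = []
    for _ in range(max_iterations):
        best = None  # (score, energy, -start, template_idx)
        for t_idx, (mu_id, w) in enumerate(templates):
            # scan the whole padded residual so flank residue left by a
            # previous partial-overlap subtraction is still visible
            scores = _psc_windows(w, residual)
            k = int(np.argmax(scores))
            cand = (float(scores[k]), energies[t_idx], -k, t_idx)
            if best is None or cand > best:
                best = cand
        score, _, neg_k, t_idx = best
        if (matches or not first_unconditional) and not score > 0:
            break
        lo = -neg_k  # template start within the padded buffer
        k_seg = lo - pad  # ... in unpadded segment coordinates
        mu_id, w = templates[t_idx]
        m = len(w)
        before = float(np.sum(residual * residual))
        trial = residual.copy()
        trial[lo : lo + m] -= w
        after = float(np.sum(trial * trial))
        if after >= before:
            break
        residual = trial
        matches.append(PscMatch(mu_id, k_seg, score))

    # one coordinate-descent refinement pass: the first subtraction's
    # offset is biased by interference from the not-yet-peeled
    # constituents, so revisit each match against the final residual
    if len(matches) > 1:
        by_id = dict(templates)
        for match in matches:
            w = by_id[match.mu_id]
            m = len(w)
            lo = pad + match.offset
            residual[lo : lo + m] += w
            scores = _psc_windows(w, residual)
            k = int(np.argmax(scores))
            before = float(np.sum(residual * residual))
            trial = residual.copy()
            trial[k : k + m] -= w
            if float(np.sum(trial * trial)) < before:
                residual = trial
                match.offset = k - pad
                match.psc = float(scores[k])
            else:  # keep the original placement
                residual[lo : lo + m] -= w

    final = residual[pad : len(residual) - pad] if pad else residual
    e_res = float(np.sum(residual * residual))
    status = COMPLETE if e_res <= energy_tol * e0 and matches else PARTIAL
    return Resolution(matches, final, status)
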