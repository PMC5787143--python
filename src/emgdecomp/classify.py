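"""Supervised minimum-distance classification of pooled MUAPs.

Unclassified isolated MUAPs are assigned to the nearest refined class in
Euclidean feature space when that distance falls below an inter-class
threshold — by default the lowest per-class mean of the inter-class
template distances.  Each accepted member adapts the class's feature and
waveform templates by weighted averaging, tracking the slow waveform
drift caused by electrode movement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cluster import UNASSIGNED, ClassTemplates


@dataclass
class Assignment:
    segment_index: int
    class_id: int  # UNASSIGNED when no class is close enough
    distance: float


def interclass_threshold(
    class_feature_templates: np.ndarray, mode: str = "per_class_mean"
) -> float:
    """Assignment threshold from the inter-class template distances.

    ``per_class_mean``: for each class, the mean Euclidean distance from
    its template to every other template; the threshold is the minimum of
    these means.  ``global_min``: the smallest pairwise template distance.
    """
    T = np.asarray(class_feature_templates, dtype=np.float64)
    n = T.shape[0]
    if n < 2:
        raise ValueError("inter-class threshold needs at least two classes")
    diff = T[:, None, :] - T[None, :, :]
    d = np.sqrt((diff * diff).sum(axis=2))
    off = d + np.diag(np.full(n, np.nan))
    if mode == "per_class_mean":
        return float(np.nanmin(np.nanmean(off, axis=1)))
    if mode == "global_min":
        return float(np.nanmin(off))
    raise ValueError(f"unknown threshold mode: {mode}")


def single_class_threshold(member_features: np.ndarray, template: np.ndarray) -> float:
    """Fallback when only one class survived refinement.

    Three times the maximum member-to-template distance: generous enough
    to keep accepting the class's own discharges, tight enough to reject
    foreign shapes.
    """
    diff = np.asarray(member_features) - np.asarray(template)
    return 3.0 * float(np.sqrt((diff * diff).sum(axis=1)).max())


def assign(
    unassigned_features: np.ndarray,
    templates: ClassTemplates,
    threshold: float,
    adapt_weight: float = 0.125,
    unassigned_waveforms: np.ndarray | None = None,
    order: np.ndarray | None = None,
) -> tuple[list[Assignment], ClassTemplates]:
    """Assign pooled candidates to their nearest class under the threshold.

    Candidates are processed in ``order`` (chronological by default, i.e.
    the given row order) because template adaptation makes the outcome
    order-dependent for ``adapt_weight`` > 0.  On each accepted candidate
    the class templates move to (1−α)·template + α·member in both the
    feature and the waveform domain.
    """
    if not 0 < adapt_weight < 1:
        raise ValueError("adapt_weight must be in (0, 1)")
    F = np.atleast_2d(np.asarray(unassigned_features, dtype=np.float64))
    feat = templates.features.copy()
    wave = templates.waveforms.copy()
    n_candidates = F.shape[0] if F.size else 0
    order = np.arange(n_candidates) if order is None else np.asarray(order)

    assignments: list[Assignment] = []
    for idx in order:
        diffs = feat - F[idx]
        d = np.sqrt((diffs * diffs).sum(axis=1))
        best = int(np.argmin(d))
        if d[best] < threshold:
            cid = templates.class_ids[best]
            feat[best] = (1 - adapt_weight) * feat[best] + adapt_weight * F[idx]
            if unassigned_waveforms is not None:
                wave[best] = (
                    (1 - adapt_weight) * wave[best]
                    + adapt_weight * unassigned_waveforms[idx]
                )
            assignments.append(Assignment(int(idx), cid, float(d[best])))
        else:
            assignments.append(Assignment(int(idx), UNASSIGNED, float(d[best])))
    updated = ClassTemplates(list(templates.class_ids), wave, feat)
    return assignments, updated
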