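"""JSON round-tripping of ground truth, segments and decomposition results."""

from __future__ import annotations

import numpy as np

from .pipeline import DecompositionResult, MUAPTrain
from .segment import Segment
from .simulate import FiringPattern, GroundTruth, MUAPTemplate


def truth_to_dict(truth: GroundTruth, fs: float) -> dict:
    def mu(t: MUAPTemplate, p: FiringPattern) -> dict:
        return {
            "mu_id": t.mu_id,
            "waveform_uv": t.waveform.tolist(),
            "n_phases": t.n_phases,
            "firing_times_s": p.times.tolist(),
            "firing_samples": [int(round(x * fs)) for x in p.times],
            "mean_ipi_s": p.mean_ipi,
            "ipi_cv": p.ipi_cv,
            "random_rate_hz": p.random_rate,
        }

    return {
        "fs": fs,
        "snr_db": truth.snr_db,
        "seed": truth.seed,
        "mus": [mu(t, truth.pattern_for(t.mu_id)) for t in truth.templates],
        "background_mus": [
            mu(t, p) for t, p in zip(truth.background_templates, truth.background_patterns)
        ],
    }


def truth_from_dict(d: dict) -> tuple[GroundTruth, float]:
    fs = float(d["fs"])
    templates, patterns = [], []
    for mu in d["mus"]:
        templates.append(
            MUAPTemplate(mu["mu_id"], np.asarray(mu["waveform_uv"]), fs, mu["n_phases"])
        )
        patterns.append(
            FiringPattern(
                mu["mu_id"], np.asarray(mu["firing_times_s"]),
                mu["mean_ipi_s"], mu["ipi_cv"], mu["random_rate_hz"],
            )
        )
    return GroundTruth(templates, patterns, d.get("snr_db"), d.get("seed")), fs


def segments_to_list(segments: list[Segment]) -> list[dict]:
    return [
        {
            "start": int(s.start),
            "end": int(s.end),
            "kind": s.kind,
            "n_phases": s.n_phases,
            "onset_s": s.onset_s,
        }
        for s in segments
    ]


def result_to_dict(result: DecompositionResult) -> dict:
    return {
        "fs": result.fs,
        "trains": [
            {
                "mu_id": tr.mu_id,
                "template_uv": tr.template.tolist(),
                "firing_samples": tr.firing_samples.tolist(),
                "firing_times_s": tr.firing_times.tolist(),
            }
            for tr in result.trains
        ],
        "residual_uv": result.residual.tolist(),
        "segments": segments_to_list(result.segments),
        "unassigned": segments_to_list(result.unassigned),
        "counts": result.counts,
    }


def trains_from_dict(d: dict) -> list[MUAPTrain]:
    fs = float(d["fs"])
    return [
        MUAPTrain(
            tr["mu_id"], np.asarray(tr["template_uv"]),
            np.asarray(tr["firing_samples"], dtype=int), fs,
        )
        for tr in d["trains"]
    ]
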