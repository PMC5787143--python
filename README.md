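# emgdecomp

Decomposition of single-channel intramuscular EMG into motor unit action
potential trains (MUAPTs), with a synthetic-signal generator for validation.

Clinical needle EMG records the summed electrical activity of the motor
units (MUs) near the electrode tip. Decomposition reverses that summation:
it finds every motor unit action potential (MUAP) in the interference
signal, groups the MUAPs by their unit of origin, and resolves waveforms in
which two or more units discharged close enough in time to superimpose.
The per-unit templates and firing statistics that come out are what a
neurophysiologist reads when diagnosing neuropathies and myopathies, and
what motor-control studies need from voluntary-contraction recordings.

## Method

The decomposition runs in six stages:

1. **De-noising** — multi-level discrete wavelet transform (db5); detail
   sub-bands lying predominantly outside 30 Hz–8 kHz are zeroed, the rest
   hard-thresholded at the universal threshold T = σ̂·√(2·ln N); optional
   IIR notch for power-line interference.
2. **Segmentation** — the noise power σ²ₙ is the minimum over all
   positions of the windowed mean square σᵢ² = (1/L_R)·Σ s²[k] (1.25 ms
   window, estimated on the raw record); resting epochs are runs of at
   least one window length with |s| < k·σₙ (k ≈ 5–8), and the spans
   between them are the active MUAP segments, expanded by 0.2 ms.
   Segments with ≤ 1 phase or shorter than 1.5 ms are invalid; segments
   with more phases than the phase template (4 for healthy muscle, 6 for
   neurogenic conditions) are flagged as superimposed.
3. **Alignment and features** — isolated MUAPs are centered on their main
   peak (either polarity) in a power-of-two buffer; features are the
   level 3–6 detail coefficients of a 6-level db5 DWT; the dissimilarity
   of two feature vectors is the variance of their difference normalized
   by the sum of their mean squares,
   d(s₁, s₂) = (E[e²] − E²[e]) / (E[s₁²] + E[s₂²]), e = s₁ − s₂.
4. **Clustering** — single-linkage hierarchical clustering via the
   minimum spanning tree: cutting the n−1 largest tree edges yields n
   clusters, independent of presentation order. Refinement deletes
   clusters with fewer than three members and subdivides clusters whose
   internal MST contains a disproportionate gap edge; near-identical
   class templates are merged (lag-corrected).
5. **Supervised classification** — pooled unclassified MUAPs go to the
   nearest class in Euclidean feature space when that distance is below
   the lowest per-class mean of inter-class template distances; accepted
   members adapt the class template by weighted averaging.
6. **Superposition resolution** — pseudo-correlation peel-off. For a
   template x (support m) and segment window y at offset k,

   PsC_k = Σⱼ (xⱼ·y_{k+j} − |xⱼ − y_{k+j}|·max{|xⱼ|, |y_{k+j}|})
           / Σⱼ (max{|xⱼ|, |y_{k+j}|})²,

   which equals 1 only on an exact match and penalizes amplitude
   discrepancy pointwise. The best-scoring template is subtracted at its
   best offset and the process repeats (up to 3 constituents), stopping
   on a residual-energy increase or a non-positive score.

Performance is reported as the detection ratio DR% = 100·NM_detected /
NM_total, the assignment ratio AR% = 100·(1 − NM_unassigned /
NM_detected), and the correct classification rate CCR% = 100·NM_correct /
NM_detected, scored against the simulator's ground truth with ±0.5 ms
firing-time matching.

The simulator composes records from 16-term Hermite–Rodriguez MUAP
waveforms with prescribed phase counts, stationary-renewal firing
(Gaussian inter-pulse intervals, 3 ms refractory floor) plus optional
uniform random discharges, and 100 Hz–10 kHz band-passed Gaussian noise
at an exact SNR.

## Worked example

```sh
$ emgdecomp simulate --duration 5 --n-mus 6 --snr-db 20 \
      --min-feature-distance 0.3 --seed 1 --out signal.csv --truth truth.json
wrote signal.csv: 150000 samples at 30000 Hz, 6 MUs

$ emgdecomp decompose --in signal.csv --out result.json
wrote result.json: 6 trains, NM_detected=318, NM_unassigned=0

$ emgdecomp evaluate --result result.json --truth truth.json
index        value
DR%         100.00
AR%         100.00
CCR%         94.97
counts: total=333 detected=318 unassigned=0 correct=302
```

The 5-s record contains 333 true discharges from 6 motor units at 20 dB
SNR. Every discharge falls inside a detected active segment (DR% = 100),
every detected MUAP is assigned to a train (AR% = 100), and 302 of the
318 detected MUAPs carry the right unit label at the right time within
±0.5 ms (CCR% = 95.0); the remainder are tight near-coincident
superpositions resolved with the wrong constituent or offset. Detected
MUAPs (318) can differ from true discharges (333) because a superimposed
segment counts once until it is resolved into its constituents.

The same workflow is available from Python:

```python
from emgdecomp import generate_recording, decompose, evaluate

record, truth = generate_recording(n_mus=6, snr_db=20.0, seed=1,
                                   min_feature_distance=0.3)
result = decompose(record)
report = evaluate(result, truth)
print(report.dr_pct, report.ar_pct, report.ccr_pct)
```

`emgdecomp benchmark --n-records 30 --seed 1` repeats
simulate → decompose → evaluate over many records and prints the mean and
standard deviation of the three indices.

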