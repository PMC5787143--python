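# Methods

This note records the models behind `emgdecomp`, the parameters that
matter, the numerical choices made where the design was genuinely open,
and what the synthetic benchmark does and does not demonstrate.

## Signal model

A single-channel intramuscular EMG record is modeled as

    s[k] = Σ_u Σ_i  w_u[k − t_{u,i}]  +  n[k]

where `w_u` is the action-potential waveform (template) of motor unit
`u` as seen by the electrode, `t_{u,i}` its discharge (firing) onsets,
and `n` additive noise. Templates are assumed quasi-stationary over the
record (slow drift is tracked by template adaptation; needle movement
that reshapes waveforms mid-record is out of scope). A firing time
always marks the template's **first sample** (onset convention)
throughout the package.

## Synthetic data generator

The generator exists to provide records with known ground truth; every
design choice aims at realistic needle-EMG statistics.

* **Waveforms.** 16-term Hermite–Rodriguez expansions (orthonormal
  Hermite functions under a Gaussian envelope), coefficients standard
  normal with geometric damping (ratio 0.75) so few-lobed shapes
  dominate. Two corrections keep the shapes physiological:
  * the envelope-shaped mean is removed, so the waveform has no net
    area — needle recordings are AC-coupled (instrument band ~2 Hz–10
    kHz) and a MUAP carries essentially no sub-30 Hz energy. Without
    this, the de-noising front end would visibly distort the waveform
    it is asked to preserve;
  * a draw is accepted only if the clinical phase counter reports the
    target phase count at every criterion level between 3% and 10% of
    the peak. Real MUAPs have unambiguous phase counts at the ~20 µV
    deflection criterion; draws with "ghost" lobes at a few percent of
    the peak flip their apparent count with the threshold and are
    rejected. A bounded number of redraws (default 100) guards against
    unreachable parameter combinations; the recording-level generator
    retries with fresh durations/targets when that happens.
* **Defaults** (chosen once as representative of moderate-force
  biceps recordings): 3–8 units, amplitudes uniform 150–600 µV,
  durations 3–6 ms, 2–4 phases (healthy morphology), mean rates 8–15
  pps, Gaussian inter-pulse intervals with CV 0.15 truncated at a 3 ms
  refractory floor, optional Poisson-uniform random discharges,
  duration 5 s at 30 kHz.
* **Noise.** Gaussian white noise band-passed to 100 Hz–10 kHz
  (4th-order Butterworth, zero-phase) and scaled so the clean-to-noise
  power ratio matches the requested SNR exactly. Optional sub-threshold
  "background" units (5–20 µV) emulate distant activity.
* **Distinctness.** For benchmark records the templates are redrawn
  until every pair is at least 0.3 apart in the normalized
  wavelet-feature distance, the condition under which classification is
  well-posed. Note this constrains *feature* distance only: waveform
  correlations up to ~0.9 still occur, which is the main driver of
  residual classification error (below).
* **Edge discharges.** A firing whose template does not fit fully
  inside the record is dropped from both signal and ground truth: a
  truncated edge waveform carries no recoverable information and would
  make detection-coverage scores unattainable by construction.

## De-noising

Wavelet: db5, matching the feature wavelet, periodized so the transform
is orthogonal (band zeroing is then an exact projection, hence
idempotent). Depth: enough levels for the coarsest band to fall below
30 Hz (10 levels at 30 kHz). A detail level is zeroed when the center
of its dyadic band [fs/2^(j+1), fs/2^j] lies outside 30 Hz–8 kHz —
i.e. when the majority of the band is out-of-band. (Full-band
containment would keep the finest level at 30 kHz, whose band 7.5–15
kHz is dominated by out-of-band noise; requiring containment in the
pass window would zero the straddling level near 30 Hz that carries
in-band energy. The center rule resolves both.) Retained details are
hard-thresholded at the universal threshold with the robust σ̂ =
median|d₁|/0.6745 from the finest level. The exact threshold estimator
is an open choice; the universal threshold is the standard default, and
its known artifacts (occasional surviving noise spikes, small
reconstruction ripple at waveform onsets) are handled downstream by the
phase-counting floor rather than by a more exotic estimator.

## Segmentation and phase counting

* Noise power is estimated on the **raw** record (quiet epochs reflect
  the true floor); segmentation runs on the de-noised record with the
  same threshold T = k·σₙ. The printed description of the threshold
  mixes an amplitude with a power; `k` times the noise RMS is the
  dimensionally consistent reading used here. The minimum-over-windows
  estimator deliberately under-estimates the Gaussian σ (it takes the
  quietest 1.25 ms of the record); `k` in 5–8 compensates.
* A relative floor of 3% of the signal peak keeps the threshold
  meaningful on (near-)noise-free records, where σₙ → 0 while
  de-noising leaves sub-µV baseline wander, and prevents low-amplitude
  waveform tails from chaining neighbouring discharges into one long
  segment.
* Phases are maximal intervals between baseline crossings (baseline =
  segment median) whose extremum reaches the counting threshold — the
  clinical convention. The counting threshold is max(T, 5% of the
  segment's own peak): an absolute-only criterion lets the tail ripple
  of large MUAPs (and surviving de-noising spikes) masquerade as
  phases, which would misroute isolated MUAPs into the superimposed
  set. The generator's 3–10% stability band brackets this operating
  point with margin for noise.
* If the final unassigned fraction exceeds 2%, the phase template is
  raised one step (at most two) and the segment classification re-run —
  the automated version of the practice of fine-tuning the phasic
  threshold when isolated MUAPs are found in the overlapped set (e.g. a
  pentaphasic template on nominally healthy data). The run with the
  fewest unassigned MUAPs is kept. The criterion uses no ground truth.

## Clustering, refinement, classification

* Initial cluster count: ⌊n/10⌋ clipped to [8, 12] (capped at n) — more
  clusters than expected units, because over-segmentation is repairable
  (see merging) while under-segmentation blends units.
* MST by Kruskal with edges sorted by (weight, i, j): deterministic
  tie-breaks, order-independent partitions. Cutting the n−1 largest
  tree edges is exactly the single-linkage cut (verified against a
  brute-force agglomerative oracle in the tests).
* Refinement: classes need ≥ 3 members; a class is split when its
  internal MST's largest edge exceeds 3× the mean of its other edges
  and both sides keep ≥ 3 members (a single-linkage-native gap test,
  standing in for visual inspection of cluster overlays).
* **Duplicate-class merging.** Peak alignment picks the largest |lobe|;
  when a unit has two lobes of comparable size, noise flips the choice
  between discharges and the unit appears as two time-shifted classes.
  Classes whose templates correlate at ≥ 0.95 under the optimal lag are
  merged, with the smaller class's onsets shifted by that lag. The 0.95
  bar sits above the waveform correlation that distinct same-muscle
  units typically reach.
* Classification threshold: the lowest per-class mean of inter-class
  template distances (a global-minimum variant is available); single
  surviving class falls back to 3× its maximum member distance.
  Adaptation weight α = 0.125 (dyadic, light tracking); candidates are
  processed chronologically so adaptation is reproducible.

## Superposition resolution

Templates are support-trimmed (2% of peak) before scanning — the zero
flanks of an aligned-buffer template would otherwise dominate the PsC
denominator. All partial-overlap offsets are scanned via zero-padding.

Stopping logic: subtraction must strictly decrease residual energy
(always), and after the first accepted peel a non-positive best score
stops the process. The first, top-ranked subtraction is attempted even
at a non-positive score: in a dense multi-unit superposition the other
constituents depress the PsC of the *correct* template below zero, and
the energy criterion alone is a reliable gate (pure-noise segments are
rejected ≥ 95% of the time in the control test). Ties: higher template
energy first, then the smaller offset. At most 3 constituents per
segment. A final coordinate-descent pass revisits each accepted match
against the finished residual, since the first offset estimate is
biased by interference from not-yet-peeled constituents.

Two auxiliary passes close the gaps left by imperfect phase routing,
both ground-truth-free:

* **Rescue:** segments rejected by the classifier get a peel-off pass —
  an isolated-looking segment that no class explains is usually a
  superposition whose phase count slipped under the criterion.
* **Hidden constituents:** after an isolated segment is assigned, its
  class template is subtracted at the PsC-optimal position; if more
  than 10% of the segment energy remains, the leftover is peeled
  (positive scores only — a leftover is not presumed to contain a
  MUAP).

## Evaluation

* DR% measures coverage: a true discharge is detected when its waveform
  span intersects a detected active segment (computed after de-noising
  and segmentation, before validity filtering).
* NM_detected counts valid isolated segments plus max(1, resolved
  constituents) per superimposed segment plus hidden constituents;
  NM_unassigned counts isolated segments no class accepted plus
  superimposed segments with zero resolved constituents. This keeps
  NM_correct ≤ NM_detected and reproduces the worked figure
  AR% = 99.54 for 216 detected / 1 unassigned.
* Decomposed units are mapped one-to-one to true units by maximal
  normalized template cross-correlation (greedy). The correlation lag
  also converts decomposed onsets into the true template's onset frame
  before the ±0.5 ms matching — without it, the difference between the
  decomposed frame (peak-centered buffer) and the true frame (waveform
  onset) would be a systematic offset, not an error of the method.
  Matching is earliest-first one-to-one.

## Benchmark scales and what passing shows

The acceptance benchmarks use ten 5-s records per quantity (detection:
4–8 units at 15–20 dB; assignment/classification: 6 units at 20 dB),
about 300 discharges per record; a full run takes ~15 s on one CPU.
Thirty-record runs via `emgdecomp benchmark` give the same means within
the seed-to-seed spread (roughly ±0.05 on AR%, ±2 on CCR%).

What the synthetic conditions do **not** exercise: waveform
nonstationarity from needle movement, real (non-Gaussian, nonstationary)
background interference, power-line artifacts, and units whose
amplitudes sit near the detection threshold. Passing here shows the
machinery is correct and calibrated under the stated model, not that the
same indices would be reached on clinical recordings.

Known limitations:

* Units with waveform correlation ≳ 0.93 are not reliably separable
  from a single channel by shape alone; the feature-distance
  distinctness bound does not exclude such pairs, and they dominate the
  residual classification error (occasional records with CCR% well
  below the mean). Firing-statistics-aware assignment would help and is
  deliberately not implemented.
* Near-complete (destructive) fusions — cross-unit onset gaps under
  ~1.5 ms — often resolve with a wrong constituent or a peak-shifted
  offset; subtraction-based peel-off cannot do better in principle, and
  modeling-based joint resolution is out of scope.
* The auto phase tuning and the two auxiliary peel passes trade a small
  risk of false constituents for completeness; on pure-noise inputs the
  false-peel rate is bounded by the energy gate (tested).
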