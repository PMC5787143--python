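"""Segment detection: noise power, resting epochs, phase counting."""

import numpy as np
import pytest

from emgdecomp.segment import (
    KIND_INVALID,
    KIND_ISOLATED,
    KIND_SUPERIMPOSED,
    Segment,
    classify_segments,
    count_phases,
    detect_segments,
    estimate_noise_power,
)

FS = 30000.0


class TestEstimateNoisePower:
    def test_enumerated_example(self):
        """[2,2,2,2,1,1,1,1] with a 4-sample window: the minimum windowed
        mean square is the all-ones window."""
        sig = np.array([2, 2, 2, 2, 1, 1, 1, 1], dtype=float)
        est = estimate_noise_power(sig, fs=3200.0, window_ms=1.25)  # L_R = 4
        assert est.window_len == 4
        assert est.sigma_n_sq == pytest.approx(1.0)
        expected = [4.0, 3.25, 2.5, 1.75, 1.0]
        np.testing.assert_allclose(est.per_window, expected)

    def test_all_zero(self):
        est = estimate_noise_power(np.zeros(100), FS)
        assert est.sigma_n_sq == 0.0

    def test_constant_signal(self):
        est = estimate_noise_power(np.full(100, 3.0), FS)
        assert est.sigma_n_sq == pytest.approx(9.0)

    def test_empty_signal_rejected(self):
        with pytest.raises(ValueError):
            estimate_noise_power(np.array([]), FS)

    def test_minimum_over_windows(self, rng):
        sig = rng.normal(0, 10, 5000)
        est = estimate_noise_power(sig, FS)
        assert est.sigma_n_sq == pytest.approx(est.per_window.min())
        assert est.sigma_n_sq <= np.mean(sig**2)


def _pulse_record(amp=300.0, center_s=1.0, dur_s=2.0, floor=10.0):
    """A biphasic pulse over a deterministic ±10 µV dither floor.

    The alternating floor gives an exact noise RMS of ``floor`` in every
    window, so the detection threshold is k·floor and only the pulse
    crosses it.
    """
    n = int(dur_s * FS)
    sig = floor * (-1.0) ** np.arange(n)
    m = int(0.004 * FS)
    t = np.linspace(-1, 1, m)
    pulse = amp * np.sin(np.pi * t) * np.exp(-4 * t * t)
    c = int(center_s * FS)
    lo = c - m // 2
    sig[lo : lo + m] = pulse
    return sig, lo, lo + m


class TestDetectSegments:
    def test_all_zero_gives_no_segments(self):
        assert detect_segments(np.zeros(10000), FS) == []

    def test_single_pulse_covered_with_expansion(self):
        sig, lo, hi = _pulse_record()
        segs = detect_segments(sig, FS, k=5.0)
        assert len(segs) == 1
        expand = int(round(0.2e-3 * FS))
        T = 5.0 * estimate_noise_power(sig, FS).sigma_n
        above = np.flatnonzero(np.abs(sig) >= T)
        # the supra-threshold pulse body plus the 0.2 ms margin is covered,
        # and the segment does not leak beyond the pulse plus that margin
        assert segs[0].start == above[0] - expand
        assert segs[0].end == above[-1] + 1 + expand
        assert lo - expand <= segs[0].start < segs[0].end <= hi + expand

    def test_every_true_firing_covered(self, noisy_recording):
        record, truth = noisy_recording
        segs = detect_segments(record.samples, record.fs, k=6.0)
        spans = [(s.start, s.end) for s in segs]
        by_id = {t.mu_id: t for t in truth.templates}
        for p in truth.patterns:
            m = len(by_id[p.mu_id].waveform)
            for t in p.times:
                o = int(round(t * record.fs))
                assert any(s < o + m and e > o for s, e in spans)

    def test_above_threshold_samples_always_inside_segments(self, rng):
        sig = rng.normal(0, 10, 30000)
        sig[5000:5050] += 200
        est = estimate_noise_power(sig, FS)
        T = 6.0 * est.sigma_n
        segs = detect_segments(sig, FS, k=6.0)
        mask = np.zeros(len(sig), bool)
        for s in segs:
            mask[s.start : s.end] = True
        assert not np.any((np.abs(sig) >= T) & ~mask)

    def test_monotone_in_k(self, rng):
        sig = rng.normal(0, 10, 60000)
        for spike in (4000, 15000, 33000, 52000):
            sig[spike : spike + 60] += rng.normal(0, 150, 60)
        counts = [len(detect_segments(sig, FS, k=k)) for k in (5.0, 6.0, 7.0, 8.0)]
        assert counts == sorted(counts, reverse=True)

    def test_saturated_signal_errors(self):
        with pytest.raises(ValueError, match="larger k"):
            detect_segments(np.full(10000, 100.0), FS, k=6.0, noise_power=1.0)

    def test_segments_never_overlap(self, noisy_recording):
        record, _ = noisy_recording
        segs = detect_segments(record.samples, record.fs, k=5.0)
        for a, b in zip(segs[:-1], segs[1:]):
            assert a.end <= b.start


class TestCountPhases:
    def test_single_bump(self):
        x = 100 * np.exp(-np.linspace(-3, 3, 90) ** 2)
        assert count_phases(x, 30.0) == 1

    def test_biphasic(self):
        t = np.linspace(0, 1, 120)
        x = 100 * np.sin(2 * np.pi * t)
        assert count_phases(x, 30.0) == 2

    def test_subthreshold_ripple_counts_zero(self):
        t = np.linspace(0, 4, 200)
        x = 5 * np.sin(2 * np.pi * t)
        assert count_phases(x, 30.0) == 0

    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_n_lobed_waveform(self, n):
        # quiet flanks mimic the expanded resting margins of a detected
        # segment and anchor the median baseline at rest level
        t = np.linspace(0, n / 2, 60 * n)
        x = np.concatenate([np.zeros(120), 200 * np.sin(2 * np.pi * t), np.zeros(120)])
        assert count_phases(x, 50.0) == n


class TestClassifySegments:
    def _seg(self, samples, fs=FS, start=0):
        samples = np.asarray(samples, float)
        return Segment(start, start + len(samples), samples, fs)

    def _lobes(self, n, amp=200.0, ms_per_lobe=1.0, flank_ms=0.5):
        t = np.linspace(0, n / 2, int(n * ms_per_lobe * 1e-3 * FS))
        flank = np.zeros(int(flank_ms * 1e-3 * FS))
        return np.concatenate([flank, amp * np.sin(2 * np.pi * t), flank])

    def test_three_phase_is_isolated_under_tetraphasic_template(self):
        segs = [self._seg(self._lobes(3))]
        iso, sup, inv = classify_segments(segs, 4, threshold=50.0)
        assert [s.kind for s in segs] == [KIND_ISOLATED]
        assert iso and not sup and not inv

    def test_six_phase_is_superimposed_under_tetraphasic_template(self):
        segs = [self._seg(self._lobes(6, ms_per_lobe=1.5))]
        iso, sup, inv = classify_segments(segs, 4, threshold=50.0)
        assert segs[0].kind == KIND_SUPERIMPOSED
        assert segs[0].n_phases == 6

    def test_six_phase_is_isolated_under_hexaphasic_template(self):
        segs = [self._seg(self._lobes(6, ms_per_lobe=1.5))]
        iso, sup, inv = classify_segments(segs, 6, threshold=50.0)
        assert segs[0].kind == KIND_ISOLATED

    def test_short_segment_invalid(self):
        # 2 phases but under 1.5 ms in total
        segs = [self._seg(self._lobes(2, ms_per_lobe=0.25, flank_ms=0.2))]
        iso, sup, inv = classify_segments(segs, 4, threshold=50.0)
        assert segs[0].kind == KIND_INVALID

    def test_single_phase_invalid(self):
        x = 200 * np.exp(-np.linspace(-3, 3, 90) ** 2)
        segs = [self._seg(x)]
        iso, sup, inv = classify_segments(segs, 4, threshold=50.0)
        assert segs[0].kind == KIND_INVALID

    def test_threshold_required(self):
        with pytest.raises(ValueError):
            classify_segments([self._seg(self._lobes(3))], 4)
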