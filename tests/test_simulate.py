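"""Simulator: template synthesis, renewal firing, record composition."""

import numpy as np
import pytest

from emgdecomp.io import EMGRecord
from emgdecomp.segment import count_phases
from emgdecomp.simulate import (
    REFRACTORY_S,
    make_firing_pattern,
    make_template,
    synthesize,
)


class TestMakeTemplate:
    def test_construction_contract(self):
        rng = np.random.default_rng(0)
        t = make_template(4.0, 300.0, 3, 30000.0, rng, max_redraws=500)
        assert len(t.waveform) == 120  # 4 ms at 30 kHz
        assert np.max(np.abs(t.waveform)) == pytest.approx(300.0)
        assert t.n_phases == 3
        assert t.peak_index == int(np.argmax(np.abs(t.waveform)))

    def test_phase_count_matches_target(self):
        rng = np.random.default_rng(1)
        for target in (2, 3, 4):
            t = make_template(5.0, 200.0, target, 30000.0, rng, max_redraws=500)
            assert count_phases(t.waveform, 0.1 * 200.0) == target

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"amplitude_uv": 0.0},
            {"amplitude_uv": -5.0},
            {"duration_ms": 1.0},
            {"fs": -1.0},
            {"n_phases_target": 0},
        ],
    )
    def test_degenerate_inputs_rejected(self, kwargs):
        base = dict(duration_ms=4.0, amplitude_uv=300.0, n_phases_target=3, fs=30000.0)
        base.update(kwargs)
        with pytest.raises(ValueError):
            make_template(rng=np.random.default_rng(0), **base)

    def test_deterministic_under_seed(self):
        a = make_template(4.0, 300.0, 3, 30000.0, np.random.default_rng(42), max_redraws=500)
        b = make_template(4.0, 300.0, 3, 30000.0, np.random.default_rng(42), max_redraws=500)
        np.testing.assert_array_equal(a.waveform, b.waveform)


class TestMakeFiringPattern:
    def test_zero_cv_gives_equispaced_firings(self):
        p = make_firing_pattern(5.0, 10.0, 0.0, 0.0, np.random.default_rng(3))
        assert abs(len(p.times) - 50) <= 1
        ipis = np.diff(p.times)
        np.testing.assert_allclose(ipis, 0.1, rtol=1e-9)

    def test_mean_ipi_converges(self):
        """Monte-Carlo: sample mean IPI within 3 SE of the configured 100 ms."""
        rng = np.random.default_rng(4)
        ipis = []
        for _ in range(200):
            p = make_firing_pattern(5.0, 10.0, 0.15, 0.0, rng)
            ipis.extend(np.diff(p.times))
        ipis = np.asarray(ipis)
        se = ipis.std() / np.sqrt(len(ipis))
        assert abs(ipis.mean() - 0.1) < 3 * se + 1e-12

    def test_random_rate_adds_poisson_discharges(self):
        rng = np.random.default_rng(5)
        n_plain = np.mean(
            [len(make_firing_pattern(5.0, 10.0, 0.15, 0.0, rng).times) for _ in range(100)]
        )
        n_extra = np.mean(
            [len(make_firing_pattern(5.0, 10.0, 0.15, 2.0, rng).times) for _ in range(100)]
        )
        # expect ~ duration * rate = 10 extra, minus refractory-collision losses
        assert 6 <= n_extra - n_plain <= 12

    def test_refractory_floor_respected(self):
        rng = np.random.default_rng(6)
        p = make_firing_pattern(5.0, 30.0, 0.5, 20.0, rng)
        assert np.all(np.diff(p.times) >= REFRACTORY_S - 1e-12)

    def test_preconditions(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            make_firing_pattern(-1.0, 10.0, 0.1, 0.0, rng)
        with pytest.raises(ValueError):
            make_firing_pattern(5.0, 80.0, 0.1, 0.0, rng)
        with pytest.raises(ValueError):
            make_firing_pattern(5.0, 10.0, 0.9, 0.0, rng)


class TestSynthesize:
    def _one_template(self, seed=0):
        t = make_template(4.0, 300.0, 3, 30000.0, np.random.default_rng(seed), max_redraws=500)
        t.mu_id = 0
        return t

    def test_identity_placement_no_noise(self):
        from emgdecomp.simulate import FiringPattern

        t = self._one_template()
        pat = FiringPattern(0, np.array([1.0]), 0.1, 0.0, 0.0)
        record, truth = synthesize([t], [pat], 2.0, 30000.0, snr_db=None)
        m = len(t.waveform)
        np.testing.assert_array_equal(record.samples[30000 : 30000 + m], t.waveform)
        assert np.all(record.samples[:30000] == 0)
        assert np.all(record.samples[30000 + m :] == 0)

    def test_snr_is_exact(self):
        from emgdecomp.simulate import FiringPattern

        t = self._one_template()
        pat = make_firing_pattern(5.0, 10.0, 0.1, 0.0, np.random.default_rng(1), mu_id=0)
        for snr in (10.0, 20.0):
            record, _ = synthesize([t], [pat], 5.0, 30000.0, snr_db=snr,
                                   rng=np.random.default_rng(2))
            clean, _ = synthesize([t], [pat], 5.0, 30000.0, snr_db=None)
            noise = record.samples - clean.samples
            measured = 10 * np.log10(np.mean(clean.samples**2) / np.mean(noise**2))
            assert abs(measured - snr) < 0.1

    def test_zero_clean_signal_with_snr_errors(self):
        from emgdecomp.simulate import FiringPattern

        t = self._one_template()
        pat = FiringPattern(0, np.array([]), 0.1, 0.0, 0.0)
        with pytest.raises(ValueError):
            synthesize([t], [pat], 1.0, 30000.0, snr_db=20.0)

    def test_superposition_is_linear(self):
        """record(A∪B) = record(A) + record(B) when noise is off."""
        from emgdecomp.simulate import FiringPattern

        ta = self._one_template(0)
        tb = make_template(3.0, 150.0, 2, 30000.0, np.random.default_rng(9), max_redraws=500)
        tb.mu_id = 1
        pa = FiringPattern(0, np.array([0.5, 1.0]), 0.5, 0.0, 0.0)
        pb = FiringPattern(1, np.array([0.501, 1.3]), 0.5, 0.0, 0.0)
        both, _ = synthesize([ta, tb], [pa, pb], 2.0, 30000.0, snr_db=None)
        only_a, _ = synthesize([ta], [pa], 2.0, 30000.0, snr_db=None)
        only_b, _ = synthesize([tb], [pb], 2.0, 30000.0, snr_db=None)
        np.testing.assert_allclose(both.samples, only_a.samples + only_b.samples)

    def test_edge_firings_dropped_from_truth(self):
        from emgdecomp.simulate import FiringPattern

        t = self._one_template()
        pat = FiringPattern(0, np.array([0.5, 1.999]), 0.5, 0.0, 0.0)
        _, truth = synthesize([t], [pat], 2.0, 30000.0, snr_db=None)
        assert truth.patterns[0].times.tolist() == [0.5]


def test_generate_recording_determinism_and_distinctness():
    from emgdecomp.features import align, distance_matrix, feature_matrix
    from emgdecomp.simulate import generate_recording

    r1, t1 = generate_recording(n_mus=4, duration_s=1.0, seed=11, min_feature_distance=0.3)
    r2, t2 = generate_recording(n_mus=4, duration_s=1.0, seed=11, min_feature_distance=0.3)
    np.testing.assert_array_equal(r1.samples, r2.samples)
    for a, b in zip(t1.patterns, t2.patterns):
        np.testing.assert_array_equal(a.times, b.times)
    D = distance_matrix(feature_matrix(align([t.waveform for t in t1.templates])))
    off = D[~np.eye(4, dtype=bool)]
    assert off.min() >= 0.3
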