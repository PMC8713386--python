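import numpy as np
import pytest

from cbfar import (ColeParams, CompartmentState, VolumeConstants,
                   cole_impedance, compartment_volumes, fit_cole,
                   ipg_flow_metrics, normalize_and_transfer,
                   simulate_compartments, simulate_eis_series,
                   volumes_to_cole)
from cbfar.preprocess import BeatSeries

FREQS = np.logspace(3, 6, 25)


class TestColeFit:
    def test_noiseless_round_trip(self):
        truth = ColeParams(100.0, 60.0, 2e-6, 0.8)
        fit = fit_cole(FREQS, cole_impedance(FREQS, truth))
        for name in ("r0", "rinf", "tau", "alpha"):
            assert getattr(fit, name) == pytest.approx(
                getattr(truth, name), rel=1e-3)
        assert fit.residual < 1e-6

    def test_intracellular_resistance_identity(self):
        fit = fit_cole(FREQS, cole_impedance(FREQS, ColeParams(100, 60, 2e-6, 0.8)))
        assert fit.ri == pytest.approx(100 * 60 / 40, rel=1e-3)  # 150 ohm

    def test_debye_limit_when_alpha_is_one(self):
        truth = ColeParams(100.0, 60.0, 2e-6, 1.0)
        z = cole_impedance(FREQS, truth)
        fit = fit_cole(FREQS, z)
        assert fit.alpha == pytest.approx(1.0, abs=1e-6)
        # explicit Debye model agrees with the alpha=1 Cole evaluation
        debye = truth.rinf + (truth.r0 - truth.rinf) / (
            1 + 1j * 2 * np.pi * FREQS * truth.tau)
        assert np.allclose(z, debye)

    def test_too_few_frequencies_rejected(self):
        with pytest.raises(ValueError, match="5"):
            fit_cole(FREQS[:4], np.ones(4, dtype=complex))

    def test_magnitude_decreases_with_frequency(self):
        z = cole_impedance(FREQS, ColeParams(100, 60, 2e-6, 0.8))
        assert np.all(np.diff(np.abs(z)) <= 1e-12)


class TestCompartmentVolumes:
    def test_doubling_re_halves_vec(self):
        p1 = ColeParams(100.0, 60.0, 2e-6, 0.8)
        p2 = ColeParams(200.0, 120.0, 2e-6, 0.8)
        v1, _ = compartment_volumes(p1)
        v2, _ = compartment_volumes(p2)
        assert v2 == pytest.approx(v1 / 2.0)

    def test_zero_length_segment_gives_zero_volumes(self):
        c = VolumeConstants(segment_length_cm=0.0)
        vec, vic = compartment_volumes(ColeParams(100, 60, 2e-6, 0.8), c)
        assert vec == 0.0 and vic == 0.0

    def test_volume_cole_inverse_pair(self):
        p = volumes_to_cole(0.45, 0.95)
        vec, vic = compartment_volumes(p)
        assert vec == pytest.approx(0.45, rel=1e-12)
        assert vic == pytest.approx(0.95, rel=1e-12)


class TestEisSimulation:
    def test_constant_volumes_zero_noise_time_invariant(self):
        state = CompartmentState.from_extracellular_split(
            np.arange(5.0), np.full(5, 0.9), np.full(5, 0.5))
        sp = simulate_eis_series(state, FREQS, noise_sd_ohm=0.0, seed=0)
        assert np.allclose(sp.z, sp.z[0])

    def test_extracellular_drop_raises_low_frequency_impedance(self):
        state = CompartmentState.from_extracellular_split(
            np.arange(2.0), [0.9, 0.9], [0.5, 0.4])
        sp = simulate_eis_series(state, FREQS, noise_sd_ohm=0.0, seed=0)
        assert abs(sp.z[1, 0]) > abs(sp.z[0, 0])

    def test_seeded_noise_deterministic(self):
        state = CompartmentState.from_extracellular_split(
            np.arange(3.0), np.full(3, 0.9), np.full(3, 0.5))
        a = simulate_eis_series(state, FREQS, noise_sd_ohm=0.05, seed=11)
        b = simulate_eis_series(state, FREQS, noise_sd_ohm=0.05, seed=11)
        assert np.array_equal(a.z, b.z)

    def test_round_trip_recovers_trajectory(self, compact_script):
        comp = simulate_compartments(compact_script, dt=60.0)
        sp = simulate_eis_series(comp, FREQS, seed=5)  # default noise
        vec = np.empty(len(sp))
        vic = np.empty(len(sp))
        for k in range(len(sp)):
            p = fit_cole(sp.frequencies_hz, sp.z[k])
            vec[k], vic[k] = compartment_volumes(p)
        assert np.corrcoef(vec, comp.vec)[0, 1] > 0.99
        assert np.max(np.abs(vec / comp.vec - 1.0)) < 0.02
        assert np.max(np.abs(vic / comp.vic - 1.0)) < 0.02


class TestNormalizeAndTransfer:
    @staticmethod
    def state(vb, vi, vic):
        vb, vi, vic = (np.asarray(a, dtype=float) for a in (vb, vi, vic))
        return CompartmentState(timestamps=np.arange(float(vb.size)),
                                vic=vic, vec=vb + vi, vb=vb, vi=vi)

    def test_constant_volumes(self):
        s = normalize_and_transfer(
            self.state([0.2] * 4, [0.3] * 4, [0.9] * 4), (0.0, 1.0))
        assert np.allclose(s.nv_blood, 1.0)
        assert np.allclose(s.fc, 0.0) and np.allclose(s.fb, 0.0)

    def test_blood_to_interstitium_sign_convention(self):
        # Vb drops 0.2 L while Vi rises 0.2 L: Fb = +0.2, Fi = -0.2
        s = normalize_and_transfer(
            self.state([0.4, 0.4, 0.2], [0.3, 0.3, 0.5], [0.9] * 3),
            (0.0, 1.0))
        assert s.fb[-1] == pytest.approx(0.2)
        assert s.fi[-1] == pytest.approx(-0.2)
        assert s.fc[-1] + s.fi[-1] + s.fb[-1] == pytest.approx(0.0, abs=1e-12)

    def test_all_compartments_losing_gives_positive_transfers(self):
        s = normalize_and_transfer(
            self.state([0.4, 0.3], [0.3, 0.25], [0.9, 0.85]), (0.0, 0.5))
        assert s.fb[-1] > 0 and s.fi[-1] > 0 and s.fc[-1] > 0

    def test_transfer_sum_conservation(self, compact_script):
        comp = simulate_compartments(compact_script, dt=30.0)
        s = normalize_and_transfer(comp, (0.0, compact_script.epochs[4].t_start))
        total_change = s.total - np.mean(
            s.total[(s.timestamps >= 0)
                    & (s.timestamps <= compact_script.epochs[4].t_start)])
        assert np.max(np.abs(s.fc + s.fi + s.fb + total_change)) < 1e-9
        assert np.allclose(s.vec, s.vb + s.vi, atol=1e-9)


class TestIpgFlowMetrics:
    @staticmethod
    def triangle_train(n_beats=6, rate=200.0, period=1.0, rise=0.2, fall=0.2):
        n = int(n_beats * period * rate)
        t = np.arange(n) / rate
        ph = np.mod(t, period)
        x = np.where(ph < rise, ph / rise,
                     np.where(ph < rise + fall, 1 - (ph - rise) / fall, 0.0))
        peaks = (np.arange(n_beats) + 0.0) * period + rise
        feet = np.arange(n_beats) * period
        beats = BeatSeries(beat_times=peaks, systolic=np.ones(n_beats),
                           diastolic=np.zeros(n_beats), foot_times=feet)
        return x, beats

    def test_tin_is_foot_to_peak_time(self):
        x, beats = self.triangle_train()
        m = ipg_flow_metrics(x, 200.0, beats)
        assert np.allclose(m.tin[np.isfinite(m.tin)], 0.2)

    def test_tout_ninety_percent_return(self):
        x, beats = self.triangle_train()
        m = ipg_flow_metrics(x, 200.0, beats)
        valid = m.valid & np.isfinite(m.tout)
        assert np.allclose(m.tout[valid], 0.18, atol=0.006)

    def test_unchanged_amplitude_and_rate_give_zero_percent(self):
        x, beats = self.triangle_train()
        m = ipg_flow_metrics(x, 200.0, beats, baseline_window=(0.0, 3.0))
        finite = m.percent_blood_flow[np.isfinite(m.percent_blood_flow)]
        assert np.allclose(finite, 0.0, atol=1e-9)

    def test_too_few_beats_rejected(self):
        x, beats = self.triangle_train(n_beats=6)
        two = BeatSeries(beats.beat_times[:2], beats.systolic[:2],
                         beats.diastolic[:2], beats.foot_times[:2])
        with pytest.raises(ValueError, match="3 beats"):
            ipg_flow_metrics(x, 200.0, two)
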