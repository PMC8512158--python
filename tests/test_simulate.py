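"""Synthetic session generator: determinism, construction properties,
generator/detector and generator/fit round trips."""

import pickle
import warnings

import numpy as np
import pytest

from myobelt.calibration import BELT_CURVE, capacitance_to_length
from myobelt.crossmodal import EvaluationConfig, evaluate_session, predict
from myobelt.errors import ValidationError
from myobelt.gait import detect_heel_contacts
from myobelt.preprocessing import emg_envelope
from myobelt.simulate import (DEFAULT_TRUTH_MODEL, GaussianBump, SimulationConfig,
                              concat_sessions, generate_session,
                              simulate_activations, simulate_capacitance,
                              simulate_circumference, simulate_emg, simulate_grf)
from myobelt.timeseries import TimeSeries


class TestConfig:
    def test_negative_bump_width_rejected(self):
        with pytest.raises(ValidationError):
            GaussianBump(50.0, -1.0, 0.5)

    def test_bump_peak_range_enforced(self):
        with pytest.raises(ValidationError):
            GaussianBump(50.0, 5.0, 1.5)

    def test_emg_band_must_fit_nyquist(self):
        with pytest.raises(ValidationError):
            SimulationConfig(rate=500.0)  # default band reaches 450 Hz

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValidationError):
            SimulationConfig(condition="moonwalk")


class TestActivations:
    def test_empty_templates_all_zero(self):
        cfg = SimulationConfig(condition="passive_flexion", n_cycles=3, seed=0)
        A = simulate_activations(cfg)
        assert np.all(A == 0.0)

    def test_single_bump_peaks_mid_cycle(self):
        templates = {m: () for m in ("RF", "VM", "BFL", "BFS")}
        templates["VL"] = (GaussianBump(50.0, 5.0, 0.5),)
        cfg = SimulationConfig(condition="squat", n_cycles=1,
                               activation_templates=templates,
                               cycle_jitter=0.0, tone_sd_mvc=0.0, seed=0)
        A = simulate_activations(cfg)
        assert A[0].max() == pytest.approx(0.5, rel=1e-6)
        assert abs(np.argmax(A[0]) - 0.5 * cfg.samples_per_cycle) <= 1

    def test_cocontraction_style_adds_tonic_floor(self):
        cfg = SimulationConfig(condition="walk", gait_style="cocontraction",
                               n_cycles=3, cocontraction_offset=0.3,
                               tone_sd_mvc=0.0, seed=0)
        A = simulate_activations(cfg)
        assert A.min() >= 0.3 - 1e-12

    def test_relaxation_reduces_swing_activity(self):
        kw = dict(condition="walk", n_cycles=6, seed=5)
        neutral = simulate_activations(SimulationConfig(gait_style="neutral", **kw))
        relaxed = simulate_activations(SimulationConfig(gait_style="relaxation", **kw))
        assert relaxed.sum() < neutral.sum()

    def test_clipped_to_valid_mvc_range(self):
        cfg = SimulationConfig(condition="cocontraction_sitting", n_cycles=3, seed=1)
        A = simulate_activations(cfg)
        assert A.min() >= 0.0 and A.max() <= 1.2


class TestEmg:
    def test_zero_activation_zero_emg(self):
        cfg = SimulationConfig(n_cycles=2, seed=0)
        act = TimeSeries(np.zeros(3000), rate=1000.0, name="VL")
        assert np.all(simulate_emg(act, cfg).values == 0.0)

    def test_same_seed_identical_traces(self):
        cfg = SimulationConfig(n_cycles=2, seed=0)
        act = TimeSeries(np.abs(np.sin(np.arange(3000) / 300.0)), rate=1000.0, name="VL")
        a = simulate_emg(act, cfg, np.random.default_rng(99))
        b = simulate_emg(act, cfg, np.random.default_rng(99))
        assert np.array_equal(a.values, b.values)

    def test_envelope_recovers_activation_shape(self, walk_session):
        # 30 s walking: envelope correlates strongly with the true activation
        for i, m in enumerate(("VL", "BFS")):
            env = emg_envelope(walk_session.emg[m]).values
            r = np.corrcoef(env, walk_session.truth.activations[i if m == "VL" else 4])[0, 1]
            assert r > 0.8


class TestGrf:
    @pytest.mark.parametrize("condition", ["walk", "run"])
    def test_swing_exactly_zero(self, condition):
        cfg = SimulationConfig(condition=condition, n_cycles=4, seed=0)
        grf = simulate_grf(cfg)
        assert np.min(grf.values) == 0.0
        frac_zero = np.mean(grf.values == 0.0)
        assert frac_zero > 0.25  # a substantial swing phase exists

    def test_walk_peak_near_body_weight_multiple(self):
        cfg = SimulationConfig(condition="walk", n_cycles=4, seed=0)
        grf = simulate_grf(cfg)
        assert grf.values.max() == pytest.approx(1.1 * cfg.grf_body_weight_N, rel=0.01)

    def test_run_peak_higher_than_walk(self):
        walk = simulate_grf(SimulationConfig(condition="walk", n_cycles=3, seed=0))
        run = simulate_grf(SimulationConfig(condition="run", n_cycles=3, seed=0))
        assert run.values.max() > 1.8 * walk.values.max() / 1.1


class TestCircumferenceAndCapacitance:
    def test_noiseless_matches_model_prediction(self):
        cfg = SimulationConfig(condition="squat", n_cycles=3,
                               circumference_noise_sd_mm=0.0, seed=0)
        A = simulate_activations(cfg)
        L = simulate_circumference(A, cfg)
        assert np.allclose(L, predict(cfg.truth_model, A.T), atol=1e-12)

    def test_passive_dip_reaches_configured_depth(self):
        cfg = SimulationConfig(condition="passive_flexion", n_cycles=4,
                               passive_amplitude_mm=2.0,
                               circumference_noise_sd_mm=0.0, seed=0)
        A = simulate_activations(cfg)
        L = simulate_circumference(A, cfg)
        assert L.min() == pytest.approx(cfg.truth_model.b - 2.0, abs=1e-6)

    def test_noise_sd_matches_configured(self):
        cfg = SimulationConfig(condition="cocontraction_sitting", n_cycles=8, seed=0)
        A = simulate_activations(cfg, np.random.default_rng(0))
        noiseless = simulate_circumference(
            A, SimulationConfig(condition="cocontraction_sitting", n_cycles=8,
                                circumference_noise_sd_mm=0.0, seed=0),
            np.random.default_rng(1))
        noisy = simulate_circumference(A, cfg, np.random.default_rng(1))
        sd = np.std(noisy - noiseless)
        assert sd == pytest.approx(1.8, rel=0.05)

    def test_capacitance_round_trip(self, belt_curve):
        L = np.linspace(97.0, 180.0, 1000)
        cap = simulate_capacitance(L, belt_curve, rate=1000.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            back = capacitance_to_length(belt_curve, cap.values)
        assert np.max(np.abs(back - L)) < 1e-9
        assert np.all(np.diff(cap.values) > 0)  # monotone branch

    def test_out_of_domain_length_names_sample(self, belt_curve):
        L = np.array([100.0, 50.0, 120.0])
        with pytest.raises(ValidationError, match="sample 1"):
            simulate_capacitance(L, belt_curve, rate=1000.0)


class TestSession:
    def test_same_config_and_seed_byte_identical(self):
        cfg = SimulationConfig(condition="run", n_cycles=3, seed=11)
        a, b = generate_session(cfg), generate_session(cfg)
        assert pickle.dumps(a) == pickle.dumps(b)

    def test_channels_share_length_and_rate(self, walk_session):
        n = walk_session.n_samples
        assert len(walk_session.vgrf) == n
        assert all(len(ts) == n for ts in walk_session.emg.values())
        assert walk_session.truth.activations.shape == (5, n)
        assert walk_session.truth.circumference_mm.shape == (n,)

    def test_walk_preset_has_n_cycles_contacts(self):
        s = generate_session(SimulationConfig(condition="walk", n_cycles=20, seed=2))
        assert s.truth.contact_indices.size == 20

    def test_passive_preset_silent_but_moving(self):
        s = generate_session(SimulationConfig(condition="passive_flexion",
                                              n_cycles=5, seed=0))
        assert np.all(s.truth.activations == 0.0)
        assert np.ptp(s.truth.circumference_mm) > 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_detector_matches_truth_all_presets(self, seed):
        for condition in ("walk", "run"):
            s = generate_session(SimulationConfig(condition=condition,
                                                  n_cycles=6, seed=seed))
            det = detect_heel_contacts(s.vgrf).contact_indices
            assert det.size == s.truth.contact_indices.size
            assert np.all(np.abs(det - s.truth.contact_indices) <= 1)

    def test_full_pipeline_recovery_walk_plus_squat(self):
        # measured-circumference path, phase-aligned filters, known activations
        errs = []
        for seed in range(20):
            s = concat_sessions(
                generate_session(SimulationConfig(condition="walk", n_cycles=27,
                                                  seed=seed)),
                generate_session(SimulationConfig(condition="squat", n_cycles=10,
                                                  seed=seed + 7919)))
            r = evaluate_session(s, EvaluationConfig(
                activity_source="truth", circumference_source="capacitance",
                zero_lag_lowpass=True))
            truth = s.truth.model.coefficients()
            errs.append(float(np.median(
                np.abs(r.model.coefficients() - truth) / np.abs(truth))))
        assert float(np.median(errs)) < 0.05
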