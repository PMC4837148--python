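"""Modulation runs, PEV extraction, scans, and the equipotent contour."""
import numpy as np
import pytest

import vestibsim as vs
from vestibsim.exceptions import ParameterError, StateError
from vestibsim.protocols import (
    MODE_BASELINE,
    MODE_HYBRID,
    MODE_PAM,
    MODE_PRM,
    SimulationTrace,
    _measure,
    config_for_mode,
    peak_eye_velocity,
    run_modulation,
    transition_midpoint,
)


def synthetic_trace(fn, n_cycles=4, bins=200, freq=2.0):
    t = np.arange(n_cycles * bins) / (bins * freq)
    phase = 2 * np.pi * freq * t
    return SimulationTrace(time=t, v=fn(phase), mod_freq=freq, bins_per_cycle=bins)


class TestPeakEyeVelocity:
    def test_pure_sinusoid_recovered_exactly(self):
        tr = synthetic_trace(lambda p: 2.5 * np.sin(p))
        res = peak_eye_velocity(tr)
        assert res.pev == pytest.approx(2.5, abs=1e-9)
        assert res.nev == pytest.approx(-2.5, abs=1e-9)

    def test_half_wave_rectified_sinusoid(self):
        tr = synthetic_trace(lambda p: np.maximum(np.sin(p), 0.0))
        res = peak_eye_velocity(tr)
        assert res.pev == pytest.approx(1.0, abs=1e-9)
        assert res.nev == pytest.approx(0.0, abs=1e-9)

    def test_zero_trace(self):
        tr = synthetic_trace(lambda p: np.zeros_like(p))
        res = peak_eye_velocity(tr)
        assert res.pev == 0.0 and res.nev == 0.0

    def test_sign_invariant_pev_nonneg_nev_nonpos(self):
        tr = synthetic_trace(lambda p: -3.0 * np.maximum(np.sin(p), 0.0))
        res = peak_eye_velocity(tr)
        assert res.pev >= 0.0 >= res.nev

    def test_requires_two_cycles(self):
        tr = synthetic_trace(lambda p: np.sin(p), n_cycles=1)
        with pytest.raises(ParameterError):
            peak_eye_velocity(tr)

    def test_constant_offset_does_not_leak_into_amplitude(self):
        tr = synthetic_trace(lambda p: 0.4 + 1.5 * np.sin(p))
        res = peak_eye_velocity(tr)
        assert res.pev == pytest.approx(1.5, abs=1e-9)
        assert res.nev == pytest.approx(-1.5, abs=1e-9)


class TestRunModulation:
    def test_pam_output_is_strongly_asymmetric(self, adapted_model):
        res = _measure(adapted_model.post_baseline, adapted_model.population, vs.StimulationConfig(), MODE_PAM, 0.25, 0.0, 21)
        assert res.pev > 2.0 * abs(res.nev)

    def test_prm_output_is_nearly_symmetric(self, adapted_model):
        res = _measure(adapted_model.post_baseline, adapted_model.population, vs.StimulationConfig(), MODE_PRM, 0.0, 0.25, 22)
        assert res.pev > 0
        assert abs(res.pev - abs(res.nev)) < 0.25 * res.pev

    def test_zero_depth_baseline_stays_quiet(self, adapted_model):
        cfg = config_for_mode(vs.StimulationConfig(), MODE_BASELINE)
        tr = run_modulation(adapted_model.post_baseline, adapted_model.population, cfg, MODE_BASELINE, seed=23)
        assert np.max(np.abs(tr.v)) < 0.2

    def test_unadapted_state_rejected(self, default_pop):
        healthy = vs.init_healthy_weights(default_pop, seed=1)
        cfg = config_for_mode(vs.StimulationConfig(), MODE_PAM, 0.25, 0)
        with pytest.raises(StateError):
            run_modulation(healthy, default_pop, cfg, MODE_PAM, seed=1)

    def test_mode_depth_consistency_enforced(self, adapted_model):
        bad = vs.StimulationConfig(amp_mod_depth=0.25, rate_mod_depth=0.25)
        with pytest.raises(ParameterError):
            run_modulation(adapted_model.post_baseline, adapted_model.population, bad, MODE_PAM, seed=1)

    def test_deterministic_given_seed(self, adapted_model):
        cfg = config_for_mode(vs.StimulationConfig(), MODE_PAM, 0.25, 0)
        a = run_modulation(adapted_model.post_baseline, adapted_model.population, cfg, MODE_PAM, seed=9)
        b = run_modulation(adapted_model.post_baseline, adapted_model.population, cfg, MODE_PAM, seed=9)
        assert np.array_equal(a.v, b.v)


class TestScans:
    def test_single_cell_scan_equals_direct_run(self):
        from vestibsim._seeding import spawn_rng
        from vestibsim.adaptation import adapt_three_phase

        grid = vs.scan_residual_vs_baseline([26.3], [200.0], master_seed=4, n_per_side=200)
        row = grid.table.iloc[0]
        cell_seed = int(spawn_rng(4, 0).integers(2**31))
        stim = vs.StimulationConfig(baseline_rate=200.0)
        pop = vs.sample_population(n_per_side=200, rate_mean=26.3, seed=cell_seed)
        model = adapt_three_phase(pop, stim, vs.AdaptationConfig(), seed=cell_seed + 1)
        direct = _measure(model.post_baseline, pop, stim, MODE_PAM, 0.25, 0.0, cell_seed + 2)
        assert row.pev_pam == pytest.approx(direct.pev)

    def test_learning_ratio_scan_columns_and_determinism(self):
        ratios = [1e2, 1e4]
        a = vs.scan_learning_ratio(ratios, master_seed=3, n_per_side=200)
        b = vs.scan_learning_ratio(ratios, master_seed=3, n_per_side=200)
        assert a.table.equals(b.table)
        assert set(["ratio", "pev_prm", "pam_symmetry"]) <= set(a.table.columns)

    def test_transition_midpoint_on_known_curve(self):
        x = np.logspace(0, 4, 9)
        # plateaus 5 and 1, linear-in-log transition between 10 and 1000
        y = np.interp(np.log10(x), [0, 1, 3, 4], [5.0, 5.0, 1.0, 1.0])
        mid = transition_midpoint(x, y)
        assert mid == pytest.approx(100.0, rel=1e-6)

    def test_transition_requires_crossing(self):
        with pytest.raises(ParameterError):
            transition_midpoint(np.array([1, 10, 100]), np.array([1.0, 5.0, 1.0]))


class TestComodulation:
    def test_surface_margins_match_pure_modes(self, adapted_model):
        grid = vs.comodulation_surface(
            pam_depths=[0.0, 0.25], prm_depths=[0.0, 1.0], master_seed=5, model=adapted_model
        )
        t = grid.table
        origin = t[(t.pam_depth == 0) & (t.prm_depth == 0)].pev.iloc[0]
        assert origin == 0.0
        pam_cell = t[(t.pam_depth == 0.25) & (t.prm_depth == 0)].pev.iloc[0]
        direct = _measure(adapted_model.post_baseline, adapted_model.population, vs.StimulationConfig(), MODE_PAM, 0.25, 0.0, 99)
        assert pam_cell == pytest.approx(direct.pev, rel=0.02)
        hybrid_cell = t[(t.pam_depth == 0.25) & (t.prm_depth == 1.0)].pev.iloc[0]
        assert hybrid_cell > pam_cell

    def test_equipotent_contour_self_consistency(self, adapted_model):
        table = vs.equipotent_contour(adapted_model, [0.25], seed=6)
        assert table.prm_depth.iloc[0] == pytest.approx(0.0, abs=0.02)

    def test_equipotent_contour_monotone(self, adapted_model):
        table = vs.equipotent_contour(adapted_model, [0.125, 0.175, 0.22], seed=6)
        depths = table.prm_depth.to_numpy()
        assert np.all(np.diff(depths) < 0)

    def test_unreachable_target_reported_as_nan(self, adapted_model):
        table = vs.equipotent_contour(adapted_model, [0.01], target_pev=50.0, seed=6)
        assert np.isnan(table.prm_depth.iloc[0])


class TestGainInvariance:
    def test_pev_ratio_invariant_to_output_gain(self):
        # doubling the output gain rescales velocities but leaves cross-mode
        # PEV ratios essentially unchanged
        ratios = []
        for gain in (10.0, 20.0):
            m = vs.default_acute_model(seed=31, n_per_side=400, output_gain=gain)
            pam = _measure(m.post_baseline, m.population, vs.StimulationConfig(), MODE_PAM, 0.25, 0.0, 32)
            prm = _measure(m.post_baseline, m.population, vs.StimulationConfig(), MODE_PRM, 0.0, 0.25, 33)
            ratios.append(pam.pev / prm.pev)
        assert ratios[0] == pytest.approx(ratios[1], rel=0.15)
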