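"""Afferent population sampling, recruitment law and ensemble-rate algebra."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import vestibsim as vs
from vestibsim.exceptions import ParameterError
from vestibsim.population import LEFT, RIGHT
from vestibsim._seeding import spawn_rng

from conftest import make_toy_population


class TestSamplePopulation:
    def test_lognormal_moments_recovered(self, default_pop):
        # 2000 draws: arithmetic mean/SD should sit within ~3 standard errors
        rates = default_pop.mean_rest_rate
        assert abs(rates.mean() - 26.3) < 3 * 6.6 / np.sqrt(rates.size)
        assert abs(rates.std(ddof=1) - 6.6) < 0.5

    def test_regularity_split_is_exact(self, default_pop):
        for side in (LEFT, RIGHT):
            mask = default_pop.side_mask(side)
            assert int(default_pop.is_regular[mask].sum()) == 670
            assert int((~default_pop.is_regular[mask]).sum()) == 330

    def test_cv_ranges_respect_class_boundary(self, default_pop):
        cv = default_pop.cv
        reg = default_pop.is_regular
        assert cv[reg].max() < 0.1 and cv[reg].min() > 0
        assert cv[~reg].min() >= 0.1

    def test_deterministic_given_seed(self):
        a = vs.sample_population(n_per_side=50, seed=3)
        b = vs.sample_population(n_per_side=50, seed=3)
        c = vs.sample_population(n_per_side=50, seed=4)
        assert np.array_equal(a.mean_rest_rate, b.mean_rest_rate)
        assert np.array_equal(a.recruitment_rank, b.recruitment_rank)
        assert not np.array_equal(a.mean_rest_rate, c.mean_rest_rate)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"rate_mean": -1.0},
            {"rate_sd": 0.0},
            {"n_per_side": 0},
            {"cv_range_regular": (0.05, 0.2)},
            {"cv_range_irregular": (0.05, 0.3)},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            vs.sample_population(n_per_side=kwargs.pop("n_per_side", 10), **kwargs)

    def test_csv_round_trip(self, tmp_path, default_pop):
        from vestibsim.population import population_from_csv, population_to_csv

        path = tmp_path / "pop.csv"
        population_to_csv(default_pop, path)
        back = population_from_csv(path)
        assert np.allclose(back.mean_rest_rate, default_pop.mean_rest_rate)
        assert np.array_equal(back.recruitment_rank, default_pop.recruitment_rank)
        assert np.array_equal(back.side, default_pop.side)


class TestRecruitment:
    @pytest.mark.parametrize(
        "mod,expected",
        [(0.0, 400), (0.25, 625), (-0.25, 225), (-1.0, 0)],
    )
    def test_quadratic_recruitment_counts(self, mod, expected):
        cfg = vs.StimulationConfig(amp_mod_depth=0.25)
        assert vs.recruited_count(cfg, 1000, mod) == expected

    @given(
        m1=st.floats(-1, 1, allow_nan=False),
        m2=st.floats(-1, 1, allow_nan=False),
    )
    def test_recruitment_nested_and_monotone(self, m1, m2):
        cfg = vs.StimulationConfig(amp_mod_depth=0.25)
        pop = make_toy_population(n_per_side=20)
        lo, hi = sorted([m1, m2])
        c_lo = vs.recruited_count(cfg, 20, lo)
        c_hi = vs.recruited_count(cfg, 20, hi)
        assert 0 <= c_lo <= c_hi <= 20
        set_lo = set(np.where(pop.stimulated_mask(c_lo, LEFT))[0])
        set_hi = set(np.where(pop.stimulated_mask(c_hi, LEFT))[0])
        assert set_lo <= set_hi

    def test_out_of_range_modulation_rejected(self):
        cfg = vs.StimulationConfig()
        with pytest.raises(ParameterError):
            vs.recruited_count(cfg, 1000, 1.5)

    def test_config_invariants_enforced(self):
        with pytest.raises(ParameterError):
            vs.StimulationConfig(amp_mod_depth=1.0, baseline_fraction=0.4)  # 0.4*(2)**2 > 1
        with pytest.raises(ParameterError):
            vs.StimulationConfig(rate_mod_depth=1.2)
        with pytest.raises(ParameterError):
            vs.StimulationConfig(mod_freq=0.0)


class TestEnvelope:
    def test_envelope_values(self):
        assert vs.modulation_envelope(0.0, 0.25, 2.0) == 0.0
        assert vs.modulation_envelope(1 / 8, 0.25, 2.0) == pytest.approx(0.25)
        t = np.linspace(0, 1, 17)
        assert np.all(vs.modulation_envelope(t, 0.0, 2.0) == 0.0)


class TestInstantaneousRates:
    def test_recruited_afferents_lock_to_pulse_rate(self):
        pop = make_toy_population(rate=27.0, cv=0.05)
        cfg = vs.StimulationConfig(baseline_rate=200.0)
        rates = vs.instantaneous_rates(pop, cfg, t=0.0, rng=spawn_rng(0))
        recruited = pop.stimulated_mask(vs.recruited_count(cfg, 10, 0.0), LEFT)
        assert np.all(rates[recruited] == 200.0)

    def test_non_recruited_emit_residual(self):
        pop = make_toy_population(rate=27.0, cv=0.05)
        cfg = vs.StimulationConfig(baseline_rate=200.0)
        rng_a, rng_b = spawn_rng(7), spawn_rng(7)
        rates = vs.instantaneous_rates(pop, cfg, t=0.0, rng=rng_a)
        residual = pop.draw_residual(rng_b)
        recruited = pop.stimulated_mask(vs.recruited_count(cfg, 10, 0.0), LEFT)
        assert np.allclose(rates[~recruited], residual[~recruited])

    def test_high_residual_beats_stimulation(self):
        # the max() entrainment keeps a 250 spikes/s residual over 200 pps stim
        pop = make_toy_population(rate=250.0, cv=1e-6)
        cfg = vs.StimulationConfig(baseline_rate=200.0)
        rates = vs.instantaneous_rates(pop, cfg, t=0.0, rng=spawn_rng(1))
        recruited = pop.stimulated_mask(vs.recruited_count(cfg, 10, 0.0), LEFT)
        assert np.all(rates[recruited] > 200.0)

    def test_rate_time_series_long_format(self, tmp_path):
        from vestibsim.population import rate_time_series

        pop = make_toy_population(rate=27.0)
        cfg = vs.StimulationConfig(amp_mod_depth=0.25)
        frame = rate_time_series(pop, cfg, times=[0.0, 0.125], seed=1)
        assert list(frame.columns) == ["time", "afferent_id", "rate"]
        assert len(frame) == 2 * pop.n_total
        path = tmp_path / "rates.csv"
        frame.to_csv(path, index=False)
        assert path.exists()

    def test_rates_never_negative(self):
        pop = make_toy_population(rate=2.0, cv=0.3)
        cfg = vs.StimulationConfig(baseline_rate=0.0)
        rates = vs.instantaneous_rates(pop, cfg, t=0.0, rng=spawn_rng(2))
        assert np.all(rates >= 0)


def _brute_force_pam(pop, cfg, m):
    """Independent oracle: explicit per-afferent summation."""
    n0 = int(round(cfg.baseline_fraction * pop.n_per_side))
    n1 = int(np.clip(round(cfg.baseline_fraction * (1 + m) ** cfg.recruitment_exponent * pop.n_per_side), 0, pop.n_per_side))
    total = 0.0
    for i in range(pop.n_total):
        if pop.side[i] == LEFT and min(n0, n1) <= pop.recruitment_rank[i] < max(n0, n1):
            total += cfg.baseline_rate - pop.mean_rest_rate[i]
    return total if n1 >= n0 else -total


class TestEnsembleRateChange:
    def test_pam_change_matches_summation_oracle(self):
        pop = make_toy_population(n_per_side=10, rate=20.0)
        cfg = vs.StimulationConfig(baseline_rate=200.0, amp_mod_depth=0.2247, baseline_fraction=0.4)
        # baseline 4 recruited, peak 6: two new afferents at (200 - 20) each
        assert vs.recruited_count(cfg, 10, 0.0) == 4
        assert vs.recruited_count(cfg, 10, cfg.amp_mod_depth) == 6
        got = vs.ensemble_rate_change_pam(pop, cfg)
        assert got == pytest.approx(2 * (200 - 20)) == pytest.approx(_brute_force_pam(pop, cfg, cfg.amp_mod_depth))

    @given(
        n=st.integers(4, 20),
        depth=st.floats(0, 0.5),
        prb=st.floats(50, 400),
        seed=st.integers(0, 100),
    )
    def test_pam_change_property_vs_oracle(self, n, depth, prb, seed):
        rng = spawn_rng(seed)
        pop = make_toy_population(n_per_side=n, rate=20.0)
        pop.mean_rest_rate = rng.uniform(5, 60, pop.n_total)
        cfg = vs.StimulationConfig(baseline_rate=prb, amp_mod_depth=depth, baseline_fraction=0.4)
        assert vs.ensemble_rate_change_pam(pop, cfg) == pytest.approx(_brute_force_pam(pop, cfg, depth))

    def test_pam_change_degenerate_cases(self):
        pop = make_toy_population(n_per_side=10, rate=20.0)
        cfg = vs.StimulationConfig(baseline_rate=200.0, amp_mod_depth=0.0)
        assert vs.ensemble_rate_change_pam(pop, cfg) == 0.0
        pop_eq = make_toy_population(n_per_side=10, rate=200.0)
        cfg2 = vs.StimulationConfig(baseline_rate=200.0, amp_mod_depth=0.2247)
        assert vs.ensemble_rate_change_pam(pop_eq, cfg2) == 0.0

    def test_prm_change_direct_product(self):
        cfg = vs.StimulationConfig(baseline_rate=200.0, rate_mod_depth=0.25)
        # 400 recruited, peak rate 250: 400 * 50
        assert vs.ensemble_rate_change_prm(cfg, 1000) == pytest.approx(20000.0)
        assert vs.ensemble_rate_change_prm(cfg, 1000, instantaneous_rate_mod=-0.25) == pytest.approx(-20000.0)
        cfg0 = vs.StimulationConfig(baseline_rate=200.0, rate_mod_depth=0.0)
        assert vs.ensemble_rate_change_prm(cfg0, 1000) == 0.0


class TestDeltaCharge:
    def test_pure_modes_reduce_to_single_terms(self):
        pam = vs.StimulationConfig(amp_mod_depth=0.25, rate_mod_depth=0.0)
        assert vs.delta_charge(pam) == pytest.approx(pam.baseline_rate * pam.amp_envelope_peak)
        prm = vs.StimulationConfig(amp_mod_depth=0.0, rate_mod_depth=0.25)
        assert vs.delta_charge(prm) == pytest.approx(prm.rate_envelope_peak * prm.baseline_amplitude)

    def test_hybrid_sum_of_terms(self):
        cfg = vs.StimulationConfig(
            baseline_amplitude=1.0, amp_mod_depth=0.25, baseline_rate=200.0, rate_mod_depth=0.25
        )
        # 200*0.25 + 50*1 + 50*0.25
        assert vs.delta_charge(cfg) == pytest.approx(112.5)
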