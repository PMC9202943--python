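"""Tests for ensembles, the fairness statistic, and sensitivity sweeps."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from elfarol import (
    EnsembleResult,
    SimulationParams,
    attendance_variability_profile,
    compare_regimes,
    fairness_variance,
    run_ensemble,
    segmentation_fraction,
    sensitivity_sweep,
    simulate_run,
    summarize_ensemble,
)


def small_params(**kw):
    defaults = dict(n_agents=30, capacity=18, stepsize=0.02, horizon=60)
    defaults.update(kw)
    return SimulationParams(**defaults)


class TestFairnessVariance:
    def test_equal_access_scores_zero(self):
        assert fairness_variance(np.full(10, 0.37)) == 0.0

    def test_maximal_segmentation_scores_quarter(self):
        assert fairness_variance(np.array([0.0] * 5 + [1.0] * 5)) == 0.25

    def test_worked_example(self):
        # mean 0.5; squared deviations (0.09, 0.01, 0.01, 0.09); sum / 4
        assert fairness_variance(np.array([0.2, 0.4, 0.6, 0.8])) == pytest.approx(0.05)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            fairness_variance(np.array([]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fairness_variance(np.array([0.5, 1.5]))

    @given(p=hnp.arrays(float, st.integers(1, 50), elements=st.floats(0, 1)))
    def test_bounded_by_quarter(self, p):
        assert 0.0 <= fairness_variance(p) <= 0.25


class TestRunEnsemble:
    def test_same_base_seed_reproduces(self):
        a = run_ensemble(small_params(), 10, 42)
        b = run_ensemble(small_params(), 10, 42)
        assert np.array_equal(a.final_attendance, b.final_attendance)
        assert np.array_equal(a.fairness, b.fairness)

    def test_single_run_ensemble_degenerates(self):
        ens = run_ensemble(small_params(), 1, 0)
        s = summarize_ensemble(ens)
        assert len(ens.fairness) == 1
        assert s.var_attendance == 0.0 and s.var_fairness == 0.0

    def test_runs_match_standalone_substreams(self):
        # run k of an ensemble equals a standalone simulation on spawn key (k,)
        ens = run_ensemble(small_params(), 5, 7)
        for k in range(5):
            seq = np.random.SeedSequence(7, spawn_key=(k,))
            run = simulate_run(small_params(), np.random.default_rng(seq))
            assert ens.final_attendance[k] == run.final_attendance
            assert ens.fairness[k] == pytest.approx(
                fairness_variance(run.final_probs), abs=0
            )

    def test_zero_stepsize_fairness_matches_uniform_variance(self):
        # mu=0 freezes the U(0,1) initialization; the divisor-M variance of
        # M uniforms has expectation (1 - 1/M) * 1/12
        ens = run_ensemble(
            SimulationParams(n_agents=100, stepsize=0.0, horizon=5), 500, 3
        )
        se = ens.fairness.std() / np.sqrt(len(ens.fairness))
        assert abs(ens.fairness.mean() - (1 - 1 / 100) / 12) < 4 * se

    def test_invalid_n_runs(self):
        with pytest.raises(ValueError):
            run_ensemble(small_params(), 0, 1)


class TestSummaries:
    def test_hand_built_summary(self):
        ens = EnsembleResult(
            params=small_params(),
            n_runs=3,
            base_seed=0,
            final_attendance=np.array([59, 60, 61]),
            fairness=np.array([0.1, 0.1, 0.1]),
        )
        s = summarize_ensemble(ens)
        assert s.mean_attendance == 60.0
        assert s.var_attendance == pytest.approx(2 / 3)
        assert s.mean_fairness == pytest.approx(0.1)
        assert s.var_fairness == pytest.approx(0.0, abs=1e-30)


class TestCompareRegimes:
    def test_mismatched_params_rejected(self):
        partial = run_ensemble(small_params(regime="partial"), 3, 0)
        full = run_ensemble(small_params(regime="full", capacity=20), 3, 0)
        with pytest.raises(ValueError, match="differ"):
            compare_regimes(partial, full)

    def test_wrong_regime_roles_rejected(self):
        ens = run_ensemble(small_params(regime="partial"), 3, 0)
        with pytest.raises(ValueError):
            compare_regimes(ens, ens)

    def test_identical_distributions_show_no_dominance(self):
        partial = run_ensemble(small_params(regime="partial"), 5, 0)
        clone = EnsembleResult(
            params=small_params(regime="full"),
            n_runs=5,
            base_seed=0,
            final_attendance=partial.final_attendance,
            fairness=partial.fairness,
        )
        cmp = compare_regimes(partial, clone)
        assert not cmp.strict_dominance

    def test_zero_stepsize_regimes_are_equivalent(self):
        p = SimulationParams(n_agents=100, stepsize=0.0, horizon=5)
        partial = run_ensemble(p.replace(regime="partial"), 300, 1)
        full = run_ensemble(p.replace(regime="full"), 300, 2)
        cmp = compare_regimes(partial, full)
        pooled_se = np.hypot(
            partial.fairness.std() / np.sqrt(300), full.fairness.std() / np.sqrt(300)
        )
        assert abs(cmp.mean_fairness_partial - cmp.mean_fairness_full) < 4 * pooled_se
        assert not cmp.strict_dominance


class TestVariabilityProfile:
    def test_constant_series_has_zero_variance(self):
        run = simulate_run(small_params(), np.random.default_rng(0))
        frozen = type(run)(
            params=run.params,
            prob_history=run.prob_history,
            attendance_history=np.full(60, 7, dtype=np.int64),
        )
        assert attendance_variability_profile(frozen, 10) == (0.0, 0.0)

    def test_window_guard(self):
        run = simulate_run(small_params(), np.random.default_rng(0))
        with pytest.raises(ValueError):
            attendance_variability_profile(run, 31)

    def test_partial_information_volatility_declines(self, paper_params):
        # attendance variance shrinks as the population settles (early vs late)
        ratios = []
        for s in range(30):
            run = simulate_run(paper_params, np.random.default_rng(1000 + s))
            early, late = attendance_variability_profile(run, 50)
            ratios.append(late / early)
        assert np.median(ratios) < 1.0

    def test_full_information_volatility_persists(self, paper_params):
        ratios = []
        for s in range(30):
            run = simulate_run(
                paper_params.replace(regime="full"), np.random.default_rng(2000 + s)
            )
            early, late = attendance_variability_profile(run, 50)
            ratios.append(late / early)
        assert np.median(ratios) >= 0.5


class TestSegmentation:
    def test_partial_information_segments_population(self, paper_params):
        # partial info drives probabilities toward {0, 1}; full info does not
        frac_partial, frac_full = [], []
        for s in range(10):
            run_p = simulate_run(paper_params, np.random.default_rng(300 + s))
            run_f = simulate_run(
                paper_params.replace(regime="full"), np.random.default_rng(400 + s)
            )
            frac_partial.append(segmentation_fraction(run_p.final_probs))
            frac_full.append(segmentation_fraction(run_f.final_probs))
        assert np.mean(frac_partial) > np.mean(frac_full)


class TestSensitivitySweep:
    def test_degenerate_grid_matches_single_ensemble(self):
        base = small_params()
        table = sensitivity_sweep(base, [18], [0.02], 5, 99)
        cell_seed = np.random.SeedSequence(99, spawn_key=(0, 0))
        for regime in ("partial", "full"):
            expected = summarize_ensemble(
                run_ensemble(base.replace(regime=regime), 5, cell_seed)
            )
            row = table[table.regime == regime].iloc[0]
            assert row.mean_attendance == expected.mean_attendance
            assert row.mean_fairness == expected.mean_fairness

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_sweep(small_params(), [], [0.01], 2, 0)

    def test_capacity_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_sweep(small_params(), [31], [0.01], 2, 0)

    def test_attendance_tracks_capacity(self):
        # mean final attendance converges toward each capacity value
        base = SimulationParams(n_agents=100, horizon=300, regime="partial")
        table = sensitivity_sweep(
            base, [40, 60, 80], [0.01], 30, 5, regimes=("partial",)
        )
        for _, row in table.iterrows():
            se = np.sqrt(row.var_attendance / 30)
            assert abs(row.mean_attendance - row.capacity) < max(4 * se, 1.0)

    def test_larger_stepsize_accelerates_segmentation(self):
        # at a fixed horizon, a larger stepsize leaves a more unequal split
        base = SimulationParams(n_agents=100, horizon=300, regime="partial")
        table = sensitivity_sweep(
            base, [60], [0.005, 0.02], 30, 8, regimes=("partial",)
        )
        slow = table[table.stepsize == 0.005].iloc[0].mean_fairness
        fast = table[table.stepsize == 0.02].iloc[0].mean_fairness
        assert fast > slow
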