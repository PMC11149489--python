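"""Feedback-circuit population model: dynamics, sorting, perturbations."""

import dataclasses

import numpy as np
import pytest

from fluxsort import population_model as pm
from fluxsort.population_model import (
    FeedbackParams,
    MetabolicCoupling,
    apply_perturbation,
    chc_snapshot,
    fermentative_rate,
    init_population,
    insilico_sort,
    p_hlac_readout,
    relaxation_experiment,
    respiratory_rate,
    simulate,
    socs3_ko_fixed_point,
    step_population,
)
from fluxsort.ph_core import chc_shift

PARAMS = FeedbackParams()
COUPLING = MetabolicCoupling()


def _equilibrated(params, seed=0, n=400, hours=48.0, dt=0.5):
    rng = np.random.default_rng(seed)
    state = init_population(n, params, rng)
    simulate(state, params, COUPLING, hours * 60.0, dt, rng)
    return state


class TestIntegration:
    def test_identical_seeds_give_bit_identical_trajectories(self):
        a = _equilibrated(PARAMS, seed=7, n=100, hours=6.0)
        b = _equilibrated(PARAMS, seed=7, n=100, hours=6.0)
        assert np.array_equal(a.s, b.s)
        assert np.array_equal(a.c, b.c)
        assert a.ligand == b.ligand

    def test_homogeneous_population_stays_identical(self):
        p = dataclasses.replace(PARAMS, cv_params=0.0, sigma_noise=0.0)
        state = _equilibrated(p, n=100, hours=12.0)
        assert np.ptp(state.s) == 0.0
        high, low = insilico_sort(state, COUPLING, "p_hlac", 0.5, 0.5)
        f_hi = fermentative_rate(high, COUPLING).mean()
        f_lo = fermentative_rate(low, COUPLING).mean()
        assert f_hi == pytest.approx(f_lo)

    def test_step_size_guard(self):
        rng = np.random.default_rng(0)
        state = init_population(60, PARAMS, rng)
        with pytest.raises(ValueError, match="stability"):
            step_population(state, PARAMS, COUPLING, dt=5.0, rng=rng)

    def test_halving_dt_changes_day_scale_outputs_below_one_percent(self):
        p = dataclasses.replace(PARAMS, sigma_noise=0.0, theta_noise=0.0,
                                cv_params=0.3)
        means = []
        for dt in (0.5, 0.25):
            rng = np.random.default_rng(3)
            state = init_population(200, p, rng)
            simulate(state, p, COUPLING, 24.0 * 60.0, dt, rng)
            means.append(fermentative_rate(state, COUPLING).mean())
        assert abs(means[1] - means[0]) / means[0] < 0.01

    def test_stationarity_after_burn_in(self):
        # mean |drift| per simulated day, averaged over seeds so that
        # finite-size fluctuation of the population mean does not mask the
        # (absence of) systematic drift
        drifts = []
        for seed in range(4):
            rng = np.random.default_rng(seed)
            state = init_population(2000, PARAMS, rng)
            simulate(state, PARAMS, COUPLING, 48.0 * 60.0, 0.5, rng)
            f0 = fermentative_rate(state, COUPLING).mean()
            simulate(state, PARAMS, COUPLING, 24.0 * 60.0, 0.5, rng)
            f1 = fermentative_rate(state, COUPLING).mean()
            drifts.append(abs(f1 - f0) / f0)
        assert np.mean(drifts) < 0.02


class TestSocs3KnockoutFixedPoint:
    def test_matches_root_finding_oracle(self):
        # deterministic single cell with the SOCS3 arm removed converges to
        # the fixed point of the reduced system
        p = dataclasses.replace(
            apply_perturbation(PARAMS, "socs3_ko", 1.0),
            cv_params=0.0, sigma_noise=0.0, theta_noise=0.0,
        )
        rng = np.random.default_rng(0)
        state = init_population(1, p, rng)
        simulate(state, p, COUPLING, 72.0 * 60.0, 0.5, rng)
        assert state.s[0] == pytest.approx(socs3_ko_fixed_point(PARAMS), rel=1e-3)

    def test_ko_fixed_point_exceeds_wild_type_average(self):
        p_wt = dataclasses.replace(PARAMS, cv_params=0.0, sigma_noise=0.0,
                                   theta_noise=0.0)
        rng = np.random.default_rng(0)
        state = init_population(1, p_wt, rng)
        simulate(state, p_wt, COUPLING, 72.0 * 60.0, 0.5, rng)
        assert socs3_ko_fixed_point(PARAMS) > state.s[0]


class TestOscillation:
    # balanced three-stage relay with steep SOCS3 inhibition and slow delay
    # stages: the classic oscillatory regime of a transcript-mediated delay
    GOODWIN = FeedbackParams(
        h=12.0, k_deph=0.02, d_m=0.02, d_c=0.02, k_m=0.02, k_c=0.02,
        K_C=1.0, k_act=0.146, r1=0.0, r0=0.01, d_r=0.01,
        l0=0.01, l1=0.0, d_l=0.01, K_L=1e-4,
        sigma_noise=0.0, theta_noise=0.0, cv_params=0.0,
    )

    def _trajectory(self, params, hours=96.0):
        rng = np.random.default_rng(0)
        state = init_population(1, params, rng, equilibrate=False)
        state.s[:] = 1.0
        state.rcv[:] = 1.0
        state.m[:] = 0.5
        state.c[:] = 0.5
        state.ligand = 1.0
        tr = []
        for _ in range(int(hours * 60.0 / 0.5)):
            step_population(state, params, COUPLING, 0.5, rng)
            tr.append(state.s[0])
        return np.array(tr)

    def test_steep_slow_feedback_oscillates(self):
        tail = self._trajectory(self.GOODWIN)[-4800:]
        assert tail.max() / tail.min() > 1.5

    def test_removing_the_feedback_abolishes_oscillation(self):
        no_fb = dataclasses.replace(self.GOODWIN, k_m=0.0)
        tail = self._trajectory(no_fb)[-4800:]
        assert tail.max() / tail.min() < 1.01


class TestPerturbations:
    def test_zero_strength_is_identity(self):
        for kind in ("il6r_kd", "stat3_kd", "socs3_kd", "napabucasin"):
            assert apply_perturbation(PARAMS, kind, 0.0) == PARAMS

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            apply_perturbation(PARAMS, "mystery_drug", 0.5)

    def test_socs3_ko_forces_full_knockout(self):
        assert apply_perturbation(PARAMS, "socs3_ko", 0.3).k_m == 0.0

    def test_receptor_knockdown_lowers_fermentation_and_narrows_p_hlac(self):
        wt = _equilibrated(PARAMS, seed=1, n=300)
        kd = _equilibrated(apply_perturbation(PARAMS, "il6r_kd", 0.8), seed=1, n=300)
        f_wt = fermentative_rate(wt, COUPLING)
        f_kd = fermentative_rate(kd, COUPLING)
        assert f_kd.mean() < f_wt.mean()
        p_wt = p_hlac_readout(wt, COUPLING)
        p_kd = p_hlac_readout(kd, COUPLING)
        assert p_kd.std() < p_wt.std()
        # upper tail ablated
        assert np.quantile(p_kd, 0.95) < np.quantile(p_wt, 0.95)

    def test_stat3_knockdown_lowers_fermentation_and_receptor(self):
        wt = _equilibrated(PARAMS, seed=2, n=300)
        kd = _equilibrated(apply_perturbation(PARAMS, "stat3_kd", 0.8), seed=2, n=300)
        assert fermentative_rate(kd, COUPLING).mean() < fermentative_rate(wt, COUPLING).mean()
        assert kd.rcv.mean() < wt.rcv.mean()

    def test_socs3_removal_raises_pstat3(self):
        wt = _equilibrated(PARAMS, seed=3, n=300)
        ko = _equilibrated(apply_perturbation(PARAMS, "socs3_ko", 1.0), seed=3, n=300)
        assert ko.s.mean() > wt.s.mean()

    def test_il6_supplement_is_noop_under_saturation(self):
        wt = _equilibrated(PARAMS, seed=4, n=300)
        supp = _equilibrated(
            apply_perturbation(PARAMS, "il6_supplement", 1.0), seed=4, n=300
        )
        f_wt = fermentative_rate(wt, COUPLING).mean()
        f_supp = fermentative_rate(supp, COUPLING).mean()
        assert abs(f_supp - f_wt) / f_wt < 0.05


class TestSorting:
    def test_median_partition_with_distinct_values(self):
        state = _equilibrated(PARAMS, seed=5, n=200, hours=2.0)
        high, low = insilico_sort(state, COUPLING, "p_hlac", 0.5, 0.5)
        assert high.n_cells + low.n_cells == 200
        assert p_hlac_readout(high, COUPLING).min() >= p_hlac_readout(low, COUPLING).max()

    def test_sorted_readouts_are_monotone_linked(self):
        state = _equilibrated(PARAMS, seed=6, n=300, hours=2.0)
        high, low = insilico_sort(state, COUPLING, "p_hlac", 0.1, 0.1)
        assert fermentative_rate(high, COUPLING).mean() > fermentative_rate(low, COUPLING).mean()

    def test_il6r_sort_predicts_fermentative_rate_next_day(self):
        state = _equilibrated(PARAMS, seed=7, n=500, hours=24.0)
        high, low = insilico_sort(state, COUPLING, "il6r", 0.15, 0.15)
        rng_h, rng_l = np.random.default_rng(70), np.random.default_rng(71)
        simulate(high, PARAMS, COUPLING, 24.0 * 60.0, 0.5, rng_h)
        simulate(low, PARAMS, COUPLING, 24.0 * 60.0, 0.5, rng_l)
        assert fermentative_rate(high, COUPLING).mean() > fermentative_rate(low, COUPLING).mean()

    def test_small_population_rejected(self):
        state = init_population(40, PARAMS, np.random.default_rng(0))
        with pytest.raises(ValueError):
            insilico_sort(state, COUPLING, "p_hlac", 0.1, 0.1)


class TestRelaxation:
    def test_homogeneous_population_has_unit_contrast(self):
        p = dataclasses.replace(PARAMS, cv_params=0.0, sigma_noise=0.0)
        table = relaxation_experiment(
            p, COUPLING, sample_days=[0.5, 1.0], n_cells=100, seed=0,
            burn_in_h=4.0,
        )
        assert np.allclose(table["fold_f"], 1.0, atol=1e-9)

    def test_contrast_decays_toward_parity(self):
        table = relaxation_experiment(
            PARAMS, COUPLING, sample_days=[1, 4, 7], n_cells=800, seed=1,
            burn_in_h=48.0,
        )
        folds = table["fold_f"].to_numpy()
        assert folds[0] > 2.0          # strong contrast on day 1
        assert folds[-1] < 1.3         # collapsed by a week


class TestChcSnapshot:
    def test_zero_fermentation_means_zero_shift(self):
        state = init_population(60, PARAMS, np.random.default_rng(0))
        quiet = MetabolicCoupling(f_min=0.0, f_gain=0.0)
        pre, post = chc_snapshot(state, quiet)
        assert np.array_equal(pre, post)

    def test_shift_linear_in_duration(self):
        state = _equilibrated(PARAMS, seed=8, n=100, hours=2.0)
        _, post3 = chc_snapshot(state, COUPLING, duration_min=3.0)
        _, post6 = chc_snapshot(state, COUPLING, duration_min=6.0)
        assert np.allclose(7.3 - post6, 2.0 * (7.3 - post3))

    def test_socs3_ko_shows_larger_acid_shift(self):
        wt = _equilibrated(PARAMS, seed=9, n=500)
        ko = _equilibrated(apply_perturbation(PARAMS, "socs3_ko", 1.0), seed=9, n=500)
        res_wt = chc_shift(*chc_snapshot(wt, COUPLING))
        res_ko = chc_shift(*chc_snapshot(ko, COUPLING))
        assert res_ko.median_shift < res_wt.median_shift < 0
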