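"""Score function, Metropolis moves, schedules and multi-run machinery.

Full-scale recovery checks on the three-layer fixture live in
test_acceptance.py; here the runs use reduced models and tiny schedules."""

import numpy as np
import pytest

import reflift as rl
from reflift.anneal import (
    AnnealSchedule,
    Constraint,
    ScoreConfig,
    anneal_run,
    average_profiles,
    multi_run,
    propose_move,
    score,
)


@pytest.fixture(scope="module")
def small_setup():
    """A reduced problem (N=16, short curves) that anneals in ~1 s."""
    system = rl.three_layer_system()
    curves = rl.render_contrast_series(system, q_grid=np.geomspace(0.006, 0.25, 60))
    config = ScoreConfig(curves)
    return config, 170.0, 16


@pytest.fixture(scope="module")
def small_model(small_setup):
    config, D, N = small_setup
    rng = np.random.default_rng(0)
    return rl.InterfacialModel(
        D=D, rho=rng.uniform(0, 6e-6, N), h=rng.uniform(0, 1, N), sigma=4.0,
        q_max=max(c.q_max for c in config.contrasts),
    )


class TestScore:
    def test_self_consistency_is_zero(self, small_setup, small_model):
        config, D, N = small_setup
        ws = config.workspace(D, N)
        theory = ws.forward(small_model)
        curves = [
            rl.ContrastCurve(q=c.q, R=r, rho_fronting=c.rho_fronting,
                             rho_solvent=c.rho_solvent, dq_over_q=c.dq_over_q,
                             label=c.label)
            for c, r in zip(config.contrasts, theory)
        ]
        assert score(small_model, ScoreConfig(curves)) <= 1e-10

    def test_contrast_order_invariance(self, small_setup, small_model):
        config, D, N = small_setup
        f1 = score(small_model, config)
        perm = ScoreConfig(config.contrasts[::-1])
        assert score(small_model, perm) == pytest.approx(f1, rel=1e-12)

    def test_doubling_theory_increases_score(self, small_setup, small_model):
        config, D, N = small_setup
        ws = config.workspace(D, N)
        theory = ws.forward(small_model)
        for factor in (1.0, 2.0):
            curves = [
                rl.ContrastCurve(q=c.q, R=factor * r, rho_fronting=c.rho_fronting,
                                 rho_solvent=c.rho_solvent, label=c.label)
                for c, r in zip(config.contrasts, theory)
            ]
            f = score(small_model, ScoreConfig(curves))
            if factor == 1.0:
                f_ref = f
        assert f > f_ref + 0.1  # log term alone contributes (ln 2)^2

    def test_empty_contrast_list_rejected(self):
        with pytest.raises(ValueError):
            ScoreConfig([])

    def test_normalizers_are_mean_q4_weighted_curves(self, small_setup):
        config, _, _ = small_setup
        for c, norm in zip(config.contrasts, config.normalizers):
            assert norm == pytest.approx(np.mean(c.q**4 * c.R), rel=1e-12)


class TestProposeMove:
    def test_bounds_respected_over_many_proposals(self, small_model):
        rng = np.random.default_rng(11)
        lo, hi = rl.sigma_limits(small_model.q_max)
        for _ in range(10_000):
            trial = propose_move(small_model, rng)
            assert np.all(trial.rho >= small_model.rho_min)
            assert np.all(trial.rho <= small_model.rho_max)
            assert np.all((trial.h >= 0) & (trial.h <= 1))
            assert lo <= trial.sigma <= hi
            # exactly one parameter changed
            n_changed = (
                int(np.count_nonzero(trial.rho != small_model.rho))
                + int(np.count_nonzero(trial.h != small_model.h))
                + int(trial.sigma != small_model.sigma)
            )
            assert n_changed == 1

    def test_constrained_layers_never_selected(self, small_model):
        rng = np.random.default_rng(12)
        cons = [Constraint((0.0, 40.0), "fix_hydration", 0.0),
                Constraint((0.0, 21.0), "fix_sld", 3.5e-6)]
        frozen_h = small_model.h[:3].copy()  # centres 5.3, 15.9, 26.6, 37.2 A
        for _ in range(3000):
            trial = propose_move(small_model, rng, constraints=cons)
            np.testing.assert_array_equal(trial.h[:3], frozen_h)
            np.testing.assert_array_equal(trial.rho[:2], small_model.rho[:2])

    def test_move_mix_frequencies(self, small_model):
        rng = np.random.default_rng(13)
        mix = (0.5, 0.4, 0.1)
        counts = np.zeros(3, dtype=int)
        n = 20_000
        for _ in range(n):
            trial = propose_move(small_model, rng, move_mix=mix)
            if np.any(trial.rho != small_model.rho):
                counts[0] += 1
            elif np.any(trial.h != small_model.h):
                counts[1] += 1
            else:
                counts[2] += 1
        for k, p in enumerate(mix):
            sd = np.sqrt(n * p * (1 - p))
            assert abs(counts[k] - n * p) < 3 * sd

    def test_fully_constrained_model_rejected(self, small_setup):
        config, D, N = small_setup
        cons = [Constraint((0.0, D), "fix_hydration", 0.0),
                Constraint((0.0, D), "fix_sld", 2e-6)]
        with pytest.raises(ValueError):
            anneal_run(config, D, constraints=cons, N=N)


TINY = AnnealSchedule(t0=0.3, trials_per_layer=6, cooling=0.7, stop_rejections=60)


class TestAnnealRun:
    def test_reproducible_given_seed(self, small_setup):
        config, D, N = small_setup
        a = anneal_run(config, D, schedule=TINY, seed=21, N=N)
        b = anneal_run(config, D, schedule=TINY, seed=21, N=N)
        assert a.f == b.f
        np.testing.assert_array_equal(a.model.rho, b.model.rho)
        np.testing.assert_array_equal(a.model.h, b.model.h)
        assert a.model.sigma == b.model.sigma

    def test_best_score_trace_non_increasing(self, small_setup):
        # evaluated on a single engine sampling so scores are comparable
        # across the cooling and polish phases
        config, D, N = small_setup
        res = anneal_run(config, D, schedule=TINY, seed=22, N=N,
                         subdivide=1, search_subdivide=1)
        assert np.all(np.diff(res.trace["f_best"]) <= 1e-15)

    def test_greedy_limit_never_accepts_uphill(self, small_setup):
        config, D, N = small_setup
        sched = AnnealSchedule(t0=1e-15, trials_per_layer=6, cooling=0.9,
                               stop_rejections=60)
        res = anneal_run(config, D, schedule=sched, seed=23, N=N,
                         subdivide=1, search_subdivide=1)
        # at T ~ 0 the current score equals the best score at every step
        np.testing.assert_allclose(res.trace["f_current"], res.trace["f_best"])

    def test_sigma_stays_within_resolution_limits(self, small_setup):
        config, D, N = small_setup
        res = anneal_run(config, D, schedule=TINY, seed=24, N=N)
        lo, hi = config.workspace(D, N).sigma_limits
        assert lo <= res.model.sigma <= hi

    def test_constraints_hold_in_result(self, small_setup):
        config, D, N = small_setup
        cons = [Constraint((0.0, 40.0), "fix_hydration", 0.25)]
        res = anneal_run(config, D, constraints=cons, schedule=TINY, seed=25, N=N)
        np.testing.assert_array_equal(res.model.h[:3], 0.25)


class TestMultiRun:
    def test_single_run_passthrough(self, small_setup):
        config, D, N = small_setup
        best, results = multi_run(config, D, schedule=TINY, n_runs=1, N=N)
        assert len(results) == 1 and best is results[0]

    def test_best_not_worse_than_median(self, small_setup):
        config, D, N = small_setup
        best, results = multi_run(config, D, schedule=TINY, n_runs=5, N=N)
        fs = sorted(r.f for r in results)
        assert best.f == fs[0] <= np.median(fs)

    def test_distinct_seeds_give_independent_runs(self, small_setup):
        config, D, N = small_setup
        _, results = multi_run(config, D, schedule=TINY, n_runs=3, N=N,
                               seeds=[5, 6, 7])
        assert len({r.f for r in results}) == 3


class TestAverageProfiles:
    def test_identical_runs_have_zero_spread(self, small_setup):
        config, D, N = small_setup
        r = anneal_run(config, D, schedule=TINY, seed=30, N=N)
        avg = average_profiles([r, r], config.contrasts)
        np.testing.assert_allclose(avg.h_std, 0.0, atol=1e-15)
        np.testing.assert_allclose(avg.rho_std, 0.0, atol=1e-20)

    def test_mean_respects_hard_constraints(self, small_setup):
        config, D, N = small_setup
        cons = [Constraint((0.0, 40.0), "fix_hydration", 0.0)]
        _, results = multi_run(config, D, constraints=cons, schedule=TINY,
                               n_runs=3, N=N, seeds=[1, 2, 3])
        avg = average_profiles(results, config.contrasts, f_threshold=1e9)
        inner = (avg.z > 8.0) & (avg.z < 30.0)  # away from smeared edges
        assert np.all(avg.h_mean[inner] < 0.02)

    def test_single_qualifying_run_warns_and_returns_best(self, small_setup, caplog):
        config, D, N = small_setup
        _, results = multi_run(config, D, schedule=TINY, n_runs=3, N=N)
        import logging

        with caplog.at_level(logging.WARNING, logger="reflift.anneal"):
            avg = average_profiles(results, config.contrasts, f_threshold=0.0)
        assert len(avg.included_seeds) == 1
        assert any("within" in rec.message for rec in caplog.records)

    def test_no_results_rejected(self, small_setup):
        config, _, _ = small_setup
        with pytest.raises(ValueError):
            average_profiles([], config.contrasts)
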