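"""Greedy / lazy / exhaustive selection, bounds, and the frequency sweep."""

import itertools
import math

import numpy as np
import pytest

import infodesign as idn
from conftest import gaussian_point_preds, make_linear_class
from infodesign.design import (
    DesignSizeError,
    exhaustive_design,
    greedy_design,
    lazy_greedy_design,
    make_mi_objective,
    offline_bound,
)

LN2 = math.log(2)


def modular_objective(weights):
    """Injected toy objective: value of a selection is the sum of channel weights."""

    def fn(pairs):
        return float(sum(weights[p] for p in pairs))

    return fn


@pytest.fixture()
def toy_space():
    return idn.DesignSpace(times=np.arange(1.0, 7.0), readouts=["x"],
                           noise=idn.FixedNoise(1.0), budget=6)


@pytest.fixture(scope="module")
def quad_setup():
    """Two point-prediction models on a 6-channel pool, quadrature-exact MI."""
    hc = make_linear_class([-1.0, -0.5], x0_sd=0.0)
    sp = idn.DesignSpace(times=np.arange(1.0, 7.0), readouts=["x"],
                         noise=idn.FixedNoise(1.0), budget=6)
    rng = np.random.default_rng(42)
    means = rng.normal(0.0, 1.5, size=(2, 6))
    preds = gaussian_point_preds(means, model_ids=hc.model_ids)
    return hc, sp, preds


class TestGreedy:
    def test_modular_objective_recovers_top_k(self, toy_space):
        hc = make_linear_class([-1.0, -0.5])
        weights = {(i, 0): w for i, w in enumerate([0.3, 1.2, 0.1, 0.9, 0.5, 0.7])}
        res = greedy_design(hc, [None, None], toy_space, budget=3,
                            objective=modular_objective(weights))
        assert set(res.selection.pairs) == {(1, 0), (3, 0), (5, 0)}
        assert res.total.value == pytest.approx(1.2 + 0.9 + 0.7)
        np.testing.assert_allclose(sorted(res.incremental_gains, reverse=True), [1.2, 0.9, 0.7])
        # online bound: achieved + top-3 remaining gains, by hand
        assert res.online_bound == pytest.approx(2.8 + (0.5 + 0.3 + 0.1))

    def test_budget_one_equals_exhaustive(self, quad_setup):
        hc, sp, preds = quad_setup
        obj = make_mi_objective(hc, preds, sp, k_max=2, estimator="quadrature")
        g = greedy_design(hc, preds, sp, budget=1, objective=obj)
        sel, val = exhaustive_design(hc, preds, sp, budget=1, objective=obj)
        assert g.selection.pairs == sel.pairs
        assert g.total.value == pytest.approx(val)

    def test_seed_determinism_bit_for_bit(self, bergman_class, bergman_space, bergman_preds):
        a = greedy_design(bergman_class, bergman_preds, bergman_space, budget=2,
                          n_outer=300, seed=11)
        b = greedy_design(bergman_class, bergman_preds, bergman_space, budget=2,
                          n_outer=300, seed=11)
        assert a.selection.pairs == b.selection.pairs
        np.testing.assert_array_equal(a.incremental_gains, b.incremental_gains)

    def test_gains_sum_to_total(self, bergman_class, bergman_space, bergman_preds):
        res = greedy_design(bergman_class, bergman_preds, bergman_space, budget=3,
                            n_outer=300, seed=1)
        assert res.incremental_gains.sum() == pytest.approx(res.total.value, abs=1e-12)
        assert len(res.selection) == 3  # always spends the full budget


class TestLazyGreedy:
    def test_matches_greedy_on_modular_objective(self, toy_space):
        hc = make_linear_class([-1.0, -0.5])
        weights = {(i, 0): w for i, w in enumerate([0.3, 1.2, 0.1, 0.9, 0.5, 0.7])}
        g = greedy_design(hc, [None, None], toy_space, budget=4, objective=modular_objective(weights))
        l = lazy_greedy_design(hc, [None, None], toy_space, budget=4, objective=modular_objective(weights))
        assert g.selection.pairs == l.selection.pairs

    def test_matches_greedy_with_quadrature(self, quad_setup):
        hc, sp, preds = quad_setup
        g = greedy_design(hc, preds, sp, budget=2,
                          objective=make_mi_objective(hc, preds, sp, 3, estimator="quadrature"))
        l = lazy_greedy_design(hc, preds, sp, budget=2,
                               objective=make_mi_objective(hc, preds, sp, 3, estimator="quadrature"))
        assert g.selection.pairs == l.selection.pairs

    def test_never_more_evaluations_than_greedy(self, bergman_class, bergman_space, bergman_preds):
        g = greedy_design(bergman_class, bergman_preds, bergman_space, budget=3, n_outer=400, seed=2)
        l = lazy_greedy_design(bergman_class, bergman_preds, bergman_space, budget=3, n_outer=400, seed=2)
        assert l.evaluations <= g.evaluations
        assert l.selection.pairs == g.selection.pairs


class TestExhaustive:
    def test_budget_equals_pool_returns_everything(self, quad_setup):
        hc, sp, preds = quad_setup
        obj = make_mi_objective(hc, preds, sp, 7, n_outer=200, seed=0)
        sel, _ = exhaustive_design(hc, preds, sp, budget=6, objective=obj)
        assert set(sel.pairs) == set(sp.all_pairs())

    def test_matches_independent_nested_loop_oracle(self, quad_setup):
        hc, sp, preds = quad_setup
        obj = make_mi_objective(hc, preds, sp, 3, estimator="quadrature")
        sel, val = exhaustive_design(hc, preds, sp, budget=2, objective=obj)
        # independently coded brute force over all unordered pairs
        best_val, best_combo = -np.inf, None
        for combo in itertools.combinations(sp.all_pairs(), 2):
            v = idn.mi_quadrature(hc, preds, idn.Experiment(list(combo)), sp)
            if v > best_val:
                best_val, best_combo = v, combo
        assert val == pytest.approx(best_val, abs=1e-9)
        assert set(sel.pairs) == set(best_combo)

    def test_optimum_at_least_greedy(self, quad_setup):
        hc, sp, preds = quad_setup
        obj = make_mi_objective(hc, preds, sp, 3, estimator="quadrature")
        g = greedy_design(hc, preds, sp, budget=2, objective=obj)
        _, val = exhaustive_design(hc, preds, sp, budget=2, objective=obj)
        assert val >= g.total.value - 1e-12

    def test_cap_refusal(self, bergman_class, bergman_preds):
        sp = idn.bergman_design_space(n_times=20, budget=5)
        with pytest.raises(DesignSizeError, match="15504"):
            exhaustive_design(bergman_class, bergman_preds, sp, budget=5, cap=10_000)


class TestBounds:
    def test_offline_bound_arithmetic(self, toy_space):
        hc = make_linear_class([-1.0, -0.5])
        weights = {(i, 0): 0.0 for i in range(6)}
        res = greedy_design(hc, [None, None], toy_space, budget=2, objective=modular_objective(weights))
        assert offline_bound(res) == 0.0
        weights = {(i, 0): (1.0 if i == 0 else 0.0) for i in range(6)}
        res = greedy_design(hc, [None, None], toy_space, budget=1, objective=modular_objective(weights))
        assert offline_bound(res) == pytest.approx(math.e / (math.e - 1.0))

    def test_online_equals_achieved_when_pool_exhausted(self):
        hc = make_linear_class([-1.0, -0.5])
        sp = idn.DesignSpace(times=np.array([1.0, 2.0]), readouts=["x"],
                             noise=idn.FixedNoise(1.0), budget=2)
        weights = {(0, 0): 0.4, (1, 0): 0.2}
        res = greedy_design(hc, [None, None], sp, budget=2, objective=modular_objective(weights))
        assert res.online_bound == pytest.approx(res.total.value)

    def test_sandwich_on_oracle_verified_instances(self, quad_setup):
        hc, sp, preds = quad_setup
        obj = make_mi_objective(hc, preds, sp, 3, estimator="quadrature")
        g = greedy_design(hc, preds, sp, budget=2, objective=obj)
        _, opt = exhaustive_design(hc, preds, sp, budget=2, objective=obj)
        assert g.total.value <= opt + 1e-12
        assert opt <= min(g.online_bound, g.offline_bound) + 1e-9


class TestFrequencySweep:
    def test_single_frequency_self_normalizes(self, bergman_class, bergman_space):
        prob = idn.ExperimentDesign(bergman_class, bergman_space, n_outer=300)
        df = prob.frequency_sweep([0.1], window=(0.0, 60.0), seed=0)
        assert df["normalized"].iloc[0] == pytest.approx(1.0)

    def test_curve_saturates_with_diminishing_returns(self, bergman_class, bergman_space):
        prob = idn.ExperimentDesign(bergman_class, bergman_space, n_outer=800)
        df = prob.frequency_sweep([0.05, 0.1, 0.2, 0.5], window=(0.0, 180.0), seed=1)
        vals = df["mi_nats"].to_numpy()
        ses = df["std_error"].to_numpy()
        # non-decreasing within combined estimator error
        for a, b, sa, sb in zip(vals[:-1], vals[1:], ses[:-1], ses[1:]):
            assert b >= a - 3 * (sa + sb)
        # diminishing returns: later doublings add less than the first
        assert (vals[1] - vals[0]) > (vals[3] - vals[2]) - 3 * (ses[0] + ses[3])
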