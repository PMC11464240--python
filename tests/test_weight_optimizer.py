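"""weight_optimizer: objectives, simplex search, consensus, relevance."""

import numpy as np
import pytest

from vitalfit.glm_engine import build_design, fit_logistic
from vitalfit.indicators import WeightVector
from vitalfit.records_io import ATTRIBUTES
from vitalfit.synthetic_data import generate
from vitalfit.weight_optimizer import (
    METHOD_REGISTRY,
    check_consistency,
    classify_relevance,
    fish_objective,
    optimize_weights,
    snap_weights,
    softmax,
    trip_objective,
)

from conftest import make_recordset, random_recordset, single_attribute_config


@pytest.fixture(scope="module")
def causal_rs():
    """n=2000 synthetic fish where only bruising-body drives mortality."""
    rs, truth = generate(single_attribute_config("bruising_body", 2.0, 2000), 3)
    return rs


class TestRegistry:
    def test_twelve_named_methods(self):
        assert len(METHOD_REGISTRY) == 12
        for name in ("Nelder-Mead", "BFGS", "CG", "L-BFGS-B", "ucminf", "nlm",
                     "nlminb", "spg", "bobyqa", "newuoa", "nmkb", "hjkb"):
            assert name in METHOD_REGISTRY

    def test_unknown_method_rejected(self, rng):
        rs = random_recordset(rng, 60)
        with pytest.raises(ValueError, match="unknown method"):
            optimize_weights(rs, "none", "fish", methods=["gradient-descent"])

    def test_empty_method_list_rejected(self, rng):
        rs = random_recordset(rng, 60)
        with pytest.raises(ValueError, match="empty"):
            optimize_weights(rs, "none", "fish", methods=[])


class TestSimplexMapping:
    def test_softmax_of_zeros_is_uniform(self):
        np.testing.assert_allclose(softmax(np.zeros(10)), 0.1)

    def test_snap_zeroes_small_weights_and_renormalizes(self):
        w = np.r_[0.001, 0.499, np.full(8, 0.0625)]
        snapped = snap_weights(w)
        assert snapped[0] == 0.0
        assert snapped.sum() == pytest.approx(1.0)


class TestObjectives:
    def test_uniform_weights_reduce_to_plain_ri_model(self, rng):
        rs = random_recordset(rng, 150)
        aic_ri = fit_logistic(build_design(rs, "RI", "none")).aic
        assert fish_objective(WeightVector.uniform(), rs) == aic_ri

    def test_attribute_permutation_symmetry(self, rng):
        rs = random_recordset(rng, 150)
        i, j = ATTRIBUTES.index("righting"), ATTRIBUTES.index("point_head")
        w = np.linspace(0.05, 0.15, 10)
        w = w / w.sum()
        base = fish_objective(w, rs)
        # swap the two attributes in both the weights and the data
        w2 = w.copy()
        w2[[i, j]] = w2[[j, i]]
        rs2 = rs.copy()
        cols = [ATTRIBUTES[i], ATTRIBUTES[j]]
        rs2.df[cols] = rs2.df[cols[::-1]].to_numpy()
        assert fish_objective(w2, rs2) == pytest.approx(base, abs=1e-9)

    def test_trip_error_zero_for_perfect_structure(self):
        # trips fully determined by one attribute -> near-perfect fit is
        # possible, but the generic lower bound is simply 0
        pred = np.array([0.6, 0.4])
        obs = np.array([0.5, 0.5])
        assert np.mean(np.abs(pred - obs)) == pytest.approx(0.1)

    def test_trip_error_closed_form_with_constant_index(self):
        # all attributes identical -> the index is constant and the inner
        # model reduces to an intercept; predictions equal the overall
        # mortality rate, so the error has a closed form from trip rates
        trips = ["T01"] * 5 + ["T02"] * 10 + ["T03"] * 5
        mortality = [1, 1, 1, 1, 0] + [0] * 10 + [1, 0, 0, 0, 0]
        rs = make_recordset(np.zeros((20, 10)), mortality, trips=trips)
        overall_surv = 1 - np.mean(mortality)
        trip_surv = np.array([1 - 4 / 5, 1.0, 1 - 1 / 5])
        expected = np.mean(np.abs(overall_surv - trip_surv))
        got = trip_objective(WeightVector.uniform(), rs)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_trip_objective_needs_two_trips(self, rng):
        rs = random_recordset(rng, 40, n_trips=1)
        with pytest.raises(ValueError, match="2 trips"):
            trip_objective(WeightVector.uniform(), rs)


@pytest.fixture(scope="module")
def results(causal_rs):
    return optimize_weights(
        causal_rs, "none", "fish",
        methods=["L-BFGS-B", "bobyqa", "spg"], max_evaluations=1500)


class TestOptimizeWeights:
    def test_descent_contract(self, results):
        for r in results:
            if r.converged:
                assert r.objective <= r.start_objective + 1e-9

    def test_stored_objective_is_fresh(self, causal_rs, results):
        for r in results:
            recomputed = fish_objective(r.weights, causal_rs)
            assert recomputed == pytest.approx(r.objective, abs=1e-9)

    def test_causal_attribute_gets_largest_weight(self, results):
        idx = ATTRIBUTES.index("bruising_body")
        for r in results:
            if r.converged:
                assert np.argmax(r.weights.weights) == idx

    def test_weights_stay_on_simplex(self, results):
        for r in results:
            w = r.weights.weights
            assert (w >= 0).all()
            assert w.sum() == pytest.approx(1.0, abs=0.015)


class TestConsistency:
    def _result(self, w, objective=100.0, converged=True, method="BFGS",
                wall_time=0.1):
        from vitalfit.weight_optimizer import OptimizationResult
        return OptimizationResult(
            method=method, level="fish", covariate_set="none",
            weights=WeightVector(np.asarray(w)), objective=objective,
            start_objective=200.0, converged=converged, n_evaluations=10,
            wall_time=wall_time)

    def test_identical_results_trusted(self):
        w = np.full(10, 0.1)
        rep = check_consistency([self._result(w), self._result(w, method="CG")])
        assert rep.status == "trusted"
        assert rep.max_linf == 0.0

    def test_disagreement_not_trusted(self):
        w1 = np.full(10, 0.1)
        w2 = np.r_[0.3, np.full(9, 0.7 / 9)]
        rep = check_consistency([self._result(w1),
                                 self._result(w2, method="CG")])
        assert rep.status == "not_trusted"

    def test_single_converged_is_insufficient(self):
        rep = check_consistency([
            self._result(np.full(10, 0.1)),
            self._result(np.full(10, 0.1), converged=False, method="CG")])
        assert rep.status == "insufficient"
        assert rep.best is not None

    def test_best_is_lowest_objective_then_fastest(self):
        w = np.full(10, 0.1)
        rep = check_consistency([
            self._result(w, objective=120.0, method="BFGS", wall_time=0.1),
            self._result(w, objective=110.0, method="CG", wall_time=9.0),
            self._result(w, objective=110.0, method="spg", wall_time=0.5),
        ])
        assert rep.best.method == "spg"


class TestRelevance:
    @pytest.mark.parametrize("weight, wall, threshold, expected", [
        (0.10, 0.1, 10.0, "little"),     # at the uniform average
        (0.04, 0.1, 10.0, "little"),
        (0.18, 0.1, 10.0, "medium"),
        (0.20, 0.1, 10.0, "medium"),     # boundary stays medium
        (0.24, 0.1, 10.0, "high"),
        (0.30, 0.1, 10.0, "high"),
        (0.35, 99.0, 10.0, "outlier"),   # large and slow
        (0.35, 0.1, 10.0, "high"),       # large but fast
    ])
    def test_classes(self, weight, wall, threshold, expected):
        assert classify_relevance(weight, wall, threshold) == expected

    def test_invalid_weight(self):
        with pytest.raises(ValueError):
            classify_relevance(1.2)
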