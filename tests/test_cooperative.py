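"""Cooperative objective and joint fitting."""

import dataclasses
import warnings

import numpy as np
import pytest

import coophaz as ch
from coophaz.cooperative import (CoopConfig, agreement_term, coop_objective,
                                 default_rho, pair_indices)
from coophaz.cox import FitOptions
from coophaz.exceptions import DataError

from conftest import brute_force_pll, make_layer, make_outcome

OPTS = FitOptions(on_nonconvergence="warn", allow_constant=True)


def two_layer_problem(seed=5, n=40, p=3):
    r = np.random.default_rng(seed)
    Z1 = r.normal(size=(n, p))
    Z2 = r.normal(size=(n, p))
    ages = np.exp(-0.7 * Z1[:, 0] - 0.5 * Z2[:, 0]
                  + 0.4 * r.normal(size=n)) + 1
    events = r.integers(0, 2, n)
    events[:4] = 1
    out = make_outcome(ages, events)
    l1 = make_layer(Z1, name="g")
    l2 = make_layer(Z2, name="m")
    bh = [ch.fit_unpenalized(l1, out, OPTS), ch.fit_unpenalized(l2, out, OPTS)]
    return [l1, l2], out, bh


@pytest.fixture(scope="module")
def problem():
    return two_layer_problem()


class TestCoopObjective:
    def test_identical_layers_and_betas_zero_agreement(self, problem):
        layers, out, bh = problem
        twin = make_layer(layers[0].values, name="g2")
        assert agreement_term([layers[0], twin],
                              [np.array([1.0, -0.5, 0.2])] * 2) == 0.0

    def test_rho_zero_separates_into_cox_lasso_objectives(self, problem):
        layers, out, bh = problem
        r = np.random.default_rng(0)
        betas = [r.normal(size=3), r.normal(size=3)]
        cfg = CoopConfig(rho=0.0, lam=0.13)
        joint = coop_objective(layers, betas, bh, out, cfg)
        parts = sum(ch.cox_lasso_objective(layer, b, out, 0.13, h)
                    for layer, b, h in zip(layers, betas, bh))
        assert joint == pytest.approx(parts, abs=1e-12)

    def test_single_layer_reduces_to_cox_lasso(self, problem):
        layers, out, bh = problem
        beta = np.array([0.3, -0.2, 0.5])
        cfg = CoopConfig(rho=2.0, lam=0.07)
        joint = coop_objective([layers[0]], [beta], [bh[0]], out, cfg)
        assert joint == pytest.approx(
            ch.cox_lasso_objective(layers[0], beta, out, 0.07, bh[0]),
            abs=1e-12)

    def test_hand_assembled_toy_value(self):
        Z1 = np.array([[1.0], [0.0], [2.0]])
        Z2 = np.array([[0.5], [1.0], [0.0]])
        ages = np.array([1.0, 2.0, 3.0])
        events = np.array([1, 1, 0])
        out = make_outcome(ages, events)
        l1, l2 = make_layer(Z1, name="a"), make_layer(Z2, name="b")
        b1, b2 = np.array([0.4]), np.array([-0.3])
        h1, h2 = np.array([2.0]), np.array([0.5])
        lam, rho = 0.11, 0.7
        expected = (
            -(brute_force_pll(Z1, ages, events, b1)
              + brute_force_pll(Z2, ages, events, b2)) / 3
            + rho / 2 * float(((Z1 @ b1 - Z2 @ b2) ** 2).sum())
            + lam * (abs(0.4 / 2.0) + abs(-0.3 / 0.5)))
        cfg = CoopConfig(rho=rho, lam=lam)
        assert coop_objective([l1, l2], [b1, b2], [h1, h2], out, cfg) == \
            pytest.approx(expected, abs=1e-12)

    def test_mismatched_samples_name_the_layer(self, problem):
        layers, out, bh = problem
        bad = make_layer(layers[1].values, name="m", prefix="other")
        with pytest.raises(DataError, match="'m'"):
            coop_objective([layers[0], bad], [np.zeros(3)] * 2, bh, out,
                           CoopConfig())

    def test_pair_schemes(self):
        assert pair_indices(3, "all_pairs") == [(0, 1), (0, 2), (1, 2)]
        assert pair_indices(3, "chain") == [(0, 1), (1, 2)]
        assert default_rho(2) == 1.0 and default_rho(3) == 0.5


class TestFitCooperative:
    def test_rho_zero_matches_per_layer_cox_lasso(self, problem):
        layers, out, bh = problem
        lam = 0.05
        cfg = CoopConfig(rho=0.0, lam=lam, fit_options=OPTS)
        model = ch.fit_cooperative(layers, out, cfg, beta_hats=bh)
        separate = sum(ch.fit_cox_lasso(layer, out, lam, h, OPTS).objective
                       for layer, h in zip(layers, bh))
        assert model.objective == pytest.approx(separate, abs=1e-6)

    def test_duplicated_layer_fits_agree(self, problem):
        layers, out, bh = problem
        twin = make_layer(layers[0].values, name="g2")
        cfg = CoopConfig(rho=1.0, lam=0.01, fit_options=OPTS)
        model = ch.fit_cooperative([layers[0], twin], out, cfg,
                                   beta_hats=[bh[0], bh[0]])
        b1, b2 = (cv.beta for cv in model.coefficients)
        cosine = b1 @ b2
        assert cosine > 0.99

    def test_disagreement_non_increasing_in_rho(self, problem):
        layers, out, bh = problem
        values = []
        x0 = None
        for rho in [0.0, 0.5, 1.0, 2.0]:
            cfg = CoopConfig(rho=rho, lam=0.01, fit_options=OPTS,
                             warm_start=False)
            model = ch.fit_cooperative(layers, out, cfg, beta_hats=bh,
                                       x0=x0)
            raws = [cv.raw for cv in model.coefficients]
            if x0 is None:
                x0 = np.concatenate(raws)
            values.append(agreement_term(layers, raws))
        assert all(a >= b - 1e-6 for a, b in zip(values, values[1:]))

    def test_objective_not_above_start(self, problem):
        layers, out, bh = problem
        cfg = CoopConfig(rho=1.0, lam=0.02, fit_options=OPTS,
                         warm_start=False)
        model = ch.fit_cooperative(layers, out, cfg, beta_hats=bh)
        at_zero = coop_objective(layers, [np.zeros(3), np.zeros(3)], bh,
                                 out, dataclasses.replace(cfg))
        assert model.objective <= at_zero + 1e-12

    def test_layer_order_invariance_all_pairs(self, problem):
        layers, out, bh = problem
        cfg = CoopConfig(rho=1.0, lam=0.02, fit_options=OPTS)
        m_ab = ch.fit_cooperative(layers, out, cfg, beta_hats=bh)
        m_ba = ch.fit_cooperative(layers[::-1], out, cfg,
                                  beta_hats=bh[::-1])
        assert m_ab.objective == pytest.approx(m_ba.objective, abs=1e-6)

    def test_unit_norm_and_baseline_invariants(self, problem):
        layers, out, bh = problem
        model = ch.fit_cooperative(
            layers, out, CoopConfig(rho=1.0, lam=0.01, fit_options=OPTS),
            beta_hats=bh)
        for cv in model.coefficients:
            assert abs(np.linalg.norm(cv.beta) - 1) < 1e-10
        assert np.all(np.diff(model.baseline.values) >= 0)
        assert model.config.rho == 1.0


class TestCrossValidateLambda:
    def test_single_grid_value_is_chosen(self, problem):
        layers, out, bh = problem
        cfg = CoopConfig(rho=1.0, fit_options=OPTS)
        res = ch.cross_validate_lambda(layers, out, cfg, [0.02], k=3,
                                       seed=0)
        assert res.chosen_lambda == 0.02
        assert res.fold_scores.shape == (3, 1)

    def test_fold_assignment_reproducible(self, problem):
        layers, out, bh = problem
        cfg = CoopConfig(rho=1.0, fit_options=OPTS)
        r1 = ch.cross_validate_lambda(layers, out, cfg, [0.01, 0.3], k=3,
                                      seed=7)
        r2 = ch.cross_validate_lambda(layers, out, cfg, [0.01, 0.3], k=3,
                                      seed=7)
        assert np.array_equal(r1.fold_scores, r2.fold_scores)
        assert r1.chosen_lambda == r2.chosen_lambda

    def test_pure_noise_layers_prefer_max_shrinkage(self):
        wins = 0
        reps = 20
        for rep in range(reps):
            r = np.random.default_rng(100 + rep)
            n = 40
            layers = [make_layer(r.normal(size=(n, 2)), name="n1"),
                      make_layer(r.normal(size=(n, 2)), name="n2")]
            out = make_outcome(r.uniform(1, 10, n),
                               r.integers(0, 2, n) | (r.random(n) < 0.5))
            cfg = CoopConfig(rho=1.0, fit_options=OPTS)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = ch.cross_validate_lambda(layers, out, cfg,
                                               [1e-4, 0.03, 1.0], k=4,
                                               seed=rep)
            wins += res.chosen_lambda == 1.0
        assert wins > reps / 2


class TestLayerWeights:
    def test_single_layer_weight_one(self, problem):
        layers, out, bh = problem
        model = ch.fit_cooperative(
            [layers[0]], out, CoopConfig(lam=0.01, fit_options=OPTS),
            beta_hats=[bh[0]])
        assert ch.layer_weights(model, [layers[0]], out) == \
            pytest.approx([1.0])

    def test_duplicated_layers_split_evenly(self, problem):
        layers, out, bh = problem
        twin = make_layer(layers[0].values, name="g2")
        model = ch.fit_cooperative(
            [layers[0], twin], out,
            CoopConfig(rho=1.0, lam=0.01, fit_options=OPTS),
            beta_hats=[bh[0], bh[0]])
        w = ch.layer_weights(model, [layers[0], twin], out)
        assert w == pytest.approx([0.5, 0.5], abs=0.02)

    def test_constant_predictor_gets_zero_weight(self, problem):
        layers, out, bh = problem
        model = ch.fit_cooperative(
            layers, out, CoopConfig(rho=0.0, lam=0.01, fit_options=OPTS),
            beta_hats=bh)
        zeroed = dataclasses.replace(
            model, coefficients=[
                model.coefficients[0],
                dataclasses.replace(model.coefficients[1],
                                    beta=np.zeros(3), normalized=False)])
        w = ch.layer_weights(zeroed, layers, out)
        assert w == pytest.approx([1.0, 0.0])
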