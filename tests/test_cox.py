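"""Single-layer Cox machinery against hand values and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import coophaz as ch
from coophaz.cox import FitOptions, PLLContext
from coophaz.exceptions import ConvergenceError, DataError

from conftest import (brute_force_conditional, brute_force_pll, make_layer,
                      make_outcome)


class TestPartialLogLikelihood:
    @pytest.mark.parametrize("beta,expected", [
        ([0.0], -np.log(2)),
        ([1.0], 1 - np.log(1 + np.e)),
    ])
    def test_two_sample_hand_values(self, beta, expected):
        layer = make_layer([[1.0], [0.0]])
        out = make_outcome([1.0, 2.0], [1, 1])
        assert ch.partial_log_likelihood(layer, np.array(beta), out) == \
            pytest.approx(expected, abs=1e-12)

    def test_all_censored_is_zero_with_warning(self):
        layer = make_layer([[1.0], [0.0], [2.0]])
        out = make_outcome([1.0, 2.0, 3.0], [0, 0, 0])
        with pytest.warns(UserWarning, match="no events"):
            assert ch.partial_log_likelihood(layer, [0.5], out) == 0.0

    def test_matches_brute_force_enumeration(self, rng):
        from conftest import random_instance
        for _ in range(100):
            Z, ages, events, beta = random_instance(rng)
            layer = make_layer(Z)
            out = make_outcome(ages, events)
            assert ch.partial_log_likelihood(layer, beta, out) == \
                pytest.approx(brute_force_pll(Z, ages, events, beta),
                              abs=1e-12)

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_invariant_under_sample_permutation(self, seed):
        r = np.random.default_rng(seed)
        from conftest import random_instance
        Z, ages, events, beta = random_instance(r)
        base = ch.partial_log_likelihood(make_layer(Z),
                                         beta, make_outcome(ages, events))
        perm = r.permutation(len(ages))
        permuted = ch.partial_log_likelihood(
            make_layer(Z[perm]), beta, make_outcome(ages[perm], events[perm]))
        assert permuted == pytest.approx(base, abs=1e-10)

    def test_dimension_mismatch_raises(self):
        layer = make_layer([[1.0], [0.0]])
        out = make_outcome([1.0, 2.0], [1, 1])
        with pytest.raises(DataError):
            ch.partial_log_likelihood(layer, [1.0, 2.0], out)


class TestConditionalLikelihood:
    def test_null_beta_two_samples(self):
        layer = make_layer([[1.0], [0.0]])
        out = make_outcome([1.0, 2.0], [1, 1])
        assert ch.conditional_partial_likelihood(layer, [0.0], out) == \
            pytest.approx(-np.log(2), abs=1e-12)

    def test_null_beta_is_log_n_factorial(self):
        n = 6
        layer = make_layer(np.zeros((n, 1)))
        out = make_outcome(np.arange(1.0, n + 1), np.ones(n, dtype=int))
        expected = -sum(np.log(r) for r in range(1, n + 1))
        assert ch.conditional_partial_likelihood(layer, [0.0], out) == \
            pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("risk_set", ["at_risk", "as_printed"])
    def test_matches_brute_force(self, rng, risk_set):
        from conftest import random_instance
        for _ in range(100):
            Z, ages, events, beta = random_instance(rng)
            got = ch.conditional_partial_likelihood(
                make_layer(Z), beta, make_outcome(ages, events), risk_set)
            want = brute_force_conditional(Z, ages, events, beta, risk_set)
            assert got == pytest.approx(want, abs=1e-12)


class TestFitUnpenalized:
    def test_unit_norm_contract(self, rng):
        Z = rng.normal(size=(12, 2))
        layer = make_layer(Z)
        out = make_outcome(rng.uniform(1, 10, 12),
                           [1, 0, 1, 1, 0, 1, 0, 1, 1, 0, 1, 1])
        cv = ch.fit_unpenalized(layer, out)
        assert abs(np.linalg.norm(cv.beta) - 1) < 1e-10
        assert cv.raw is not None

    def test_planted_positive_effect_recovers_sign(self, rng):
        # high covariate -> early event: positive hazard coefficient
        n = 40
        z = rng.normal(size=n)
        ages = 10 - 2 * z + rng.normal(0, 0.5, n)
        ages = ages - ages.min() + 1
        cv = ch.fit_unpenalized(make_layer(z[:, None]),
                                make_outcome(ages, np.ones(n, dtype=int)))
        assert cv.beta[0] > 0

    def test_beats_dense_grid_oracle(self, rng):
        Z = rng.normal(size=(5, 1))
        layer = make_layer(Z)
        out = make_outcome([3.0, 1.0, 4.0, 2.0, 5.0], [1, 1, 0, 1, 1])
        cv = ch.fit_unpenalized(layer, out)
        best_fit = ch.partial_log_likelihood(layer, cv.raw, out)
        grid = np.linspace(-10, 10, 4001)
        ctx = PLLContext(out)
        grid_vals = ctx.partial_loglik(layer.values @ grid[None, :])
        assert best_fit >= grid_vals.max() - 1e-8

    def test_matches_lifelines_on_well_posed_data(self, rng):
        lifelines = pytest.importorskip("lifelines")
        n = 60
        Z = rng.normal(size=(n, 2))
        ages = np.sort(rng.uniform(1, 20, n))  # distinct with prob 1
        events = rng.integers(0, 2, n)
        events[:3] = 1
        cv = ch.fit_unpenalized(make_layer(Z), make_outcome(ages, events))
        import pandas as pd
        df = pd.DataFrame({"T": ages, "E": events, "x0": Z[:, 0],
                           "x1": Z[:, 1]})
        cph = lifelines.CoxPHFitter()
        cph.fit(df, duration_col="T", event_col="E")
        ref = cph.params_.to_numpy()
        assert np.allclose(cv.raw, ref, atol=1e-3)

    def test_constant_column_raises_with_name(self, rng):
        Z = np.column_stack([rng.normal(size=6), np.full(6, 2.0)])
        layer = make_layer(Z)
        out = make_outcome(np.arange(1.0, 7.0), [1, 0, 1, 1, 0, 1])
        with pytest.raises(DataError, match="f1"):
            ch.fit_unpenalized(layer, out)

    def test_nonconvergence_raises_with_iterate(self):
        # separable single covariate: monotone likelihood, no finite max
        z = np.arange(6, dtype=float)
        ages = np.arange(1.0, 7.0)[::-1]
        out = make_outcome(ages, np.ones(6, dtype=int))
        opts = FitOptions(maxiter=5)
        with pytest.raises(ConvergenceError) as exc:
            ch.fit_unpenalized(make_layer(z[:, None]), out, opts)
        assert exc.value.last_iterate is not None
        assert exc.value.grad_norm > 0


@pytest.fixture(scope="module")
def problem():
    r = np.random.default_rng(7)
    n = 30
    Z = r.normal(size=(n, 3))
    ages = np.exp(-Z[:, 0] + 0.5 * r.normal(size=n)) + 1
    layer = make_layer(Z)
    out = make_outcome(ages, r.integers(0, 2, n) | 1)
    bh = ch.fit_unpenalized(layer, out)
    return layer, out, bh


class TestFitCoxLasso:

    def test_lambda_zero_matches_unpenalized(self, problem):
        layer, out, bh = problem
        fit = ch.fit_cox_lasso(layer, out, 0.0, bh)
        cos = fit.coefficients.beta @ bh.beta
        assert cos > 1 - 1e-6

    def test_penalty_at_beta_hat_is_lambda_p(self, problem):
        layer, out, bh = problem
        lam = 0.37
        obj = ch.cox_lasso_objective(layer, bh.raw, out, lam, bh)
        pll = ch.partial_log_likelihood(layer, bh.raw, out)
        assert obj - (-pll / out.n) == pytest.approx(lam * layer.p,
                                                     rel=1e-12)

    @pytest.mark.filterwarnings("ignore:.*zero coefficient.*")
    def test_penalty_path_monotone_in_lambda(self, problem):
        from coophaz.cox import adaptive_penalty
        layer, out, bh = problem
        sizes = []
        for lam in [0.0, 0.01, 0.05, 0.2, 1.0]:
            fit = ch.fit_cox_lasso(layer, out, lam, bh)
            raw = fit.coefficients.raw
            sizes.append(float(adaptive_penalty(raw[:, None], bh.raw)[0]))
        assert all(a >= b - 1e-6 for a, b in zip(sizes, sizes[1:]))

    def test_negative_lambda_rejected(self, problem):
        layer, out, bh = problem
        with pytest.raises(DataError):
            ch.fit_cox_lasso(layer, out, -0.1, bh)

    def test_degenerate_beta_hat_rejected(self, problem):
        layer, out, _ = problem
        with pytest.raises(DataError):
            ch.fit_cox_lasso(layer, out, 0.1, np.zeros(layer.p))


class TestFitConditionalModel:
    def test_unit_norm_and_sign_agreement(self, rng):
        n = 40
        z = rng.normal(size=n)
        ages = 10 - 2 * z + rng.normal(0, 0.5, n)
        ages = ages - ages.min() + 1
        layer = make_layer(z[:, None])
        out = make_outcome(ages, np.ones(n, dtype=int))
        cv = ch.fit_conditional_model(layer, out)
        assert abs(np.linalg.norm(cv.beta) - 1) < 1e-10
        assert np.sign(cv.beta[0]) == \
            np.sign(ch.fit_unpenalized(layer, out).beta[0])

    def test_beats_dense_grid_oracle(self, rng):
        Z = rng.normal(size=(5, 1))
        layer = make_layer(Z)
        out = make_outcome([3.0, 1.0, 4.0, 2.0, 5.0], [1, 1, 0, 1, 1])
        cv = ch.fit_conditional_model(layer, out)
        best = ch.conditional_partial_likelihood(layer, cv.raw, out)
        ctx = PLLContext(out)
        grid = np.linspace(-10, 10, 4001)
        vals = ctx.conditional_loglik(layer.values @ grid[None, :])
        assert best >= vals.max() - 1e-8


class TestBreslowBaseline:
    def test_zero_lp_equals_nelson_aalen(self):
        out = make_outcome([1.0, 2.0, 3.0], [1, 1, 1])
        curve = ch.breslow_baseline(np.zeros(3), out)
        assert np.allclose(curve.knots, [1, 2, 3])
        assert np.allclose(curve.values,
                           [1 / 3, 1 / 3 + 1 / 2, 1 / 3 + 1 / 2 + 1],
                           atol=1e-15)

    def test_matches_lifelines_nelson_aalen(self, rng):
        lifelines = pytest.importorskip("lifelines")
        n = 25
        ages = rng.uniform(1, 10, n)
        events = rng.integers(0, 2, n)
        events[0] = 1
        curve = ch.breslow_baseline(np.zeros(n), make_outcome(ages, events))
        naf = lifelines.NelsonAalenFitter(nelson_aalen_smoothing=False)
        naf.fit(ages, events)
        ref = naf.cumulative_hazard_.loc[curve.knots].to_numpy().ravel()
        assert np.allclose(curve.values, ref, atol=1e-10)

    def test_constant_shift_scales_increments(self, rng):
        n = 8
        lp = rng.normal(size=n)
        ages = np.arange(1.0, n + 1)
        out = make_outcome(ages, [1, 0, 1, 1, 0, 1, 1, 1])
        base = ch.breslow_baseline(lp, out)
        shifted = ch.breslow_baseline(lp + 1.7, out)
        assert np.allclose(shifted.values, base.values * np.exp(-1.7))

    def test_tied_event_ages_share_one_increment(self):
        out = make_outcome([1.0, 1.0, 2.0], [1, 1, 1])
        curve = ch.breslow_baseline(np.zeros(3), out)
        # two events at t=1 among 3 at risk, one event at t=2 among 1
        assert np.allclose(curve.knots, [1.0, 2.0])
        assert np.allclose(curve.values, [2 / 3, 2 / 3 + 1])

    def test_no_events_rejected(self):
        out = make_outcome([1.0, 2.0], [0, 0])
        with pytest.raises(DataError):
            ch.breslow_baseline(np.zeros(2), out)
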