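"""Single-layer Cox machinery.

Implements the Cox partial log-likelihood with Breslow tie handling, its
unpenalized quasi-Newton maximizer, the adaptive-lasso ("Cox-lasso")
penalized fit, a conditional-partial-likelihood comparator, and the Breslow
baseline cumulative hazard.

All fits follow the same numerical recipe: BFGS with central
finite-difference gradients (step 1e-6), gradient tolerance 1e-6, at most
500 iterations, started from the zero vector, and coefficients rescaled to
unit Euclidean norm afterwards.  The L1 penalty is smoothed as
``|x| ~ sqrt(x^2 + eps^2)`` with ``eps = 1e-8`` so the same smooth
optimizer applies throughout.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.optimize import minimize

from .data import CoefficientVector, DataLayer, OutcomeTable, StepCurve
from .exceptions import ConvergenceError, DataError


@dataclasses.dataclass
class FitOptions:
    """Numerical settings shared by every fitting routine.

    ``on_nonconvergence`` decides what happens when the iteration budget is
    exhausted with the gradient still above tolerance: ``"raise"`` throws a
    :class:`ConvergenceError` carrying the last iterate, ``"warn"`` keeps
    the last iterate with a warning (useful for high-dimensional layers
    whose unpenalized likelihood has no finite maximizer).
    """

    gtol: float = 1e-6
    maxiter: int = 500
    fd_step: float = 1e-6
    smooth_eps: float = 1e-8
    weight_floor: float = 1e-8
    on_nonconvergence: str = "raise"
    allow_constant: bool = False

    def __post_init__(self):
        if self.on_nonconvergence not in ("raise", "warn"):
            raise DataError("on_nonconvergence must be 'raise' or 'warn'")


# ---------------------------------------------------------------------------
# likelihood evaluation


class PLLContext:
    """Precomputed sort structure for repeated likelihood evaluations.

    Sorting the cohort once by decreasing observed age lets both the Cox
    partial log-likelihood and the conditional variant be evaluated for a
    whole batch of coefficient vectors with one cumulative log-sum-exp.
    """

    def __init__(self, outcome: OutcomeTable):
        ages = outcome.observed_age
        self.n = ages.size
        # descending ages: risk set {j: age_j >= age_i} is a prefix
        self.order_desc = np.argsort(-ages, kind="stable")
        a_desc = ages[self.order_desc]
        self.last_desc = np.searchsorted(-a_desc, -a_desc, side="right") - 1
        self.events_desc = outcome.event[self.order_desc].astype(bool)
        # ascending ages: the set {j: age_j <= age_i} is a prefix
        self.order_asc = np.argsort(ages, kind="stable")
        a_asc = ages[self.order_asc]
        self.last_asc = np.searchsorted(a_asc, a_asc, side="right") - 1

    def partial_loglik(self, lp: np.ndarray) -> np.ndarray:
        """Cox partial log-likelihood for each column of ``lp`` (n x q)."""
        if not self.events_desc.any():
            return np.zeros(lp.shape[1])
        lp_s = lp[self.order_desc]
        cum = np.logaddexp.accumulate(lp_s, axis=0)
        terms = lp_s - cum[self.last_desc]
        return terms[self.events_desc].sum(axis=0)

    def conditional_loglik(self, lp: np.ndarray,
                           risk_set: str = "at_risk") -> np.ndarray:
        """Conditional partial log-likelihood, summed over all individuals.

        ``risk_set`` selects the normalizing set: ``"at_risk"`` uses the
        standard at-risk set {j: age_j >= age_i}; ``"as_printed"`` uses
        {j: age_j <= age_i}.
        """
        if risk_set == "at_risk":
            lp_s = lp[self.order_desc]
            last = self.last_desc
        elif risk_set == "as_printed":
            lp_s = lp[self.order_asc]
            last = self.last_asc
        else:
            raise DataError(f"unknown risk_set {risk_set!r}")
        cum = np.logaddexp.accumulate(lp_s, axis=0)
        return (lp_s - cum[last]).sum(axis=0)


def _beta_array(beta, layer: DataLayer) -> np.ndarray:
    b = beta.beta if isinstance(beta, CoefficientVector) else \
        np.asarray(beta, dtype=float)
    if b.ndim != 1 or b.size != layer.p:
        raise DataError(
            f"coefficient length {b.size} does not match the "
            f"{layer.p} features of layer '{layer.name}'")
    if not np.all(np.isfinite(b)):
        raise DataError("non-finite coefficient vector")
    return b


def _check_samples(layer: DataLayer, outcome: OutcomeTable):
    if layer.n != outcome.n:
        raise DataError(
            f"layer '{layer.name}' has {layer.n} rows but the outcome "
            f"table has {outcome.n}")


def partial_log_likelihood(layer: DataLayer, beta,
                           outcome: OutcomeTable) -> float:
    """Cox partial log-likelihood l_Z(beta) with Breslow tie handling.

    Each event contributes its linear predictor minus the log-sum-exp of
    the linear predictors of everyone still at risk (observed age greater
    than or equal to the event age, ties included).
    """
    _check_samples(layer, outcome)
    b = _beta_array(beta, layer)
    if outcome.n_events == 0:
        warnings.warn("no events: partial log-likelihood is identically 0",
                      stacklevel=2)
        return 0.0
    ctx = PLLContext(outcome)
    return float(ctx.partial_loglik(layer.values @ b[:, None])[0])


def conditional_partial_likelihood(layer: DataLayer, beta,
                                   outcome: OutcomeTable,
                                   risk_set: str = "at_risk") -> float:
    """Log conditional partial likelihood summed over all individuals.

    The normalizing set defaults to the standard at-risk set
    {j: age_j >= age_i}; ``risk_set="as_printed"`` flips the inequality.
    """
    _check_samples(layer, outcome)
    b = _beta_array(beta, layer)
    ctx = PLLContext(outcome)
    return float(ctx.conditional_loglik(layer.values @ b[:, None],
                                        risk_set)[0])


# ---------------------------------------------------------------------------
# optimization


def _fd_gradient(fun_batch, x: np.ndarray, h: float) -> np.ndarray:
    """Central finite-difference gradient, one batched objective call."""
    d = x.size
    X = np.repeat(x[:, None], 2 * d, axis=1)
    idx = np.arange(d)
    X[idx, 2 * idx] += h
    X[idx, 2 * idx + 1] -= h
    vals = fun_batch(X)
    return (vals[0::2] - vals[1::2]) / (2.0 * h)


def minimize_smooth(fun_batch, x0: np.ndarray, opts: FitOptions,
                    context: str = ""):
    """BFGS with numerical gradients over a batched objective.

    ``fun_batch`` maps a (d, q) array of column parameter vectors to q
    objective values; gradients are central differences with step
    ``opts.fd_step``.
    """

    def f(x):
        return float(fun_batch(np.asarray(x, dtype=float)[:, None])[0])

    def g(x):
        return _fd_gradient(fun_batch, np.asarray(x, dtype=float),
                            opts.fd_step)

    res = minimize(f, np.asarray(x0, dtype=float), jac=g, method="BFGS",
                   options={"gtol": opts.gtol, "maxiter": opts.maxiter})
    if res.status != 0 and np.all(np.isfinite(res.x)):
        # line searches can stall near the smoothed-L1 kink; one restart
        # with a fresh inverse-Hessian often recovers the last digits
        retry = minimize(f, res.x, jac=g, method="BFGS",
                         options={"gtol": opts.gtol,
                                  "maxiter": opts.maxiter})
        if retry.fun <= res.fun:
            res = retry
    if not np.all(np.isfinite(res.x)):
        raise ConvergenceError(
            f"optimizer diverged to non-finite iterate{context}",
            res.x, float(np.linalg.norm(res.jac)))
    gnorm = float(np.linalg.norm(res.jac, ord=np.inf))
    if res.status == 1 and gnorm > opts.gtol:  # iteration budget exhausted
        msg = (f"no convergence after {opts.maxiter} iterations"
               f"{context}: max |gradient| = {gnorm:.3e}")
        if opts.on_nonconvergence == "raise":
            raise ConvergenceError(msg, res.x, gnorm)
        warnings.warn(msg, stacklevel=2)
    return res


def _check_constant(layer: DataLayer, opts: FitOptions):
    """Constant columns cancel in every risk-set ratio, so the likelihood
    is flat in those coordinates; reject them unless explicitly allowed
    (they then stay at zero and the adaptive penalty shrinks them away)."""
    const = layer.constant_columns
    if const.any() and not opts.allow_constant:
        raise DataError(
            f"layer '{layer.name}': constant column(s) "
            f"{list(layer.feature_id[const])} make the fit degenerate")


def minimize_multistart(fun_batch, starts, opts: FitOptions,
                        context: str = ""):
    """Run :func:`minimize_smooth` from several starts, keep the best.

    The L1 kink (even smoothed) can stall a gradient-based line search at
    the zero vector, so penalized fits are additionally started from the
    preliminary unpenalized maximizer; the run with the lowest final
    objective wins (deterministic tie-break: earlier start).
    """
    best = None
    for x0 in starts:
        res = minimize_smooth(fun_batch, x0, opts, context)
        if best is None or res.fun < best.fun - 1e-15:
            best = res
    return best


def _normalized(layer_name: str, raw: np.ndarray) -> CoefficientVector:
    return CoefficientVector(layer_name, raw, False).normalize()


def fit_unpenalized(layer: DataLayer, outcome: OutcomeTable,
                    opts: FitOptions | None = None) -> CoefficientVector:
    """Maximize the partial log-likelihood; return a unit-norm vector.

    The returned :class:`CoefficientVector` carries the unnormalized
    maximizer in its ``raw`` field, which the adaptive penalty needs.
    """
    opts = opts or FitOptions()
    _check_samples(layer, outcome)
    if outcome.n_events == 0:
        raise DataError("cannot fit: no events in the outcome table")
    _check_constant(layer, opts)
    ctx = PLLContext(outcome)
    Z = layer.values

    def fun(B):
        return -ctx.partial_loglik(Z @ B)

    res = minimize_smooth(fun, np.zeros(layer.p), opts,
                          context=f" (layer '{layer.name}')")
    return _normalized(layer.name, res.x)


def fit_conditional_model(layer: DataLayer, outcome: OutcomeTable,
                          opts: FitOptions | None = None,
                          risk_set: str = "at_risk") -> CoefficientVector:
    """Maximize the conditional partial likelihood; unit-norm result."""
    opts = opts or FitOptions()
    _check_samples(layer, outcome)
    if outcome.n_events == 0:
        raise DataError("cannot fit: no events in the outcome table")
    _check_constant(layer, opts)
    ctx = PLLContext(outcome)
    Z = layer.values

    def fun(B):
        return -ctx.conditional_loglik(Z @ B, risk_set)

    res = minimize_smooth(fun, np.zeros(layer.p), opts,
                          context=f" (conditional, layer '{layer.name}')")
    return _normalized(layer.name, res.x)


# ---------------------------------------------------------------------------
# adaptive lasso


def floored_weights(beta_hat_raw: np.ndarray,
                    floor: float = 1e-8) -> np.ndarray:
    """Adaptive-penalty denominators |beta_hat| floored at floor*max|.|."""
    a = np.abs(np.asarray(beta_hat_raw, dtype=float))
    m = a.max() if a.size else 0.0
    if m == 0:
        raise DataError("degenerate preliminary estimate: every entry of "
                        "beta_hat is zero")
    return np.maximum(a, floor * m)


def adaptive_penalty(B: np.ndarray, beta_hat_raw: np.ndarray,
                     eps: float = 0.0, floor: float = 1e-8) -> np.ndarray:
    """Sum_k |beta_k / beta_hat_k| for each column of ``B``.

    ``eps > 0`` replaces |x| with sqrt(x^2 + eps^2) for smooth
    optimization; ``eps = 0`` is the exact penalty.
    """
    w = floored_weights(beta_hat_raw, floor)
    R = np.atleast_2d(B.T).T / w[:, None]
    if eps > 0:
        return np.sqrt(R ** 2 + eps ** 2).sum(axis=0)
    return np.abs(R).sum(axis=0)


def _raw_beta_hat(beta_hat) -> np.ndarray:
    if isinstance(beta_hat, CoefficientVector):
        return beta_hat.raw if beta_hat.raw is not None else beta_hat.beta
    return np.asarray(beta_hat, dtype=float)


def cox_lasso_objective(layer: DataLayer, beta, outcome: OutcomeTable,
                        lam: float, beta_hat, eps: float = 0.0,
                        floor: float = 1e-8) -> float:
    """Adaptive-lasso objective -l_Z(beta)/n + lam * sum|beta/beta_hat|."""
    b = _beta_array(beta, layer)
    ctx = PLLContext(outcome)
    pll = float(ctx.partial_loglik(layer.values @ b[:, None])[0])
    pen = float(adaptive_penalty(b[:, None], _raw_beta_hat(beta_hat),
                                 eps, floor)[0])
    return -pll / outcome.n + lam * pen


@dataclasses.dataclass(frozen=True)
class PenalizedFit:
    """Result of an adaptive-lasso fit: unit-norm coefficients plus the
    exact (unsmoothed) objective value at the solution."""

    coefficients: CoefficientVector
    objective: float
    lam: float


def fit_cox_lasso(layer: DataLayer, outcome: OutcomeTable, lam: float,
                  beta_hat, opts: FitOptions | None = None,
                  x0: np.ndarray | None = None) -> PenalizedFit:
    """Minimize the adaptive-lasso Cox objective for one layer.

    ``beta_hat`` must be the unnormalized maximizer of the partial
    log-likelihood for this layer (it supplies the adaptive weights).
    """
    opts = opts or FitOptions()
    if lam < 0:
        raise DataError("lambda must be non-negative")
    _check_samples(layer, outcome)
    if outcome.n_events == 0:
        raise DataError("cannot fit: no events in the outcome table")
    bh = _raw_beta_hat(beta_hat)
    if bh.size != layer.p:
        raise DataError("beta_hat length does not match the layer")
    w = floored_weights(bh, opts.weight_floor)  # validates degeneracy
    ctx = PLLContext(outcome)
    Z = layer.values
    n = outcome.n
    eps = opts.smooth_eps

    def fun(B):
        pen = np.sqrt((B / w[:, None]) ** 2 + eps ** 2).sum(axis=0)
        return -ctx.partial_loglik(Z @ B) / n + lam * pen

    starts = [np.zeros(layer.p), bh] if x0 is None else \
        [np.asarray(x0, dtype=float)]
    res = minimize_multistart(fun, starts, opts,
                              context=f" (Cox-lasso, layer '{layer.name}')")
    obj = cox_lasso_objective(layer, res.x, outcome, lam, bh,
                              eps=0.0, floor=opts.weight_floor)
    return PenalizedFit(_normalized(layer.name, res.x), obj, lam)


# ---------------------------------------------------------------------------
# baseline hazard


def breslow_baseline(linear_predictors, outcome: OutcomeTable,
                     center: bool = False) -> StepCurve:
    """Breslow cumulative baseline hazard as a step curve.

    At each distinct event age t the cumulative hazard jumps by
    d_t / sum_{k at risk at t} exp(lp_k).  With ``center=False`` (default)
    the baseline refers to a linear predictor of zero; ``center=True``
    subtracts the mean linear predictor first, so the curve refers to an
    average individual and callers must carry the same offset when
    predicting.
    """
    lp = np.asarray(linear_predictors, dtype=float)
    if lp.shape != (outcome.n,):
        raise DataError("need exactly one linear predictor per sample")
    if outcome.n_events == 0:
        raise DataError("cannot estimate a baseline hazard without events")
    if center:
        lp = lp - lp.mean()
    ages = outcome.observed_age
    shift = lp.max()  # overflow guard
    e = np.exp(lp - shift)
    order = np.argsort(-ages, kind="stable")
    csum = np.cumsum(e[order])
    event_ages = np.unique(ages[outcome.event == 1])  # ascending
    # at-risk mass for age t: everyone with observed age >= t
    a_desc = ages[order]
    last = np.searchsorted(-a_desc, -event_ages, side="right") - 1
    denom = csum[last] * np.exp(shift)
    d = np.array([(ages[outcome.event == 1] == t).sum() for t in event_ages],
                 dtype=float)
    return StepCurve(event_ages, np.cumsum(d / denom), "cumulative_hazard")
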