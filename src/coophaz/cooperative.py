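"""Joint fitting of per-layer Cox coefficients under an agreement penalty.

The cooperative objective couples the per-layer adaptive-lasso Cox
objectives through a quadratic penalty on the pairwise differences of the
layer-wise linear predictors:

    -(1/n) sum_j l_{Z_j}(beta_j)
    + (rho/2) sum_{pairs} ||Z_i beta_i - Z_j beta_j||^2
    + lam * sum_j sum_k |beta_{j,k} / beta_hat_{j,k}|

rho = 0 decouples the layers (late fusion); large rho forces the layer
predictions to agree.  Fitting is two-step: first the unpenalized
per-layer maximizers beta_hat_j (adaptive weights), then a joint BFGS
minimization over the concatenated parameter vector.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .cox import (FitOptions, PLLContext, breslow_baseline,
                  fit_unpenalized, minimize_multistart, _raw_beta_hat,
                  floored_weights)
from .data import CoefficientVector, DataLayer, OutcomeTable, StepCurve
from .exceptions import DataError

_PAIR_SCHEMES = ("all_pairs", "chain")


def default_rho(m: int) -> float:
    """Default agreement weight: 1 for two layers, 0.5 for three or more,
    0 for a single layer (no pairs exist)."""
    if m <= 1:
        return 0.0
    return 1.0 if m == 2 else 0.5


def pair_indices(m: int, scheme: str) -> list[tuple[int, int]]:
    if scheme == "all_pairs":
        return [(i, j) for i in range(m) for j in range(i + 1, m)]
    if scheme == "chain":
        return [(i, i + 1) for i in range(m - 1)]
    raise DataError(f"unknown pair_scheme {scheme!r}")


@dataclasses.dataclass
class CoopConfig:
    """Configuration of the cooperative fit.

    ``rho=None`` resolves to the layer-count default at fit time.
    ``normalize_agreement`` divides the agreement term by n (off by
    default: the objective is used as displayed).  ``warm_start`` starts
    the rho > 0 joint minimization from the rho = 0 solution.
    """

    rho: float | None = None
    lam: float = 0.0
    pair_scheme: str = "all_pairs"
    normalize_agreement: bool = False
    warm_start: bool = True
    center_baseline: bool = False
    fit_options: FitOptions = dataclasses.field(default_factory=FitOptions)

    def __post_init__(self):
        if self.rho is not None and self.rho < 0:
            raise DataError("rho must be non-negative")
        if self.lam < 0:
            raise DataError("lambda must be non-negative")
        if self.pair_scheme not in _PAIR_SCHEMES:
            raise DataError(f"pair_scheme must be one of {_PAIR_SCHEMES}")


@dataclasses.dataclass(frozen=True)
class CoopModel:
    """Fitted cooperative polygenic hazard score model.

    Unit-norm coefficients per layer, the Breslow baseline cumulative
    hazard on the combined linear predictor, and the resolved (rho, lam).
    ``lp_offset`` is nonzero only for a mean-centered baseline.
    """

    coefficients: list[CoefficientVector]
    baseline: StepCurve
    config: CoopConfig
    layer_names: list[str]
    feature_ids: list[np.ndarray]
    lp_offset: float = 0.0
    objective: float | None = None
    beta_hats: list[np.ndarray] | None = None

    @property
    def m(self) -> int:
        return len(self.coefficients)

    def linear_predictor(self, layers: list[DataLayer]) -> np.ndarray:
        """Combined linear predictor sum_j Z_j beta_j minus the offset."""
        check_layer_match(self, layers)
        lp = np.zeros(layers[0].n)
        for layer, cv in zip(layers, self.coefficients):
            lp += layer.values @ cv.beta
        return lp - self.lp_offset


def check_layer_match(model: CoopModel, layers: list[DataLayer]):
    if len(layers) != model.m:
        raise DataError(f"model has {model.m} layers, got {len(layers)}")
    for layer, name, fid in zip(layers, model.layer_names,
                                model.feature_ids):
        if layer.name != name:
            raise DataError(f"expected layer '{name}', got '{layer.name}'")
        if layer.p != fid.size or not np.array_equal(layer.feature_id, fid):
            raise DataError(
                f"layer '{layer.name}': feature list does not match the "
                f"fitted model")


def _check_alignment(layers: list[DataLayer], outcome: OutcomeTable):
    if not layers:
        raise DataError("need at least one data layer")
    for layer in layers:
        if layer.n != outcome.n or \
                not np.array_equal(layer.sample_id, outcome.sample_id):
            raise DataError(
                f"layer '{layer.name}': sample order does not match the "
                f"outcome table")


def _slices(layers: list[DataLayer]) -> list[slice]:
    out, start = [], 0
    for layer in layers:
        out.append(slice(start, start + layer.p))
        start += layer.p
    return out


class _CoopObjective:
    """Batched cooperative objective over the concatenated parameters."""

    def __init__(self, layers, outcome, bh_raws, config: CoopConfig,
                 rho: float, eps: float):
        self.layers = layers
        self.n = outcome.n
        self.ctx = PLLContext(outcome)
        self.weights = [floored_weights(bh, config.fit_options.weight_floor)
                        for bh in bh_raws]
        self.lam = config.lam
        self.rho = rho
        self.eps = eps
        self.norm_agree = config.normalize_agreement
        self.pairs = pair_indices(len(layers), config.pair_scheme)
        self.slices = _slices(layers)

    def __call__(self, B: np.ndarray) -> np.ndarray:
        B = np.atleast_2d(B.T).T
        q = B.shape[1]
        total = np.zeros(q)
        preds = []
        for layer, sl, w in zip(self.layers, self.slices, self.weights):
            Bj = B[sl]
            lp = layer.values @ Bj
            preds.append(lp)
            total -= self.ctx.partial_loglik(lp) / self.n
            R = Bj / w[:, None]
            if self.eps > 0:
                total += self.lam * np.sqrt(R ** 2 + self.eps ** 2).sum(axis=0)
            else:
                total += self.lam * np.abs(R).sum(axis=0)
        if self.rho > 0 and self.pairs:
            agree = np.zeros(q)
            for i, j in self.pairs:
                agree += ((preds[i] - preds[j]) ** 2).sum(axis=0)
            if self.norm_agree:
                agree /= self.n
            total += 0.5 * self.rho * agree
        return total


def agreement_term(layers: list[DataLayer], betas,
                   pair_scheme: str = "all_pairs",
                   normalize: bool = False) -> float:
    """sum_{pairs} ||Z_i beta_i - Z_j beta_j||^2 (optionally / n)."""
    preds = [layer.values @ (b.beta if isinstance(b, CoefficientVector)
                             else np.asarray(b, dtype=float))
             for layer, b in zip(layers, betas)]
    total = 0.0
    for i, j in pair_indices(len(layers), pair_scheme):
        total += float(((preds[i] - preds[j]) ** 2).sum())
    if normalize:
        total /= layers[0].n
    return total


def coop_objective(layers: list[DataLayer], betas, beta_hats,
                   outcome: OutcomeTable, config: CoopConfig,
                   smooth_eps: float = 0.0) -> float:
    """Evaluate the cooperative objective at given per-layer coefficients.

    ``beta_hats`` are the per-layer unnormalized partial-likelihood
    maximizers supplying the adaptive weights.  The penalty is exact
    (unsmoothed) unless ``smooth_eps > 0``.
    """
    _check_alignment(layers, outcome)
    m = len(layers)
    if len(betas) != m or len(beta_hats) != m:
        raise DataError("betas and beta_hats must have one entry per layer")
    rho = config.rho if config.rho is not None else default_rho(m)
    bh_raws = [_raw_beta_hat(bh) for bh in beta_hats]
    obj = _CoopObjective(layers, outcome, bh_raws, config, rho, smooth_eps)
    b = np.concatenate([np.asarray(x.beta if isinstance(x, CoefficientVector)
                                   else x, dtype=float) for x in betas])
    return float(obj(b[:, None])[0])


def fit_cooperative(layers: list[DataLayer], outcome: OutcomeTable,
                    config: CoopConfig | None = None,
                    beta_hats=None, x0: np.ndarray | None = None
                    ) -> CoopModel:
    """Fit the cooperative polygenic hazard score model.

    Two-step procedure: (1) per layer, maximize the partial log-likelihood
    to obtain the unnormalized beta_hat_j (skipped when ``beta_hats`` is
    supplied); (2) jointly minimize the cooperative objective over the
    concatenated parameter vector, warm-started from the rho = 0 solution
    when ``config.warm_start`` is set, otherwise from zero.  Each beta_j
    is then normalized to unit Euclidean norm and the Breslow baseline is
    fitted on the combined linear predictor.
    """
    config = config or CoopConfig()
    _check_alignment(layers, outcome)
    m = len(layers)
    rho = config.rho if config.rho is not None else default_rho(m)
    opts = config.fit_options

    if beta_hats is None:
        beta_hats = [fit_unpenalized(layer, outcome, opts)
                     for layer in layers]
    bh_raws = [_raw_beta_hat(bh) for bh in beta_hats]
    for layer, bh in zip(layers, bh_raws):
        if bh.size != layer.p:
            raise DataError(f"beta_hat length does not match layer "
                            f"'{layer.name}'")

    d = sum(layer.p for layer in layers)
    obj = _CoopObjective(layers, outcome, bh_raws, config, rho,
                         opts.smooth_eps)
    if x0 is not None:
        starts = [np.asarray(x0, dtype=float)]
        if starts[0].size != d:
            raise DataError("x0 length does not match the concatenated "
                            "parameter vector")
    else:
        starts = [np.zeros(d), np.concatenate(bh_raws)]
        if rho > 0 and config.warm_start:
            obj0 = _CoopObjective(layers, outcome, bh_raws, config, 0.0,
                                  opts.smooth_eps)
            warm = minimize_multistart(obj0, starts, opts,
                                       context=" (cooperative warm start)")
            starts = starts + [warm.x]

    res = minimize_multistart(obj, starts, opts,
                              context=" (cooperative fit)")
    raws = [res.x[sl] for sl in _slices(layers)]
    coeffs = [CoefficientVector(layer.name, raw, False).normalize()
              for layer, raw in zip(layers, raws)]
    exact = _CoopObjective(layers, outcome, bh_raws, config, rho, 0.0)
    objective = float(exact(res.x[:, None])[0])

    lp = np.zeros(outcome.n)
    for layer, cv in zip(layers, coeffs):
        lp += layer.values @ cv.beta
    offset = float(lp.mean()) if config.center_baseline else 0.0
    baseline = breslow_baseline(lp, outcome, center=config.center_baseline)
    resolved = dataclasses.replace(config, rho=rho)
    return CoopModel(coeffs, baseline, resolved,
                     [layer.name for layer in layers],
                     [layer.feature_id for layer in layers],
                     lp_offset=offset, objective=objective,
                     beta_hats=bh_raws)


# ---------------------------------------------------------------------------
# lambda selection


@dataclasses.dataclass(frozen=True)
class CVResult:
    """Cross-validation trace: held-out IBS per (fold, lambda) and the
    selected lambda (largest value attaining the minimal mean IBS)."""

    lambda_grid: np.ndarray
    fold_scores: np.ndarray
    chosen_lambda: float


def default_lambda_grid(num: int = 20, low: float = 1e-4,
                        high: float = 1.0) -> np.ndarray:
    """Log-spaced lambda grid used when no grid is supplied."""
    return np.geomspace(low, high, num)


def _stratified_folds(events: np.ndarray, k: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Fold labels, event-stratified: shuffle each stratum, deal round-robin."""
    fold = np.empty(events.size, dtype=int)
    for value in (0, 1):
        idx = np.flatnonzero(events == value)
        rng.shuffle(idx)
        fold[idx] = np.arange(idx.size) % k
    return fold


def cross_validate_lambda(layers: list[DataLayer], outcome: OutcomeTable,
                          config: CoopConfig, lambda_grid=None, k: int = 10,
                          seed: int = 0) -> CVResult:
    """Select lambda by k-fold cross-validation with held-out IBS.

    Samples are partitioned into event-stratified folds by a seeded
    shuffle; for each lambda the cooperative model is fitted on k-1 folds
    and scored by the integrated Brier score on the held-out fold.  The
    lambda minimizing the mean held-out IBS wins (largest such lambda on
    ties).
    """
    from .curves import predict_curves  # local import: cycle guard
    from .metrics import integrated_brier_score

    if k < 2:
        raise DataError("need at least 2 folds")
    grid = np.asarray(default_lambda_grid() if lambda_grid is None
                      else lambda_grid, dtype=float)
    if grid.size == 0 or np.any(grid < 0):
        raise DataError("lambda grid must be non-empty and non-negative")
    _check_alignment(layers, outcome)

    folds = None
    for attempt in range(10):
        rng = np.random.default_rng([seed, attempt])
        cand = _stratified_folds(outcome.event, k, rng)
        ok = all(outcome.event[cand == f].sum() >= 1 and
                 outcome.event[cand != f].sum() >= 1 for f in range(k))
        if ok:
            folds = cand
            break
    if folds is None:
        raise DataError("could not build folds with at least one event "
                        "each after 10 attempts")

    scores = np.empty((k, grid.size))
    for f in range(k):
        tr = np.flatnonzero(folds != f)
        te = np.flatnonzero(folds == f)
        tr_layers = [layer.subset(tr) for layer in layers]
        tr_out = outcome.subset(tr)
        te_layers = [layer.subset(te) for layer in layers]
        te_out = outcome.subset(te)
        bh = [fit_unpenalized(layer, tr_out, config.fit_options)
              for layer in tr_layers]
        te_grid = np.unique(te_out.observed_age[te_out.event == 1])
        for g, lam in enumerate(grid):
            cfg = dataclasses.replace(config, lam=float(lam))
            model = fit_cooperative(tr_layers, tr_out, cfg, beta_hats=bh)
            curves = predict_curves(model, te_layers)
            surv = [c.survival for c in curves]
            scores[f, g] = integrated_brier_score(
                surv, te_out.observed_age, te_out.event, te_grid)
    mean = scores.mean(axis=0)
    chosen = float(grid[mean == mean.min()].max())
    return CVResult(grid, scores, chosen)


def layer_weights(model: CoopModel, layers: list[DataLayer],
                  outcome: OutcomeTable | None = None) -> np.ndarray:
    """Relative predictive weight of each layer.

    Defined as w_j = sd(Z_j beta_j) / sum_k sd(Z_k beta_k) over the given
    (training) samples -- a repository convention for summarizing how much
    linear-predictor variation each layer contributes.
    """
    check_layer_match(model, layers)
    sds = np.array([float(np.std(layer.values @ cv.beta))
                    for layer, cv in zip(layers, model.coefficients)])
    total = sds.sum()
    if total == 0 or not math.isfinite(total):
        raise DataError("all layer linear predictors are constant; "
                        "weights are undefined")
    return sds / total
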