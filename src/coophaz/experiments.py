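"""Experiment runners: repeated train/validation evaluation and the
agreement-parameter (rho) ablation.

Each repetition draws a seeded train/validation split, fits the
cooperative model and its comparators on the same training set, predicts
every validation individual's survival at their recorded age, and scores
the four metrics.  Comparators: early fusion (adaptive-lasso Cox on the
column-wise concatenated layers), the conditional-likelihood model on the
concatenated layers, and the rho = 0 late-fusion variant of the
cooperative model.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd

from .cooperative import (CoopConfig, CoopModel, default_rho,
                          fit_cooperative, cross_validate_lambda)
from .cox import FitOptions, breslow_baseline, fit_conditional_model, \
    fit_unpenalized
from .curves import predict_curves
from .data import DataLayer, OutcomeTable
from .exceptions import DataError
from .metrics import (MetricReport, auc, concordance_index, confidence_band,
                      integrated_brier_score, normalized_l1)
from .simulate import SimulationConfig, generate_cohort

logger = logging.getLogger("coophaz")

METHODS = ("cooperative", "late_fusion", "early_fusion", "conditional")


@dataclasses.dataclass
class ExperimentConfig:
    """Protocol of a repeated train/validation experiment.

    ``train_count`` overrides ``train_fraction`` when set (fixed-size
    training set).  ``lam`` is the adaptive-lasso weight used when
    ``use_cv`` is off; with ``use_cv`` the weight is re-selected per
    repetition by cross-validated IBS on the training set.
    """

    train_fraction: float = 0.7
    train_count: int | None = None
    repetitions: int = 100
    rho: float | None = None
    lam: float = 0.01
    use_cv: bool = False
    lambda_grid: np.ndarray | None = None
    cv_folds: int = 10
    alpha: float = 0.05
    seed: int = 0
    methods: tuple = METHODS
    pair_scheme: str = "all_pairs"

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise DataError("train_fraction must lie in (0, 1)")
        if self.repetitions < 1:
            raise DataError("repetitions must be >= 1")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise DataError(f"unknown methods {sorted(unknown)}")


def _derived_seed(seed: int, *branch: int) -> int:
    """Deterministic sub-seed below 2**31."""
    return int(np.random.SeedSequence([seed, *branch]).generate_state(1)[0]
               % (2 ** 31))


def _split(outcome: OutcomeTable, n_train: int,
           rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Random split whose validation part contains both classes and whose
    training part contains at least one event."""
    n = outcome.n
    for _ in range(10):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        ev_te = outcome.event[te]
        if outcome.event[tr].sum() >= 1 and 0 < ev_te.sum() < te.size:
            return np.sort(tr), np.sort(te)
    raise DataError("could not draw a usable train/validation split "
                    "(classes too unbalanced)")


def _concat_layer(layers: list[DataLayer]) -> DataLayer:
    values = np.concatenate([layer.values for layer in layers], axis=1)
    fids = np.concatenate([np.array([f"{layer.name}:{f}"
                                     for f in layer.feature_id],
                                    dtype=object) for layer in layers])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return DataLayer("concat", layers[0].sample_id, fids, values)


def evaluate_model(model: CoopModel, layers: list[DataLayer],
                   outcome: OutcomeTable) -> MetricReport:
    """Score predicted survival on a validation cohort.

    The risk score is 1 - S_i(a_i) at the recorded age a_i; the IBS grid
    is the set of unique validation event ages.
    """
    curves = predict_curves(model, layers)
    s_at_age = np.array([c.survival_at(a) for c, a in
                         zip(curves, outcome.observed_age)])
    risk = 1.0 - s_at_age
    grid = np.unique(outcome.observed_age[outcome.event == 1])
    return MetricReport(
        l1=normalized_l1(s_at_age, outcome.event),
        auc=auc(risk, outcome.event),
        cindex=concordance_index(outcome.observed_age, outcome.event, risk),
        ibs=integrated_brier_score([c.survival for c in curves],
                                   outcome.observed_age, outcome.event,
                                   grid),
        n_validation=outcome.n)


def _fit_method(method: str, layers, outcome, beta_hats, rho, lam,
                config: ExperimentConfig, opts: FitOptions) -> CoopModel:
    if method == "cooperative":
        cfg = CoopConfig(rho=rho, lam=lam, pair_scheme=config.pair_scheme,
                         fit_options=opts)
        return fit_cooperative(layers, outcome, cfg, beta_hats=beta_hats)
    if method == "late_fusion":
        cfg = CoopConfig(rho=0.0, lam=lam, pair_scheme=config.pair_scheme,
                         fit_options=opts)
        return fit_cooperative(layers, outcome, cfg, beta_hats=beta_hats)
    if method == "early_fusion":
        concat = _concat_layer(layers)
        cfg = CoopConfig(rho=0.0, lam=lam, fit_options=opts)
        return fit_cooperative([concat], outcome, cfg)
    if method == "conditional":
        concat = _concat_layer(layers)
        cv = fit_conditional_model(concat, outcome, opts)
        lp = concat.values @ cv.beta
        baseline = breslow_baseline(lp, outcome)
        return CoopModel([cv], baseline, CoopConfig(rho=0.0, lam=0.0),
                         [concat.name], [concat.feature_id])
    raise DataError(f"unknown method {method!r}")


def run_experiment(layers: list[DataLayer], outcome: OutcomeTable,
                   config: ExperimentConfig) -> pd.DataFrame:
    """Repeated train/validation comparison of all configured methods.

    Returns one row per (repetition, method) with the four metrics; every
    method within a repetition sees the identical split.
    """
    n = outcome.n
    rho = config.rho if config.rho is not None else default_rho(len(layers))
    opts = FitOptions(on_nonconvergence="warn", allow_constant=True)
    rows = []
    for rep in range(config.repetitions):
        rng = np.random.default_rng(_derived_seed(config.seed, rep))
        n_train = config.train_count if config.train_count is not None \
            else int(round(config.train_fraction * n))
        if not 0 < n_train < n:
            raise DataError(f"training size {n_train} out of range")
        tr, te = _split(outcome, n_train, rng)
        tr_layers = [layer.subset(tr) for layer in layers]
        tr_out = outcome.subset(tr)
        te_layers = [layer.subset(te) for layer in layers]
        te_out = outcome.subset(te)
        beta_hats = [fit_unpenalized(layer, tr_out, opts)
                     for layer in tr_layers]
        lam = config.lam
        if config.use_cv:
            cv_cfg = CoopConfig(rho=rho, lam=0.0,
                                pair_scheme=config.pair_scheme,
                                fit_options=opts)
            lam = cross_validate_lambda(
                tr_layers, tr_out, cv_cfg, config.lambda_grid,
                k=config.cv_folds,
                seed=_derived_seed(config.seed, rep, 1)).chosen_lambda
        logger.info("repetition %d: n_train=%d n_val=%d lam=%g rho=%g",
                    rep, tr.size, te.size, lam, rho)
        for method in config.methods:
            try:
                model = _fit_method(method, tr_layers, tr_out, beta_hats,
                                    rho, lam, config, opts)
                val_layers = te_layers if model.m == len(layers) else \
                    [_concat_layer(te_layers)]
                report = evaluate_model(model, val_layers, te_out)
            except Exception as exc:
                raise type(exc)(
                    f"repetition {rep}, method '{method}': {exc}") from exc
            rows.append({"repetition": rep, "method": method,
                         **dataclasses.asdict(report)})
    return pd.DataFrame(rows)


def aggregate_metrics(table: pd.DataFrame,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Mean and normal-approximation band of each metric per group.

    Groups by every non-metric identifier column present (``method``
    and/or ``rho``).
    """
    metric_cols = ["l1", "auc", "cindex", "ibs"]
    keys = [c for c in ("method", "rho") if c in table.columns]
    rows = []
    for key_vals, grp in table.groupby(keys):
        if not isinstance(key_vals, tuple):
            key_vals = (key_vals,)
        row = dict(zip(keys, key_vals))
        row["repetitions"] = len(grp)
        for col in metric_cols:
            if len(grp) >= 2:
                mean, lo, hi = confidence_band(grp[col].to_numpy(), alpha)
            else:
                mean = float(grp[col].iloc[0])
                lo = hi = mean
            row[f"{col}_mean"] = mean
            row[f"{col}_lo"] = lo
            row[f"{col}_hi"] = hi
        rows.append(row)
    return pd.DataFrame(rows)


def run_ablation(sim_config: SimulationConfig, rho_values,
                 repetitions: int = 20, seed: int = 0, lam: float = 0.01,
                 train_fraction: float = 0.7, alpha: float = 0.05,
                 return_raw: bool = False):
    """Sweep the agreement parameter rho on freshly simulated cohorts.

    Per repetition one cohort is generated, split once, and the
    cooperative model is fitted at every rho on the identical training
    data (sharing the per-layer preliminary maximizers; rho > 0 fits are
    warm-started from the rho = 0 solution).  Returns the aggregated
    table (one row per rho with means and confidence bands), or
    (aggregated, raw) when ``return_raw`` is set.
    """
    rho_values = list(rho_values)
    opts = FitOptions(on_nonconvergence="warn", allow_constant=True)
    rows = []
    for rep in range(repetitions):
        cohort = generate_cohort(dataclasses.replace(
            sim_config, seed=_derived_seed(seed, rep)))
        layers = [cohort.genetic, cohort.methylation]
        outcome = cohort.outcome
        rng = np.random.default_rng(_derived_seed(seed, rep, 1))
        n_train = int(round(train_fraction * outcome.n))
        tr, te = _split(outcome, n_train, rng)
        tr_layers = [layer.subset(tr) for layer in layers]
        tr_out = outcome.subset(tr)
        te_layers = [layer.subset(te) for layer in layers]
        te_out = outcome.subset(te)
        beta_hats = [fit_unpenalized(layer, tr_out, opts)
                     for layer in tr_layers]
        base_cfg = CoopConfig(rho=0.0, lam=lam, fit_options=opts,
                              warm_start=False)
        model0 = fit_cooperative(tr_layers, tr_out, base_cfg,
                                 beta_hats=beta_hats)
        x0 = np.concatenate([cv.raw for cv in model0.coefficients])
        for rho in rho_values:
            if rho == 0:
                model = model0
            else:
                cfg = dataclasses.replace(base_cfg, rho=float(rho))
                model = fit_cooperative(tr_layers, tr_out, cfg,
                                        beta_hats=beta_hats, x0=x0)
            report = evaluate_model(model, te_layers, te_out)
            rows.append({"repetition": rep, "rho": float(rho),
                         **dataclasses.asdict(report)})
        logger.info("ablation repetition %d done", rep)
    raw = pd.DataFrame(rows)
    agg = aggregate_metrics(raw, alpha)
    return (agg, raw) if return_raw else agg
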