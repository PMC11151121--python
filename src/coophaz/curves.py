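"""Per-individual hazard and survival curves from a fitted model.

A fitted model yields, for each individual, the cumulative hazard
H(t) = H_0(t) * exp(lp) on the baseline knots and the survival curve
S(t) = exp(-H(t)).  For a step cumulative hazard the exponential relation
is exact (no quadrature error); :func:`cumulative_from_rate` integrates a
smooth hazard rate sampled on a dense grid by the trapezoidal rule.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .cooperative import CoopModel, check_layer_match
from .data import DataLayer, StepCurve
from .exceptions import DataError


def individual_hazard(model: CoopModel, covariates) -> StepCurve:
    """Cumulative hazard curve for one individual.

    ``covariates`` is one row per layer: a list in layer order or a dict
    keyed by layer name.
    """
    if isinstance(covariates, dict):
        try:
            rows = [covariates[name] for name in model.layer_names]
        except KeyError as exc:
            raise DataError(f"missing covariates for layer {exc}") from None
    else:
        rows = list(covariates)
        if len(rows) != model.m:
            raise DataError(f"expected {model.m} covariate rows, "
                            f"got {len(rows)}")
    lp = 0.0
    for name, fid, cv, row in zip(model.layer_names, model.feature_ids,
                                  model.coefficients, rows):
        z = np.asarray(row, dtype=float)
        if z.shape != (fid.size,):
            raise DataError(
                f"layer '{name}': expected {fid.size} covariate values, "
                f"got shape {z.shape}")
        lp += float(cv.beta @ z)
    lp -= model.lp_offset
    return StepCurve(model.baseline.knots,
                     model.baseline.values * np.exp(lp),
                     "cumulative_hazard")


def survival_from_hazard(cumulative: StepCurve) -> StepCurve:
    """Survival S(t) = exp(-H(t)) from a cumulative hazard step curve."""
    if cumulative.kind != "cumulative_hazard":
        raise DataError("input curve must be a cumulative hazard")
    return StepCurve(cumulative.knots, np.exp(-cumulative.values),
                     "survival")


def cumulative_from_rate(grid, rate) -> StepCurve:
    """Trapezoidal integration of a hazard rate sampled on a dense grid.

    Intended for smooth hazard inputs; the result is the cumulative
    hazard as a step curve on the grid (the integral from the first grid
    point).
    """
    grid = np.asarray(grid, dtype=float)
    rate = np.asarray(rate, dtype=float)
    if grid.shape != rate.shape or grid.ndim != 1:
        raise DataError("grid and rate must be 1-D of equal length")
    if np.any(rate < 0):
        raise DataError("hazard rate must be non-negative")
    widths = np.diff(grid)
    cum = np.concatenate([[0.0],
                          np.cumsum(0.5 * widths * (rate[1:] + rate[:-1]))])
    return StepCurve(grid, cum, "cumulative_hazard")


@dataclasses.dataclass(frozen=True)
class IndividualCurves:
    """Cumulative hazard and survival curves for one individual."""

    sample_id: str
    hazard: StepCurve
    survival: StepCurve

    def survival_at(self, age: float) -> float:
        return float(self.survival(age))

    def risk_at(self, age: float) -> float:
        return 1.0 - self.survival_at(age)


def survival_at_recorded_age(curves: IndividualCurves, age: float) -> float:
    """Right-continuous survival evaluation at an individual's recorded age.

    Ages below the first knot give 1; ages beyond the last knot use the
    last survival value.
    """
    if age <= 0:
        raise DataError("age must be positive")
    return curves.survival_at(age)


def predict_curves(model: CoopModel, layers: list[DataLayer]
                   ) -> list[IndividualCurves]:
    """Hazard and survival curves for every row of the given layers."""
    check_layer_match(model, layers)
    lp = model.linear_predictor(layers)
    knots = model.baseline.knots
    H0 = model.baseline.values
    out = []
    for i, sid in enumerate(layers[0].sample_id):
        H = H0 * np.exp(lp[i])
        haz = StepCurve(knots, H, "cumulative_hazard")
        surv = StepCurve(knots, np.exp(-H), "survival")
        out.append(IndividualCurves(str(sid), haz, surv))
    return out
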