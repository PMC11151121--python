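"""Core containers: outcomes, covariate layers, coefficients, step curves.

All survival quantities in this package are right-censored: each individual
carries one observed age (age of onset for events, age of last follow-up
otherwise) and a binary event indicator.  Risk sets are always formed on the
observed ages.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .exceptions import DataError

_NORM_TOL = 1e-10


@dataclasses.dataclass(frozen=True)
class OutcomeTable:
    """Per-sample right-censored outcome.

    Parameters
    ----------
    sample_id
        Unique string identifiers, one per individual.
    observed_age
        Strictly positive observed age in years: age of onset for events,
        age of last follow-up for censored individuals.
    event
        Binary indicator, 1 if the event was observed.
    """

    sample_id: np.ndarray
    observed_age: np.ndarray
    event: np.ndarray

    def __post_init__(self):
        sid = np.asarray(self.sample_id, dtype=object)
        age = np.asarray(self.observed_age, dtype=float)
        ev = np.asarray(self.event)
        if not (sid.shape == age.shape == ev.shape) or sid.ndim != 1:
            raise DataError("sample_id, observed_age and event must be "
                            "1-D arrays of equal length")
        if sid.size and len(set(sid.tolist())) != sid.size:
            raise DataError("duplicate sample_id in outcome table")
        if not np.all(np.isfinite(age)) or np.any(age <= 0):
            raise DataError("observed_age must be strictly positive and finite")
        if not np.isin(ev, (0, 1)).all():
            raise DataError("event indicator must be 0 or 1")
        object.__setattr__(self, "sample_id", sid)
        object.__setattr__(self, "observed_age", age)
        object.__setattr__(self, "event", ev.astype(np.int64))

    @property
    def n(self) -> int:
        return self.sample_id.size

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, idx) -> "OutcomeTable":
        idx = np.asarray(idx)
        return OutcomeTable(self.sample_id[idx], self.observed_age[idx],
                            self.event[idx])


@dataclasses.dataclass(frozen=True)
class DataLayer:
    """One n x p covariate matrix over a named data source.

    Rows must follow the sample order of the accompanying
    :class:`OutcomeTable` (use :func:`coophaz.io.align_layers` to enforce
    this when reading from disk).  Constant columns are permitted in the
    container but flagged, because penalized fits reject them.
    """

    name: str
    sample_id: np.ndarray
    feature_id: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        sid = np.asarray(self.sample_id, dtype=object)
        fid = np.asarray(self.feature_id, dtype=object)
        val = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "sample_id", sid)
        object.__setattr__(self, "feature_id", fid)
        object.__setattr__(self, "values", val)
        if val.ndim != 2:
            raise DataError(f"layer '{self.name}': values must be 2-D")
        if val.shape != (sid.size, fid.size):
            raise DataError(
                f"layer '{self.name}': values shape {val.shape} does not "
                f"match {sid.size} samples x {fid.size} features")
        if sid.size and len(set(sid.tolist())) != sid.size:
            raise DataError(f"layer '{self.name}': duplicate sample_id")
        if not np.all(np.isfinite(val)):
            bad = np.argwhere(~np.isfinite(val))[0]
            raise DataError(
                f"layer '{self.name}': non-finite value at row "
                f"{bad[0]} ('{sid[bad[0]]}'), column {bad[1]} "
                f"('{fid[bad[1]]}')")
        const = self.constant_columns
        if const.any():
            warnings.warn(
                f"layer '{self.name}': constant column(s) "
                f"{list(fid[const])}", stacklevel=2)

    @property
    def n(self) -> int:
        return self.sample_id.size

    @property
    def p(self) -> int:
        return self.feature_id.size

    @property
    def constant_columns(self) -> np.ndarray:
        """Boolean mask of zero-variance columns."""
        if self.n == 0:
            return np.zeros(self.p, dtype=bool)
        return np.ptp(self.values, axis=0) == 0

    def subset(self, idx) -> "DataLayer":
        idx = np.asarray(idx)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return DataLayer(self.name, self.sample_id[idx], self.feature_id,
                             self.values[idx])


@dataclasses.dataclass(frozen=True)
class CoefficientVector:
    """Fitted regression coefficients for one layer.

    ``beta`` is the coefficient vector as used in the hazard model; when
    ``normalized`` is set it has unit Euclidean norm.  ``raw`` keeps the
    unnormalized optimizer output, which downstream code needs for the
    adaptive-lasso weights.
    """

    layer_name: str
    beta: np.ndarray
    normalized: bool = False
    raw: np.ndarray | None = None

    def __post_init__(self):
        b = np.asarray(self.beta, dtype=float)
        object.__setattr__(self, "beta", b)
        if self.raw is not None:
            object.__setattr__(self, "raw", np.asarray(self.raw, dtype=float))
        if b.ndim != 1:
            raise DataError("beta must be a 1-D vector")
        if not np.all(np.isfinite(b)):
            raise DataError(f"non-finite coefficient in layer "
                            f"'{self.layer_name}'")
        if self.normalized and abs(np.linalg.norm(b) - 1.0) > _NORM_TOL:
            raise DataError(
                f"layer '{self.layer_name}': coefficient vector marked "
                f"normalized but has norm {np.linalg.norm(b)!r}")

    @property
    def p(self) -> int:
        return self.beta.size

    def normalize(self) -> "CoefficientVector":
        """Return a unit-norm copy, keeping the original as ``raw``."""
        nrm = np.linalg.norm(self.beta)
        if nrm == 0:
            warnings.warn(f"layer '{self.layer_name}': zero coefficient "
                          "vector cannot be normalized", stacklevel=2)
            return CoefficientVector(self.layer_name, self.beta, False,
                                     self.beta.copy())
        return CoefficientVector(self.layer_name, self.beta / nrm, True,
                                 self.beta.copy())


_CURVE_KINDS = ("cumulative_hazard", "hazard_increment", "survival")


@dataclasses.dataclass(frozen=True)
class StepCurve:
    """Right-continuous step function on an increasing age grid.

    The value before the first knot is the kind-specific baseline (0 for a
    cumulative hazard, 1 for a survival curve); beyond the last knot the
    last value is carried forward.
    """

    knots: np.ndarray
    values: np.ndarray
    kind: str

    def __post_init__(self):
        k = np.asarray(self.knots, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "knots", k)
        object.__setattr__(self, "values", v)
        if self.kind not in _CURVE_KINDS:
            raise DataError(f"unknown curve kind {self.kind!r}")
        if k.ndim != 1 or k.shape != v.shape:
            raise DataError("knots and values must be 1-D of equal length")
        if k.size == 0:
            raise DataError("step curve needs at least one knot")
        if np.any(np.diff(k) <= 0):
            raise DataError("knots must be strictly increasing")
        if not (np.all(np.isfinite(k)) and np.all(np.isfinite(v))):
            raise DataError("non-finite knot or value in step curve")
        if self.kind == "cumulative_hazard":
            if np.any(v < 0) or np.any(np.diff(v) < 0):
                raise DataError("cumulative hazard must be non-negative "
                                "and non-decreasing")
        elif self.kind == "survival":
            if np.any(v < 0) or np.any(v > 1) or np.any(np.diff(v) > 0):
                raise DataError("survival values must lie in [0, 1] and be "
                                "non-increasing")
        elif self.kind == "hazard_increment":
            if np.any(v < 0):
                raise DataError("hazard increments must be non-negative")

    @property
    def pre_value(self) -> float:
        """Value before the first knot."""
        return 1.0 if self.kind == "survival" else 0.0

    def __call__(self, ages):
        """Right-continuous evaluation with last-value carry-forward."""
        ages = np.asarray(ages, dtype=float)
        idx = np.searchsorted(self.knots, ages, side="right") - 1
        padded = np.concatenate([[self.pre_value], self.values])
        out = padded[idx + 1]
        return out if out.ndim else float(out)
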