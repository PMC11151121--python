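"""Evaluation metrics for predicted survival against observed status.

Orientation convention, fixed package-wide: survival is compared against
1 - y (controls' target survival is 1, cases' is 0), and the risk score
used for AUC and the concordance index is 1 - S_i(a_i) evaluated at the
individual's recorded age.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .exceptions import DataError


@dataclasses.dataclass(frozen=True)
class MetricReport:
    """The four evaluation metrics on one validation set."""

    l1: float
    auc: float
    cindex: float
    ibs: float
    n_validation: int


def normalized_l1(survival_at_age, status) -> float:
    """Mean absolute difference between predicted survival at the recorded
    age and the target survival 1 - y (y = 1 for cases)."""
    s = np.asarray(survival_at_age, dtype=float)
    y = np.asarray(status)
    if s.size == 0:
        raise DataError("empty input")
    if s.shape != y.shape:
        raise DataError("survival and status must have equal length")
    if np.any(s < 0) or np.any(s > 1):
        raise DataError("survival values must lie in [0, 1]")
    return float(np.mean(np.abs(s - (1 - y))))


def auc(scores, labels) -> float:
    """Mann-Whitney AUC: fraction of (case, control) pairs where the case
    has the higher risk score, ties counted one half."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise DataError("scores and labels must be 1-D of equal length")
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise DataError("AUC needs both classes present")
    ranks = stats.rankdata(s)  # average ranks implement the half-tie rule
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def concordance_index(ages, events, risk_scores) -> float:
    """Harrell's C over comparable pairs.

    A pair is comparable when the individual with the strictly shorter
    observed age has an event; it is concordant when that individual also
    carries the higher risk score (score ties count one half).
    """
    t = np.asarray(ages, dtype=float)
    d = np.asarray(events)
    r = np.asarray(risk_scores, dtype=float)
    if not (t.shape == d.shape == r.shape) or t.ndim != 1:
        raise DataError("ages, events and risk_scores must be 1-D of "
                        "equal length")
    comparable = (t[:, None] < t[None, :]) & (d[:, None] == 1)
    den = int(comparable.sum())
    if den == 0:
        raise DataError("no comparable pairs")
    conc = (comparable & (r[:, None] > r[None, :])).sum()
    ties = (comparable & (r[:, None] == r[None, :])).sum()
    return float((conc + 0.5 * ties) / den)


def _censoring_km(ages: np.ndarray, events: np.ndarray):
    """Kaplan-Meier estimate of the censoring survival G(t).

    Censorings are the 'events' of this estimator; at tied ages true
    events are taken to precede censorings, the usual reverse-KM
    convention.  Returns (times, values) of the right-continuous step
    function; G before the first drop is 1.
    """
    order = np.argsort(ages, kind="stable")
    a = ages[order]
    cens = (events[order] == 0)
    times = np.unique(a[cens])
    n = a.size
    at_risk = n - np.searchsorted(a, times, side="left")
    c_counts = np.array([(a[cens] == t).sum() for t in times], dtype=float)
    factors = 1.0 - c_counts / at_risk
    return times, np.cumprod(factors)


def _km_eval(times, values, t, left=False):
    """Evaluate the censoring KM at t (or its left limit t-)."""
    side = "left" if left else "right"
    idx = np.searchsorted(times, t, side=side) - 1
    padded = np.concatenate([[1.0], values])
    return padded[idx + 1]


def integrated_brier_score(survival_curves, ages, events, time_grid) -> float:
    """Time-averaged Brier score with inverse-censoring-probability weights.

    At each grid time t the Brier score is

        (1/n) * sum_i [ S_i(t)^2 * I(T_i <= t, event) / G(T_i-)
                        + (1 - S_i(t))^2 * I(T_i > t) / G(t) ]

    with G the Kaplan-Meier estimate of the censoring distribution; the
    average over the grid uses the trapezoidal rule (a single-point grid
    returns the pointwise score).
    """
    t = np.asarray(ages, dtype=float)
    d = np.asarray(events)
    grid = np.sort(np.asarray(time_grid, dtype=float))
    n = t.size
    if len(survival_curves) != n:
        raise DataError("need one survival curve per individual")
    if grid.size == 0:
        raise DataError("empty time grid")
    if grid[-1] > t.max():
        raise DataError("time grid extends beyond the observed follow-up")
    S = np.empty((n, grid.size))
    for i, curve in enumerate(survival_curves):
        S[i] = np.asarray(curve(grid), dtype=float)
    km_t, km_v = _censoring_km(t, d)
    G_at_T = _km_eval(km_t, km_v, t, left=True)
    G_at_grid = _km_eval(km_t, km_v, grid)
    bs = np.empty(grid.size)
    for g, tt in enumerate(grid):
        had_event = (t <= tt) & (d == 1)
        still_in = t > tt
        if np.any(had_event & (G_at_T == 0)):
            raise DataError(f"censoring distribution is 0 at an event time "
                            f"needed for the Brier score at t={tt}")
        if still_in.any() and G_at_grid[g] == 0:
            raise DataError(f"censoring distribution is 0 at grid time "
                            f"t={tt}")
        terms = np.zeros(n)
        terms[had_event] = S[had_event, g] ** 2 / G_at_T[had_event]
        terms[still_in] = (1 - S[still_in, g]) ** 2 / G_at_grid[g]
        bs[g] = terms.sum() / n
    if grid.size == 1:
        return float(bs[0])
    return float(np.trapezoid(bs, grid) / (grid[-1] - grid[0]))


def confidence_band(samples, alpha: float = 0.05):
    """Normal-approximation band across repetitions.

    Returns (mean, lo, hi) with half-width z_{1-alpha/2} * sd / sqrt(R).
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise DataError("need at least 2 repetitions for a band")
    if not 0 < alpha <= 1:
        raise DataError("alpha must lie in (0, 1]")
    mean = float(x.mean())
    half = float(stats.norm.ppf(1 - alpha / 2) * x.std(ddof=1)
                 / np.sqrt(x.size))
    return mean, mean - half, mean + half
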