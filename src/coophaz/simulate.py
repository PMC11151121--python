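"""Synthetic multi-omic survival cohorts.

Two generators provide all test inputs without external data:

* :func:`generate_cohort` builds a genotype layer (Balding-Nichols allele
  frequencies, binomial dosages in {0, 1, 2}), a methylation layer whose
  first columns are linearly coupled to paired genotype columns with a
  coupling coefficient derived from h, and a right-censored outcome whose
  latent age is a linear score of all columns scaled into a fixed age
  range, with uniform onset ages deciding case status.
* :func:`bootstrap_cohort` resamples an existing cohort entry-by-entry
  within the case and control pools, optionally separating the group age
  distributions by a fixed number of years.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .data import DataLayer, OutcomeTable
from .exceptions import DataError


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the cohort generator.

    ``h`` couples each paired methylation column to its genotype column
    (the population correlation of an unfiltered pair equals h); ``F`` is
    Wright's fixation index of the Balding-Nichols allele-frequency model;
    background frequencies are uniform on ``p_interval``.  ``cor_interval``
    is the acceptance window for the empirical correlation of a retained
    pair (rejection sampling).
    """

    n: int = 100
    n_g: int = 100
    n_m: int = 100
    n_p: int = 50
    h: float = 0.3
    F: float = 0.001
    p_interval: tuple[float, float] = (0.0, 0.1)
    cor_interval: tuple[float, float] = (0.0, 0.1)
    age_range: tuple[float, float] = (50.0, 100.0)
    seed: int = 0
    max_attempts: int = 10_000

    def __post_init__(self):
        if min(self.n, self.n_g, self.n_m) < 1 or self.n_p < 0:
            raise DataError("n, n_g, n_m must be >= 1 and n_p >= 0")
        if self.n_p >= min(self.n_g, self.n_m):
            raise DataError("n_p must be smaller than min(n_g, n_m)")
        if not 0 < self.h < 1:
            raise DataError("h must lie in (0, 1)")
        if not 0 < self.F < 1:
            raise DataError("F must lie in (0, 1)")
        for name, (lo, hi) in (("p_interval", self.p_interval),
                               ("cor_interval", self.cor_interval),
                               ("age_range", self.age_range)):
            if not lo < hi:
                raise DataError(f"{name} must be well-ordered")
        if self.age_range[0] <= 0:
            raise DataError("ages must be positive")


@dataclasses.dataclass(frozen=True)
class SimulatedCohort:
    """Generator output: two layers, the outcome, and the ground truth
    (score weights, per-locus allele frequencies, pair map)."""

    genetic: DataLayer
    methylation: DataLayer
    outcome: OutcomeTable
    truth: dict


def draw_maf(p: float, F: float, rng: np.random.Generator, size=None):
    """Allele frequency draw(s) from the Balding-Nichols model.

    Beta(p(1-F)/F, (1-p)(1-F)/F): mean p, variance F*p*(1-p).
    """
    if not 0 < p < 1:
        raise DataError("background frequency p must lie in (0, 1)")
    if not 0 < F < 1:
        raise DataError("fixation index F must lie in (0, 1)")
    a = p * (1 - F) / F
    b = (1 - p) * (1 - F) / F
    out = rng.beta(a, b, size=size)
    return out if size is not None else float(out)


def simulate_genotype_column(n: int, maf: float,
                             rng: np.random.Generator) -> np.ndarray:
    """n iid genotype dosages Binomial(2, maf)."""
    if not 0 <= maf <= 1:
        raise DataError("maf must lie in [0, 1]")
    return rng.binomial(2, maf, size=n)


def coupling_coefficient(maf: float, h: float) -> float:
    """b = sqrt(h^2 / (2 maf (1 - maf))); the pair correlation equals h."""
    if not 0 < maf < 1:
        raise DataError("maf must lie strictly in (0, 1)")
    return float(np.sqrt(h ** 2 / (2 * maf * (1 - maf))))


def simulate_methylation_pair(v_g: np.ndarray, maf: float, h: float,
                              rng: np.random.Generator) -> np.ndarray:
    """Methylation values coupled to a genotype column: b*v_g + noise with
    noise standard deviation sqrt(1 - h^2)."""
    b = coupling_coefficient(maf, h)
    eps = rng.normal(0.0, np.sqrt(1 - h ** 2), size=len(v_g))
    return b * np.asarray(v_g, dtype=float) + eps


def _draw_locus(cfg: SimulationConfig, rng: np.random.Generator):
    """One genotype column with a usable (non-constant) dosage vector."""
    lo, hi = cfg.p_interval
    for _ in range(cfg.max_attempts):
        p = rng.uniform(lo, hi)
        if not 0 < p < 1:
            continue
        maf = draw_maf(p, cfg.F, rng)
        v_g = simulate_genotype_column(cfg.n, maf, rng)
        if np.ptp(v_g) > 0:
            return maf, v_g
    raise DataError("could not draw a non-constant genotype column within "
                    f"{cfg.max_attempts} attempts")


def generate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a genotype + methylation cohort with survival outcomes.

    The first ``n_p`` columns of each layer form correlated pairs,
    accepted by rejection sampling on the empirical pair correlation;
    remaining genotype columns are independent loci and remaining
    methylation columns pure noise.  The latent age is the linear score
    of the concatenated matrix under uniform weights, affinely rescaled
    into ``age_range``; a uniform onset age decides case status.  Cases
    carry the onset age with event = 1, controls the latent age with
    event = 0.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    lo_c, hi_c = cfg.cor_interval

    g_cols, m_cols, mafs, pair_map = [], [], [], []
    for pair in range(cfg.n_p):
        accepted = False
        for attempt in range(cfg.max_attempts):
            maf, v_g = _draw_locus(cfg, rng)
            v_m = simulate_methylation_pair(v_g, maf, cfg.h, rng)
            r = float(np.corrcoef(v_g, v_m)[0, 1])
            if lo_c <= r <= hi_c:
                g_cols.append(v_g)
                m_cols.append(v_m)
                mafs.append(maf)
                pair_map.append((pair, pair))
                accepted = True
                break
        if not accepted:
            raise DataError(
                f"pair {pair}: no draw with correlation in "
                f"[{lo_c}, {hi_c}] within {cfg.max_attempts} attempts "
                f"(acceptance rate 0/{cfg.max_attempts})")
    for _ in range(cfg.n_g - cfg.n_p):
        maf, v_g = _draw_locus(cfg, rng)
        g_cols.append(v_g)
        mafs.append(maf)
    noise_sd = np.sqrt(1 - cfg.h ** 2)
    for _ in range(cfg.n_m - cfg.n_p):
        m_cols.append(rng.normal(0.0, noise_sd, size=cfg.n))

    X_g = np.column_stack(g_cols).astype(float)
    X_m = np.column_stack(m_cols)
    X = np.concatenate([X_g, X_m], axis=1)
    v = rng.uniform(0.0, 1.0, size=cfg.n_g + cfg.n_m)
    score = X @ v
    a_lo, a_hi = cfg.age_range
    span = score.max() - score.min()
    if span == 0:
        raise DataError("degenerate linear score: all individuals equal")
    age = a_lo + (score - score.min()) / span * (a_hi - a_lo)
    onset = rng.uniform(a_lo, a_hi, size=cfg.n)
    status = (onset < age).astype(int)
    observed = np.where(status == 1, onset, age)

    sample_id = np.array([f"S{i + 1:05d}" for i in range(cfg.n)],
                         dtype=object)
    g_ids = np.array([f"locus_{j + 1:04d}" for j in range(cfg.n_g)],
                     dtype=object)
    m_ids = np.array([f"cpg_{j + 1:04d}" for j in range(cfg.n_m)],
                     dtype=object)
    genetic = DataLayer("genetic", sample_id, g_ids, X_g)
    methyl = DataLayer("methylation", sample_id, m_ids, X_m)
    outcome = OutcomeTable(sample_id, observed, status)
    truth = {"v": v, "maf": np.array(mafs), "pair_map": pair_map,
             "latent_age": age, "onset": onset}
    return SimulatedCohort(genetic, methyl, outcome, truth)


def bootstrap_cohort(layers: list[DataLayer], outcome: OutcomeTable,
                     s: int, separation_years: float = 5.0,
                     rng: np.random.Generator | None = None,
                     direction: str = "symmetric"):
    """Entry-wise within-group bootstrap of an existing cohort.

    Draws ``s`` case/control labels with replacement at the empirical
    frequency, fills every feature (and the age) entry-by-entry from the
    matching pool, then separates the group age distributions by
    ``separation_years``: symmetrically by default (cases shifted down by
    half, controls up by half), or one-sidedly with
    ``direction="cases_down"`` / ``"controls_up"``.

    Returns (new_layers, new_outcome).
    """
    rng = rng if rng is not None else np.random.default_rng()
    if direction not in ("symmetric", "cases_down", "controls_up"):
        raise DataError(f"unknown direction {direction!r}")
    ev = outcome.event
    pools = {1: np.flatnonzero(ev == 1), 0: np.flatnonzero(ev == 0)}
    if s > 0 and (pools[1].size == 0 or pools[0].size == 0):
        raise DataError("source cohort must contain both cases and controls")
    labels = (rng.random(s) < ev.mean()).astype(int) if s > 0 else \
        np.zeros(0, dtype=int)

    new_values = [np.empty((s, layer.p)) for layer in layers]
    new_ages = np.empty(s)
    for label in (0, 1):
        rows = np.flatnonzero(labels == label)
        pool = pools[label]
        if rows.size == 0:
            continue
        for vals, layer in zip(new_values, layers):
            pick = rng.integers(0, pool.size, size=(rows.size, layer.p))
            vals[rows] = layer.values[pool[pick], np.arange(layer.p)]
        pick = rng.integers(0, pool.size, size=rows.size)
        new_ages[rows] = outcome.observed_age[pool[pick]]

    if direction == "symmetric":
        shift_case, shift_ctrl = -separation_years / 2, separation_years / 2
    elif direction == "cases_down":
        shift_case, shift_ctrl = -separation_years, 0.0
    else:
        shift_case, shift_ctrl = 0.0, separation_years
    new_ages = new_ages + np.where(labels == 1, shift_case, shift_ctrl)

    sample_id = np.array([f"B{i + 1:06d}" for i in range(s)], dtype=object)
    out_layers = [DataLayer(layer.name, sample_id, layer.feature_id, vals)
                  for layer, vals in zip(layers, new_values)]
    return out_layers, OutcomeTable(sample_id, new_ages, labels)
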