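"""Shared fixtures and independent oracles."""

import numpy as np
import pytest

from coophaz import DataLayer, OutcomeTable, SimulationConfig, \
    generate_cohort


def make_outcome(ages, events, prefix="s"):
    ids = [f"{prefix}{i}" for i in range(len(ages))]
    return OutcomeTable(ids, ages, events)


def make_layer(values, name="layer", prefix="s"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    ids = [f"{prefix}{i}" for i in range(values.shape[0])]
    fids = [f"f{j}" for j in range(values.shape[1])]
    return DataLayer(name, ids, fids, values)


def random_instance(rng, n_max=8, p_max=3, ensure_event=True):
    """Small random survival instance for oracle comparisons."""
    n = int(rng.integers(2, n_max + 1))
    p = int(rng.integers(1, p_max + 1))
    Z = rng.normal(size=(n, p))
    # mix of tied and distinct ages
    ages = rng.choice(np.arange(1.0, n + 1.0), size=n, replace=True)
    events = rng.integers(0, 2, size=n)
    if ensure_event and events.sum() == 0:
        events[int(rng.integers(0, n))] = 1
    beta = rng.normal(size=p)
    return Z, ages, events, beta


def brute_force_pll(Z, ages, events, beta):
    """Explicit risk-set enumeration of the Cox partial log-likelihood."""
    total = 0.0
    for i in range(len(ages)):
        if events[i] != 1:
            continue
        risk = [j for j in range(len(ages)) if ages[j] >= ages[i]]
        lps = [float(beta @ Z[j]) for j in risk]
        total += float(beta @ Z[i]) - np.log(np.sum(np.exp(lps)))
    return total


def brute_force_conditional(Z, ages, events, beta, risk_set="at_risk"):
    """Explicit enumeration of the conditional partial log-likelihood."""
    total = 0.0
    for i in range(len(ages)):
        if risk_set == "at_risk":
            risk = [j for j in range(len(ages)) if ages[j] >= ages[i]]
        else:
            risk = [j for j in range(len(ages)) if ages[j] <= ages[i]]
        lps = [float(beta @ Z[j]) for j in risk]
        total += float(beta @ Z[i]) - np.log(np.sum(np.exp(lps)))
    return total


def brute_force_cindex(ages, events, risk):
    conc = ties = comp = 0
    n = len(ages)
    for i in range(n):
        for j in range(n):
            if ages[i] < ages[j] and events[i] == 1:
                comp += 1
                if risk[i] > risk[j]:
                    conc += 1
                elif risk[i] == risk[j]:
                    ties += 1
    return (conc + 0.5 * ties) / comp


def brute_force_auc(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    wins = ties = 0
    cases = scores[labels == 1]
    ctrls = scores[labels == 0]
    for c in cases:
        for k in ctrls:
            if c > k:
                wins += 1
            elif c == k:
                ties += 1
    return (wins + 0.5 * ties) / (len(cases) * len(ctrls))


@pytest.fixture(scope="session")
def small_cohort():
    """Small simulated two-layer cohort shared across tests."""
    return generate_cohort(SimulationConfig(n=60, n_g=5, n_m=5, n_p=2,
                                            seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
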