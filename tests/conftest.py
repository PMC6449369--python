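from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from divehmm.hmm_core import (
    EmissionParams,
    HMMParameters,
    TransitionCoefficients,
)

DATA_DIR = Path(__file__).resolve().parent.parent / "data"


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tracking_table():
    return pd.read_csv(DATA_DIR / "tracking_summary.csv")


def make_params(n_states=3, p=0, seed=0):
    """Random valid parameters for oracle fixtures."""
    r = np.random.default_rng(seed)
    mu = r.uniform(5, 50, size=(n_states, 4))
    sigma = r.uniform(1, 10, size=(n_states, 4))
    m = r.uniform(-np.pi, np.pi, size=n_states)
    kappa = r.uniform(0, 3, size=n_states)
    beta = r.normal(0, 0.7, size=(n_states, n_states, 1 + p))
    return HMMParameters(
        EmissionParams(mu, sigma, m, kappa), TransitionCoefficients(beta)
    )


def make_obs_frame(n_states, p, T, seed=0, missing_angle_first=True):
    """Random observation frame compatible with make_params."""
    r = np.random.default_rng(seed + 1000)
    df = pd.DataFrame(
        {
            "individual_id": "a",
            "segment_id": "s0",
            "batch_index": np.arange(T),
            "max_depth": r.gamma(5, 4, T),
            "dive_duration": r.gamma(6, 5, T),
            "surface_duration": r.gamma(4, 6, T),
            "step_length": r.gamma(3, 10, T),
            "turning_angle": r.uniform(-np.pi, np.pi, T),
        }
    )
    if missing_angle_first:
        df.loc[0, "turning_angle"] = np.nan
    for j in range(p):
        df[f"z{j + 1}"] = r.normal(size=T)
    return df


def brute_force_loglik(params, df, design_columns=()):
    """Exhaustive path-enumeration likelihood for small fixtures."""
    from itertools import product

    from divehmm import hmm_core as hc

    packed = hc.pack_batches(df, design_columns)
    logB, Gam, pi0 = hc._prepare(params, packed)
    total = 0.0
    with np.errstate(divide="ignore"):
        logGam = np.log(Gam)
        logpi = np.log(pi0)
    for s in range(packed.n_sequences):
        L = packed.lengths[s]
        acc = -np.inf
        for path in product(range(params.n_states), repeat=int(L)):
            lp = logpi[s, path[0]] + logB[s, 0, path[0]]
            for t in range(1, L):
                lp += logGam[s, t, path[t - 1], path[t]] + logB[s, t, path[t]]
            acc = np.logaddexp(acc, lp)
        total += acc
    return total


def brute_force_viterbi(params, df, design_columns=()):
    """Exhaustive argmax path for small fixtures (first-best on ties)."""
    from itertools import product

    from divehmm import hmm_core as hc

    packed = hc.pack_batches(df, design_columns)
    logB, Gam, pi0 = hc._prepare(params, packed)
    with np.errstate(divide="ignore"):
        logGam = np.log(Gam)
        logpi = np.log(pi0)
    out = np.full(len(df), -1, dtype=int)
    for s in range(packed.n_sequences):
        L = int(packed.lengths[s])
        best, best_lp = None, -np.inf
        for path in product(range(params.n_states), repeat=L):
            lp = logpi[s, path[0]] + logB[s, 0, path[0]]
            for t in range(1, L):
                lp += logGam[s, t, path[t - 1], path[t]] + logB[s, t, path[t]]
            if lp > best_lp:
                best, best_lp = path, lp
        rows = packed.row_index[s, :L]
        out[rows] = best
    return out


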