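"""State decoding, diagnostics and covariate-profile summaries.

Decoding uses the Viterbi algorithm with batch-specific transition
matrices.  Covariate profiles report the stationary state-occupancy
probabilities as a function of one covariate (the others held at their
means / reference levels), with confidence bands from Monte-Carlo draws of
the working parameters out of the fitted covariance.  Goodness of fit is
assessed through one-step-ahead (forecast) pseudo-residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtri

from .hmm_core import (
    N_GAMMA,
    STATE_LABELS,
    FittedModel,
    HMMParameters,
    _as_packed,
    _forward,
    _prepare,
    _transition_matrices,
    gamma_shape_scale,
    natural_from_working,
    stationary_distribution,
)
from .preprocess import CHANNELS, GAMMA_CHANNELS

__all__ = [
    "viterbi",
    "stationary_distribution",
    "state_probability_profile",
    "pseudo_residuals",
    "activity_budget",
    "ProfileCurve",
]

RESIDUAL_CLAMP = 1e-12


# ---------------------------------------------------------------------------
# Viterbi decoding
# ---------------------------------------------------------------------------

def viterbi(params: HMMParameters, batches, design_columns=()) -> np.ndarray:
    """Jointly most probable state path, one (0-based) state per batch row.

    Runs per segment with the batch-specific transition matrices; ties are
    broken toward the lowest state index.  Returns an int array aligned with
    the input row order.
    """
    if not isinstance(batches, pd.DataFrame) or len(batches) > 0:
        packed = _as_packed(batches, design_columns)
    else:
        return np.empty(0, dtype=int)
    S, T, N = packed.X.shape[0], packed.X.shape[1], params.n_states
    logB, Gam, pi0 = _prepare(params, packed)
    with np.errstate(divide="ignore"):
        logGam = np.log(Gam)
        logpi = np.log(pi0)
    delta = logpi + logB[:, 0]
    psi = np.zeros((S, T, N), dtype=int)
    for t in range(1, T):
        cand = delta[:, :, None] + logGam[:, t]  # (S, from, to)
        psi[:, t] = cand.argmax(axis=1)
        delta = cand.max(axis=1) + logB[:, t]
    path = np.empty((S, T), dtype=int)
    path[:, T - 1] = delta.argmax(axis=1)
    rows = np.arange(S)
    for t in range(T - 2, -1, -1):
        path[:, t] = psi[rows, t + 1, path[:, t + 1]]
    n_rows = int(packed.row_index.max()) + 1
    out = np.full(n_rows, -1, dtype=int)
    valid = packed.row_index >= 0
    out[packed.row_index[valid]] = path[valid]
    return out


def state_labels(states: np.ndarray) -> np.ndarray:
    """Map canonical 0-based state indices to their behavioural labels."""
    return np.asarray(STATE_LABELS, dtype=object)[np.asarray(states, int)]


# ---------------------------------------------------------------------------
# covariate profiles
# ---------------------------------------------------------------------------

@dataclass
class ProfileCurve:
    """Stationary state probabilities along one covariate's natural-scale grid."""

    covariate: str
    grid: np.ndarray          # (G,) natural-scale values (or level labels)
    point: np.ndarray         # (G, N)
    lo: np.ndarray            # (G, N)
    hi: np.ndarray            # (G, N)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g, gv in enumerate(self.grid):
            for i, lab in enumerate(STATE_LABELS[: self.point.shape[1]]):
                rows.append(
                    {
                        "covariate": self.covariate,
                        "value": gv,
                        "state": lab,
                        "probability": self.point[g, i],
                        "lo": self.lo[g, i],
                        "hi": self.hi[g, i],
                    }
                )
        return pd.DataFrame(rows)


def _stationary_stack(beta, Z) -> np.ndarray:
    """Stationary distributions for a stack of design rows (G, 1 + p)."""
    G = _transition_matrices(beta, Z)
    n = G.shape[-1]
    A = np.swapaxes(np.eye(n) - G, -1, -2).copy()
    A[..., -1, :] = 1.0
    b = np.zeros(A.shape[:-2] + (n, 1))
    b[..., -1, 0] = 1.0
    try:
        return np.linalg.solve(A, b)[..., 0]
    except np.linalg.LinAlgError:
        flatA = A.reshape(-1, n, n)
        flatB = b.reshape(-1, n, 1)
        out = np.full((flatA.shape[0], n), np.nan)
        for i in range(flatA.shape[0]):
            try:
                out[i] = np.linalg.solve(flatA[i], flatB[i])[:, 0]
            except np.linalg.LinAlgError:
                out[i] = 1.0 / n
        return out.reshape(A.shape[:-2] + (n,))


def state_probability_profile(
    fit: FittedModel,
    covariate: str,
    grid=None,
    n_draws: int = 1000,
    seed: int | None = None,
) -> ProfileCurve:
    """Stationary state probabilities over a covariate grid, with 95% MC bands.

    The target covariate is swept over ``grid`` (natural scale; defaults to
    100 points across its observed range) while all other continuous
    covariates sit at their means (0 on the standardized scale) and
    categorical ones at their reference level.  Bands are 2.5/97.5
    percentiles over ``n_draws`` multivariate-normal draws of the working
    parameters from the fitted covariance.
    """
    cs = fit.spec.covariate_spec
    cov = cs[covariate]
    design_cols = cs.design_columns
    p = len(design_cols)
    N = fit.spec.n_states
    if fit.cov is None or not np.all(np.isfinite(fit.cov)):
        raise ValueError("fitted covariance is missing or singular")

    if cov.kind == "continuous":
        if grid is None:
            if cov.vmin is None:
                raise ValueError(f"no observed range stored for {covariate!r}")
            grid = np.linspace(cov.vmin, cov.vmax, 100)
        grid = np.asarray(grid, float)
        if cov.vmin is not None and (
            grid.min() < cov.vmin - 1e-9 or grid.max() > cov.vmax + 1e-9
        ):
            warnings.warn(f"profile grid extends outside the observed range of {covariate!r}")
        std = cs.standardize_value(covariate, grid)
        Z = np.zeros((grid.size, 1 + p))
        Z[:, 0] = 1.0
        Z[:, 1 + design_cols.index(covariate)] = std
        grid_out = grid
    else:
        levels = list(cov.levels) if grid is None else list(grid)
        Z = np.zeros((len(levels), 1 + p))
        Z[:, 0] = 1.0
        for g, lv in enumerate(levels):
            if lv != cov.reference:
                Z[g, 1 + design_cols.index(f"{covariate}[{lv}]")] = 1.0
        grid_out = np.asarray(levels, dtype=object)

    point = _stationary_stack(fit.params.transition.beta, Z)

    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(
        np.asarray(fit.working, float), np.asarray(fit.cov, float),
        size=n_draws, check_valid="ignore", method="svd",
    )
    probs = np.empty((n_draws, Z.shape[0], N))
    for d in range(n_draws):
        pars = natural_from_working(draws[d], N, p, fit.params.initial_rule)
        probs[d] = _stationary_stack(pars.transition.beta, Z)
    lo = np.nanpercentile(probs, 2.5, axis=0)
    hi = np.nanpercentile(probs, 97.5, axis=0)
    return ProfileCurve(covariate, grid_out, point, lo, hi)


# ---------------------------------------------------------------------------
# pseudo-residuals
# ---------------------------------------------------------------------------

def _vonmises_cdf_interval(x, m, kappa):
    """P(angle in (-pi, x]) for a von Mises(m, kappa) variable."""
    # scipy's vonmises cdf is the unwrapped antiderivative, so differencing
    # two evaluations gives the mass of the arc
    return stats.vonmises.cdf(x - m, kappa) - stats.vonmises.cdf(-np.pi - m, kappa)


def pseudo_residuals(fit_or_params, batches, design_columns=None) -> pd.DataFrame:
    """One-step-ahead forecast pseudo-residuals per channel, on the normal scale.

    For batch b and channel c the residual is ``ndtri(sum_i w_ib F_ic(x_bc))``
    where ``w_ib`` is the state-prediction probability given batches 1..b-1
    (the initial distribution at the first batch of a segment) and ``F_ic``
    the state-c channel CDF.  MISSING channels give MISSING residuals;
    probability-integral values are clamped to ``[1e-12, 1 - 1e-12]``.
    """
    if isinstance(fit_or_params, FittedModel):
        params = fit_or_params.params
        if design_columns is None:
            design_columns = fit_or_params.spec.covariate_spec.design_columns
    else:
        params = fit_or_params
        if design_columns is None:
            design_columns = ()
    packed = _as_packed(batches, design_columns)
    logB, Gam, pi0 = _prepare(params, packed)
    _, alpha, _, _, _ = _forward(logB, Gam, pi0, packed.lengths)
    S, T, _ = packed.X.shape
    N = params.n_states
    w = np.empty((S, T, N))
    w[:, 0] = pi0
    if T > 1:
        w[:, 1:] = np.einsum("sti,stij->stj", alpha[:, :-1], Gam[:, 1:])

    em = params.emission
    U = np.full((S, T, len(CHANNELS)), np.nan)
    for c in range(N_GAMMA):
        x = packed.X[..., c]
        ok = np.isfinite(x)
        if not ok.any():
            continue
        F = np.zeros(ok.sum())
        for i in range(N):
            a, s = gamma_shape_scale(em.mu[i, c], em.sigma[i, c])
            F += w[..., i][ok] * stats.gamma.cdf(x[ok], a, scale=s)
        U[..., c][ok] = F
    ang = packed.X[..., N_GAMMA]
    ok = np.isfinite(ang)
    if ok.any():
        F = np.zeros(ok.sum())
        for i in range(N):
            F += w[..., i][ok] * _vonmises_cdf_interval(
                ang[ok], em.angle_mean[i], em.angle_kappa[i]
            )
        U[..., N_GAMMA][ok] = F

    finite = np.isfinite(U)
    clipped = finite & ((U < RESIDUAL_CLAMP) | (U > 1 - RESIDUAL_CLAMP))
    if clipped.any():
        warnings.warn(f"{int(clipped.sum())} pseudo-residuals clamped at the tails")
        U = np.clip(U, RESIDUAL_CLAMP, 1 - RESIDUAL_CLAMP)

    n_rows = int(packed.row_index.max()) + 1
    out = pd.DataFrame(
        np.nan, index=range(n_rows), columns=[f"resid_{c}" for c in CHANNELS]
    )
    valid = packed.row_index >= 0
    rows = packed.row_index[valid]
    for c, name in enumerate(CHANNELS):
        vals = np.full(n_rows, np.nan)
        u = U[..., c][valid]
        ok = np.isfinite(u)
        vals[rows[ok]] = ndtri(u[ok])
        out[f"resid_{name}"] = vals
    return out


# ---------------------------------------------------------------------------
# activity budgets
# ---------------------------------------------------------------------------

def activity_budget(
    states: np.ndarray,
    batches: pd.DataFrame,
    n_states: int = 3,
    tz_offset_hours: float = 1.0,
):
    """Hour-of-day state frequencies and overall per-individual proportions.

    Returns ``(budget, proportions, average)``: ``budget`` has one row per
    populated (individual, hour, state) with frequencies summing to 1 within
    each populated (individual, hour); hours with no batches are omitted,
    not zero-filled.  ``proportions`` gives each individual's overall state
    proportions; ``average`` is their unweighted cross-individual mean.
    """
    df = pd.DataFrame(
        {
            "individual_id": batches["individual_id"].to_numpy(),
            "hour": (
                pd.to_datetime(batches["t_begin"])
                + pd.to_timedelta(tz_offset_hours, unit="h")
            ).dt.hour,
            "state": np.asarray(states, int),
        }
    )
    rows = []
    for (ind, hour), sub in df.groupby(["individual_id", "hour"], sort=True):
        counts = np.bincount(sub["state"], minlength=n_states)
        freq = counts / counts.sum()
        for i in range(n_states):
            rows.append(
                {
                    "individual_id": ind,
                    "hour": hour,
                    "state": STATE_LABELS[i] if i < len(STATE_LABELS) else str(i),
                    "frequency": freq[i],
                }
            )
    budget = pd.DataFrame(rows)

    prop_rows = []
    for ind, sub in df.groupby("individual_id", sort=True):
        counts = np.bincount(sub["state"], minlength=n_states)
        props = counts / counts.sum()
        rec = {"individual_id": ind}
        for i in range(n_states):
            rec[STATE_LABELS[i] if i < len(STATE_LABELS) else str(i)] = props[i]
        prop_rows.append(rec)
    proportions = pd.DataFrame(prop_rows).set_index("individual_id")
    average = proportions.mean(axis=0)
    return budget, proportions, average
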