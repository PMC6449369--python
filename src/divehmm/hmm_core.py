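"""Multivariate covariate-dependent hidden Markov model core.

The model: an N-state first-order Markov chain whose one-step transition
probabilities depend on covariates through a multinomial logit with the
staying probability as reference category,

    Gamma_b[i, j] = exp(eta_ij(z_b)) / (1 + sum_{l != i} exp(eta_il(z_b))),
    eta_ij(z) = beta_ij0 + beta_ij1 z_1 + ... + beta_ijp z_p,   j != i,

and, conditional on the state, independent emissions for five channels:
gamma distributions (mean/sd parameterization) for maximum depth, dive
duration, surface duration and step length, and a von Mises distribution
for the turning angle.  MISSING channel values are marginalized out.

The likelihood is evaluated with a scaled forward recursion vectorized
across sequences (individuals x track segments); its exact gradient in the
unconstrained working parameterization is obtained from the forward-backward
smoothing probabilities, which keeps numerical maximization fast.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import digamma, gammaln, i0e, i1e

from .preprocess import ANGLE_CHANNEL, CHANNELS, GAMMA_CHANNELS, Covariate, CovariateSpec

N_GAMMA = len(GAMMA_CHANNELS)
KAPPA_EPS = 1e-10
LOG_DENSITY_FLOOR = np.log(1e-300)

#: canonical state labels, in ascending order of step-length mean
STATE_LABELS = ("resting", "foraging", "travelling")


def wrap_angle(a):
    """Wrap angles to (-pi, pi]."""
    a = np.asarray(a, float)
    w = -(np.mod(-a + np.pi, 2 * np.pi) - np.pi)
    return w if w.ndim else float(w)


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class EmissionParams:
    """State-dependent emission parameters.

    ``mu``/``sigma`` have shape (N, 4) in channel order
    (max_depth, dive_duration, surface_duration, step_length);
    ``angle_mean``/``angle_kappa`` have shape (N,).
    """

    mu: np.ndarray
    sigma: np.ndarray
    angle_mean: np.ndarray
    angle_kappa: np.ndarray

    def __post_init__(self):
        self.mu = np.atleast_2d(np.asarray(self.mu, float))
        self.sigma = np.atleast_2d(np.asarray(self.sigma, float))
        self.angle_mean = np.atleast_1d(np.asarray(self.angle_mean, float))
        self.angle_kappa = np.atleast_1d(np.asarray(self.angle_kappa, float))
        if self.mu.shape != self.sigma.shape or self.mu.shape[1] != N_GAMMA:
            raise ValueError("mu/sigma must both have shape (N, 4)")
        if np.any(self.mu <= 0) or np.any(self.sigma <= 0):
            raise ValueError("gamma means and sds must be positive")
        if np.any(self.angle_kappa < 0):
            raise ValueError("von Mises concentration must be non-negative")

    @property
    def n_states(self) -> int:
        return self.mu.shape[0]


@dataclass
class TransitionCoefficients:
    """Multinomial-logit coefficients ``beta`` with shape (N, N, 1 + p).

    ``beta[i, j, 0]`` is the intercept of the i->j predictor and
    ``beta[i, j, 1:]`` the covariate slopes; the diagonal is the reference
    category and carries no coefficients (kept at zero).
    """

    beta: np.ndarray

    def __post_init__(self):
        self.beta = np.asarray(self.beta, float)
        if self.beta.ndim != 3 or self.beta.shape[0] != self.beta.shape[1]:
            raise ValueError("beta must have shape (N, N, 1 + p)")
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("beta must be finite")
        di = np.arange(self.beta.shape[0])
        self.beta[di, di, :] = 0.0

    @property
    def n_states(self) -> int:
        return self.beta.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.beta.shape[2] - 1


@dataclass
class HMMParameters:
    emission: EmissionParams
    transition: TransitionCoefficients
    initial_rule: str = "stationary"  # stationary-at-first-covariates | uniform

    def __post_init__(self):
        if self.initial_rule not in ("stationary", "uniform"):
            raise ValueError("initial_rule must be 'stationary' or 'uniform'")
        if self.emission.n_states != self.transition.n_states:
            raise ValueError("emission/transition state counts disagree")

    @property
    def n_states(self) -> int:
        return self.emission.n_states

    def to_dict(self) -> dict:
        return {
            "emission": {
                "mu": self.emission.mu.tolist(),
                "sigma": self.emission.sigma.tolist(),
                "angle_mean": self.emission.angle_mean.tolist(),
                "angle_kappa": self.emission.angle_kappa.tolist(),
            },
            "transition": {"beta": self.transition.beta.tolist()},
            "initial_rule": self.initial_rule,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HMMParameters":
        em = d["emission"]
        return cls(
            EmissionParams(
                np.array(em["mu"]), np.array(em["sigma"]),
                np.array(em["angle_mean"]), np.array(em["angle_kappa"]),
            ),
            TransitionCoefficients(np.array(d["transition"]["beta"])),
            d.get("initial_rule", "stationary"),
        )


@dataclass
class ModelSpec:
    """Model dimensions: state count and the encoded covariate design."""

    n_states: int = 3
    covariate_spec: CovariateSpec = field(default_factory=CovariateSpec)

    def __post_init__(self):
        if self.n_states < 2:
            raise ValueError("need at least two states")

    @property
    def n_design(self) -> int:
        return self.covariate_spec.n_design


@dataclass
class FittedModel:
    params: HMMParameters
    spec: ModelSpec
    loglik: float
    k: int
    n_batches: int
    converged: bool
    working: np.ndarray
    cov: np.ndarray | None
    restarts_summary: list

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "n_states": self.spec.n_states,
            "design_columns": self.spec.covariate_spec.design_columns,
            "loglik": self.loglik,
            "k": self.k,
            "n_batches": self.n_batches,
            "converged": bool(self.converged),
            "working": np.asarray(self.working).tolist(),
            "cov": None if self.cov is None else np.asarray(self.cov).tolist(),
            "restarts_summary": self.restarts_summary,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict, covariate_spec: CovariateSpec | None = None) -> "FittedModel":
        spec = ModelSpec(
            n_states=int(d["n_states"]),
            covariate_spec=covariate_spec or CovariateSpec(),
        )
        return cls(
            params=HMMParameters.from_dict(d["params"]),
            spec=spec,
            loglik=float(d["loglik"]),
            k=int(d["k"]),
            n_batches=int(d["n_batches"]),
            converged=bool(d["converged"]),
            working=np.asarray(d["working"], float),
            cov=None if d.get("cov") is None else np.asarray(d["cov"], float),
            restarts_summary=d.get("restarts_summary", []),
        )

    @classmethod
    def load(cls, path, covariate_spec: CovariateSpec | None = None) -> "FittedModel":
        with open(path) as fh:
            d = json.load(fh)
        loaded = cls.from_dict(d, covariate_spec)
        if covariate_spec is None and d.get("design_columns"):
            # design columns are known but the covariate transforms are not;
            # callers needing profiles must supply the fitted CovariateSpec
            loaded.spec.covariate_spec = CovariateSpec(
                [Covariate(name, "continuous") for name in d["design_columns"]]
            )
        return loaded


# ---------------------------------------------------------------------------
# elementary densities
# ---------------------------------------------------------------------------

def gamma_shape_scale(mu, sigma):
    """Convert a gamma (mean, sd) pair to (shape, scale)."""
    mu = np.asarray(mu, float)
    sigma = np.asarray(sigma, float)
    if np.any(mu <= 0) or np.any(sigma <= 0):
        raise ValueError("gamma mean and sd must be positive")
    return mu**2 / sigma**2, sigma**2 / mu


def gamma_logpdf_musigma(x, mu, sigma):
    """Gamma log-density at ``x`` under the mean/sd parameterization."""
    a, s = gamma_shape_scale(mu, sigma)
    x = np.asarray(x, float)
    return (a - 1) * np.log(x) - x / s - a * np.log(s) - gammaln(a)


def vonmises_logdensity(angle, m, kappa):
    """Von Mises log-density; ``kappa = 0`` is the circular uniform 1/(2 pi)."""
    kappa = np.asarray(kappa, float)
    if np.any(kappa < 0):
        raise ValueError("kappa must be non-negative")
    # log I0(kappa) = log(i0e(kappa)) + kappa, stable for large kappa
    return (
        kappa * np.cos(np.asarray(angle, float) - np.asarray(m, float))
        - np.log(2 * np.pi)
        - (np.log(i0e(kappa)) + kappa)
    )


def emission_logdensity(obs, emission: EmissionParams, state: int) -> float:
    """Joint log-density of one observation under one state.

    ``obs`` maps channel names to values; channels that are absent or NaN
    are marginalized out (contribute 0).  Non-positive values in a gamma
    channel raise.
    """
    total = 0.0
    for c, name in enumerate(GAMMA_CHANNELS):
        v = obs.get(name, np.nan)
        if v is None or not np.isfinite(v):
            continue
        if v <= 0:
            raise ValueError(f"non-positive value {v} in gamma channel {name!r}")
        total += float(
            gamma_logpdf_musigma(v, emission.mu[state, c], emission.sigma[state, c])
        )
    ang = obs.get(ANGLE_CHANNEL, np.nan)
    if ang is not None and np.isfinite(ang):
        total += float(
            vonmises_logdensity(ang, emission.angle_mean[state], emission.angle_kappa[state])
        )
    return total


# ---------------------------------------------------------------------------
# transition matrices
# ---------------------------------------------------------------------------

def transition_matrix(beta, z) -> np.ndarray:
    """N x N transition matrix at covariate vector ``z`` (length p)."""
    if isinstance(beta, TransitionCoefficients):
        beta = beta.beta
    beta = np.asarray(beta, float)
    z = np.asarray(z, float).ravel()
    if z.size != beta.shape[2] - 1:
        raise ValueError(
            f"covariate vector has length {z.size}, expected {beta.shape[2] - 1}"
        )
    design = np.concatenate([[1.0], z])
    return _transition_matrices(beta, design[None, :])[0]


def _transition_matrices(beta, design) -> np.ndarray:
    """Row-stochastic matrices for a stack of design vectors (..., 1 + p)."""
    H = np.einsum("...k,ijk->...ij", design, beta)
    n = beta.shape[0]
    di = np.arange(n)
    H[..., di, di] = 0.0  # reference category: stay put
    H -= H.max(axis=-1, keepdims=True)
    G = np.exp(H)
    G /= G.sum(axis=-1, keepdims=True)
    return G


def stationary_distribution(gamma: np.ndarray) -> np.ndarray:
    """Stationary probability vector of a row-stochastic matrix.

    Raises when the stationary distribution is not unique (reducible chain)
    or not strictly positive.
    """
    gamma = np.asarray(gamma, float)
    n = gamma.shape[0]
    if not np.allclose(gamma.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("matrix is not row-stochastic")
    sv = np.linalg.svd(np.eye(n) - gamma, compute_uv=False)
    if np.sum(sv < 1e-10 * max(1.0, sv[0])) > 1:
        raise ValueError("stationary distribution not unique")
    A = (np.eye(n) - gamma).T
    A[-1, :] = 1.0
    b = np.zeros(n)
    b[-1] = 1.0
    pi = np.linalg.solve(A, b)
    if np.any(pi <= 0):
        raise ValueError("stationary distribution not strictly positive")
    return pi


def _initial_distributions(Gam0, rule: str) -> np.ndarray:
    """Per-sequence initial state distribution from Gamma at the first batch."""
    S, n = Gam0.shape[0], Gam0.shape[1]
    pi0 = np.full((S, n), 1.0 / n)
    if rule == "stationary":
        for s in range(S):
            try:
                pi0[s] = stationary_distribution(Gam0[s])
            except (ValueError, np.linalg.LinAlgError):
                pass  # uniform fallback
    return pi0


# ---------------------------------------------------------------------------
# packing batch tables into padded arrays
# ---------------------------------------------------------------------------

@dataclass
class PackedSeries:
    """Batch series padded to a (sequence, time) grid for vectorized recursion."""

    X: np.ndarray        # (S, T, 5) channel values, NaN where missing/pad
    design: np.ndarray   # (S, T, 1 + p) with leading 1s column
    lengths: np.ndarray  # (S,)
    row_index: np.ndarray  # (S, T) original row positions, -1 at pads
    keys: list           # per-sequence (individual_id, segment_id)

    @property
    def n_sequences(self) -> int:
        return self.X.shape[0]

    @property
    def n_batches(self) -> int:
        """Batches contributing to the likelihood (>= 1 observed channel)."""
        present = np.isfinite(self.X).any(axis=2)
        return int(present.sum())


def pack_batches(batches: pd.DataFrame, design_columns=()) -> PackedSeries:
    """Group a batch table by (individual, segment) into padded arrays."""
    if len(batches) == 0:
        raise ValueError("empty batch table")
    df = batches.reset_index(drop=True)
    if "individual_id" not in df.columns:
        df = df.assign(individual_id="ind0")
    if "segment_id" not in df.columns:
        df = df.assign(segment_id="seg0")
    missing = [c for c in design_columns if c not in df.columns]
    if missing:
        raise KeyError(f"design columns missing from batches: {missing}")
    groups = []
    for key, sub in df.groupby(["individual_id", "segment_id"], sort=False):
        if "t_begin" in sub.columns:
            sub = sub.sort_values("t_begin", kind="stable")
        groups.append((key, sub))
    S = len(groups)
    T = max(len(sub) for _, sub in groups)
    p = len(design_columns)
    X = np.full((S, T, len(CHANNELS)), np.nan)
    design = np.zeros((S, T, 1 + p))
    design[:, :, 0] = 1.0
    lengths = np.zeros(S, dtype=int)
    row_index = np.full((S, T), -1, dtype=int)
    keys = []
    for s, (key, sub) in enumerate(groups):
        L = len(sub)
        lengths[s] = L
        keys.append(key)
        for c, name in enumerate(CHANNELS):
            if name in sub.columns:
                X[s, :L, c] = sub[name].to_numpy(float)
        for j, name in enumerate(design_columns):
            design[s, :L, 1 + j] = sub[name].to_numpy(float)
        row_index[s, :L] = sub.index.to_numpy()
    bad = X[..., :N_GAMMA] <= 0
    if np.any(bad & np.isfinite(X[..., :N_GAMMA])):
        raise ValueError("non-positive value in a gamma channel")
    return PackedSeries(X, design, lengths, row_index, keys)


def _as_packed(batches, design_columns=()) -> PackedSeries:
    if isinstance(batches, PackedSeries):
        return batches
    return pack_batches(batches, design_columns)


# ---------------------------------------------------------------------------
# emission log-probability grids
# ---------------------------------------------------------------------------

def _emission_logprob(X, emission: EmissionParams) -> np.ndarray:
    """(S, T, N) per-state log-densities; missing/pad entries contribute 0."""
    S, T, _ = X.shape
    N = emission.n_states
    logB = np.zeros((S, T, N))
    for c in range(N_GAMMA):
        x = X[..., c]
        ok = np.isfinite(x)
        if not ok.any():
            continue
        xv = x[ok]
        for i in range(N):
            logB[..., i][ok] += gamma_logpdf_musigma(
                xv, emission.mu[i, c], emission.sigma[i, c]
            )
    ang = X[..., N_GAMMA]
    ok = np.isfinite(ang)
    if ok.any():
        av = ang[ok]
        for i in range(N):
            logB[..., i][ok] += vonmises_logdensity(
                av, emission.angle_mean[i], emission.angle_kappa[i]
            )
    return np.maximum(logB, LOG_DENSITY_FLOOR)


# ---------------------------------------------------------------------------
# forward recursion / likelihood
# ---------------------------------------------------------------------------

def _forward(logB, Gam, pi0, lengths):
    """Scaled forward pass vectorized across sequences.

    Padding is inert by construction: padded logB entries are 0 and padded
    Gam slices are the identity, so padded steps multiply by 1.
    Returns (loglik_per_sequence, alpha_hat, log_scale, Bstar, m_shift).
    """
    S, T, N = logB.shape
    m = logB.max(axis=2)
    Bstar = np.exp(logB - m[:, :, None])
    alpha = np.empty((S, T, N))
    logc = np.empty((S, T))
    a = pi0 * Bstar[:, 0]
    c = a.sum(axis=1)
    alpha[:, 0] = a / c[:, None]
    logc[:, 0] = np.log(c) + m[:, 0]
    for t in range(1, T):
        pred = np.einsum("si,sij->sj", alpha[:, t - 1], Gam[:, t])
        a = pred * Bstar[:, t]
        c = a.sum(axis=1)
        alpha[:, t] = a / c[:, None]
        logc[:, t] = np.log(c) + m[:, t]
    return logc.sum(axis=1), alpha, logc, Bstar, m


def _prepare(params: HMMParameters, packed: PackedSeries):
    """logB, per-step transition matrices (pads = identity) and pi0."""
    N = params.n_states
    logB = _emission_logprob(packed.X, params.emission)
    Gam = _transition_matrices(params.transition.beta, packed.design)
    pad = packed.row_index < 0
    Gam[pad] = np.eye(N)
    logB[pad] = 0.0
    pi0 = _initial_distributions(Gam[:, 0], params.initial_rule)
    return logB, Gam, pi0


def forward_loglik(params: HMMParameters, batches, design_columns=None) -> float:
    """Total log-likelihood over all sequences via the scaled forward algorithm."""
    if design_columns is None:
        design_columns = _default_design_columns(params, batches)
    packed = _as_packed(batches, design_columns)
    if packed.n_batches == 0:
        raise ValueError("no observed batches")
    logB, Gam, pi0 = _prepare(params, packed)
    ll, *_ = _forward(logB, Gam, pi0, packed.lengths)
    return float(ll.sum())


def _default_design_columns(params, batches):
    p = params.transition.n_covariates
    if p == 0 or isinstance(batches, PackedSeries):
        return ()
    raise ValueError(
        "design_columns must name the p covariate columns when p > 0"
    )


# ---------------------------------------------------------------------------
# working-scale parameterization
# ---------------------------------------------------------------------------

def n_working(n_states: int, p: int) -> int:
    return 2 * N_GAMMA * n_states + 2 * n_states + n_states * (n_states - 1) * (1 + p)


def working_from_natural(params: HMMParameters) -> np.ndarray:
    """Map natural parameters to the unconstrained working vector.

    log for gamma means/sds, identity for angle means (periodic objective),
    log(kappa + eps) for concentrations and identity for beta.
    """
    em, beta = params.emission, params.transition.beta
    N = params.n_states
    off = ~np.eye(N, dtype=bool)
    w = np.concatenate(
        [
            np.log(em.mu).ravel(),
            np.log(em.sigma).ravel(),
            em.angle_mean,
            np.log(em.angle_kappa + KAPPA_EPS),
            beta[off].ravel(),
        ]
    )
    if not np.all(np.isfinite(w)):
        raise ValueError("non-finite working values")
    return w


def natural_from_working(
    w: np.ndarray, n_states: int, p: int, initial_rule: str = "stationary"
) -> HMMParameters:
    w = np.asarray(w, float)
    if not np.all(np.isfinite(w)):
        raise ValueError("non-finite working values")
    if w.size != n_working(n_states, p):
        raise ValueError("working vector has wrong length")
    N, q = n_states, N_GAMMA * n_states
    mu = np.exp(w[:q]).reshape(N, N_GAMMA)
    sigma = np.exp(w[q : 2 * q]).reshape(N, N_GAMMA)
    m = wrap_angle(w[2 * q : 2 * q + N])
    kappa = np.maximum(np.exp(w[2 * q + N : 2 * q + 2 * N]) - KAPPA_EPS, 0.0)
    beta = np.zeros((N, N, 1 + p))
    off = ~np.eye(N, dtype=bool)
    beta[off] = w[2 * q + 2 * N :].reshape(N * (N - 1), 1 + p)
    return HMMParameters(
        EmissionParams(mu, sigma, np.atleast_1d(m), kappa),
        TransitionCoefficients(beta),
        initial_rule,
    )


# ---------------------------------------------------------------------------
# negative log-likelihood with analytic gradient
# ---------------------------------------------------------------------------

def _nll_and_grad(w, packed: PackedSeries, n_states: int, p: int, initial_rule: str):
    """Negative log-likelihood and its exact working-scale gradient.

    The gradient uses the Fisher identity: smoothing probabilities weight the
    per-observation emission scores, pairwise smoothing probabilities weight
    the multinomial-logit scores, and the stationary initial distribution's
    dependence on beta is differentiated implicitly through its defining
    linear system.
    """
    N = n_states
    params = natural_from_working(w, N, p, initial_rule)
    em, beta = params.emission, params.transition.beta
    X, design, lengths = packed.X, packed.design, packed.lengths
    S, T, _ = X.shape
    pad = packed.row_index < 0

    # emission log-densities and per-parameter scores
    logB = np.zeros((S, T, N))
    d_mu = np.zeros((S, T, N, N_GAMMA))
    d_sigma = np.zeros((S, T, N, N_GAMMA))
    for c in range(N_GAMMA):
        x = X[..., c]
        ok = np.isfinite(x)
        if not ok.any():
            continue
        xv, lxv = x[ok], np.log(x[ok])
        for i in range(N):
            mu, sig = em.mu[i, c], em.sigma[i, c]
            a, s = mu**2 / sig**2, sig**2 / mu
            logB[..., i][ok] += (a - 1) * lxv - xv / s - a * np.log(s) - gammaln(a)
            dl_da = lxv - np.log(s) - digamma(a)
            dl_ds = xv / s**2 - a / s
            # chain to (mu, sigma): da/dmu = 2a/mu, ds/dmu = -s/mu, etc.
            d_mu[..., i, c][ok] = (2 * a / mu) * dl_da - (s / mu) * dl_ds
            d_sigma[..., i, c][ok] = (-2 * a / sig) * dl_da + (2 * s / sig) * dl_ds
    ang = X[..., N_GAMMA]
    ok = np.isfinite(ang)
    d_m = np.zeros((S, T, N))
    d_kappa = np.zeros((S, T, N))
    if ok.any():
        av = ang[ok]
        for i in range(N):
            m_i, k_i = em.angle_mean[i], em.angle_kappa[i]
            logB[..., i][ok] += (
                k_i * np.cos(av - m_i) - np.log(2 * np.pi) - (np.log(i0e(k_i)) + k_i)
            )
            d_m[..., i][ok] = k_i * np.sin(av - m_i)
            d_kappa[..., i][ok] = np.cos(av - m_i) - i1e(k_i) / i0e(k_i)
    logB = np.maximum(logB, LOG_DENSITY_FLOOR)
    logB[pad] = 0.0

    Gam = _transition_matrices(beta, design)
    Gam[pad] = np.eye(N)
    pi0 = _initial_distributions(Gam[:, 0], initial_rule)

    ll_seq, alpha, logc, Bstar, _ = _forward(logB, Gam, pi0, lengths)
    nll = -float(ll_seq.sum())

    # backward pass and pairwise smoothing probabilities
    c_t = np.exp(logc - logB.max(axis=2))  # local scale: c in the shifted units
    bet = np.empty((S, T, N))
    bet[:, T - 1] = 1.0
    xi = np.zeros((S, T, N, N))
    for t in range(T - 1, 0, -1):
        w_t = Bstar[:, t] * bet[:, t]
        xi[:, t] = (
            alpha[:, t - 1, :, None] * Gam[:, t] * w_t[:, None, :] / c_t[:, t, None, None]
        )
        bet[:, t - 1] = np.einsum("sij,sj->si", Gam[:, t], w_t) / c_t[:, t, None]
    gamma_smooth = alpha * bet

    # emission gradient, chained to the working scale
    g_mu = np.einsum("stic,sti->ic", d_mu, gamma_smooth) * em.mu
    g_sigma = np.einsum("stic,sti->ic", d_sigma, gamma_smooth) * em.sigma
    g_m = np.einsum("sti,sti->i", d_m, gamma_smooth)
    g_kappa = np.einsum("sti,sti->i", d_kappa, gamma_smooth) * (em.angle_kappa + KAPPA_EPS)

    # transition gradient: d logL / d eta_il summed against the design
    g_eta = xi - xi.sum(axis=3, keepdims=True) * Gam
    g_eta[:, 0] = 0.0
    g_beta = np.einsum("stil,stk->ilk", g_eta, design)

    if initial_rule == "stationary":
        g_beta += _initial_beta_gradient(Gam[:, 0], design[:, 0], gamma_smooth[:, 0], N)

    off = ~np.eye(N, dtype=bool)
    grad = -np.concatenate(
        [g_mu.ravel(), g_sigma.ravel(), g_m, g_kappa, g_beta[off].ravel()]
    )
    return nll, grad


def _initial_beta_gradient(Gam0, D0, gamma0, N):
    """Gradient contribution of log pi0 when pi0 is stationary at z_1."""
    S = Gam0.shape[0]
    p1 = D0.shape[1]
    g = np.zeros((N, N, p1))
    eyeN = np.eye(N)
    for s in range(S):
        G = Gam0[s]
        try:
            pi = stationary_distribution(G)
        except (ValueError, np.linalg.LinAlgError):
            continue  # uniform fallback carries no beta dependence
        A = (eyeN - G).T
        A[-1, :] = 1.0
        try:
            u = np.linalg.solve(A.T, gamma0[s] / pi)
        except np.linalg.LinAlgError:
            continue
        for i in range(N):
            for l in range(N):
                if l == i:
                    continue
                dG = np.zeros((N, N))
                dG[i, :] = -G[i, :] * G[i, l]
                dG[i, l] += G[i, l]
                dA = -dG.T
                dA[-1, :] = 0.0
                g[i, l, :] += -(u @ dA @ pi) * D0[s]
    return g


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _starting_values(spec: ModelSpec, packed: PackedSeries, rng, jitter: float):
    """Data-driven starts: quantile-split per-channel means, seeded jitter."""
    N = spec.n_states
    X = packed.X[packed.row_index >= 0]
    step = X[:, GAMMA_CHANNELS.index("step_length")]
    order = np.argsort(step)
    order = order[np.isfinite(step[order])]
    groups = np.array_split(order, N)
    mu = np.empty((N, N_GAMMA))
    sigma = np.empty((N, N_GAMMA))
    angle_mean = np.zeros(N)
    angle_kappa = np.full(N, 0.5)
    for i, idx in enumerate(groups):
        sub = X[idx]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mu[i] = np.nanmean(sub[:, :N_GAMMA], axis=0)
            sigma[i] = np.nanstd(sub[:, :N_GAMMA], axis=0)
        ang = sub[:, N_GAMMA]
        ang = ang[np.isfinite(ang)]
        if ang.size >= 5:
            # circular moment start: groups with reversal-heavy angles need a
            # mean near pi, which a flat zero start cannot reach
            z = np.exp(1j * ang).mean()
            R = min(abs(z), 0.999)
            angle_mean[i] = np.angle(z)
            angle_kappa[i] = R * (2 - R**2) / (1 - R**2)
    pooled_sd = np.nanstd(X[:, :N_GAMMA], axis=0)
    mu = np.where(np.isfinite(mu) & (mu > 0), mu, np.nanmean(X[:, :N_GAMMA], axis=0))
    sigma = np.where(np.isfinite(sigma) & (sigma > 0), sigma, pooled_sd)
    sigma = np.maximum(sigma, 1e-6)
    mu = np.maximum(mu, 1e-6)
    p = spec.n_design
    beta = np.zeros((N, N, 1 + p))
    beta[:, :, 0] = -2.0
    di = np.arange(N)
    beta[di, di, :] = 0.0
    mu = mu * np.exp(jitter * rng.standard_normal(mu.shape))
    sigma = sigma * np.exp(jitter * rng.standard_normal(sigma.shape))
    angle_mean = wrap_angle(angle_mean + 4 * jitter * rng.standard_normal(N))
    angle_kappa = np.maximum(angle_kappa, 0.05) * np.exp(jitter * rng.standard_normal(N))
    beta[:, :, 0] += 0.5 * jitter * rng.standard_normal((N, N)) * (~np.eye(N, dtype=bool))
    params = HMMParameters(
        EmissionParams(mu, sigma, np.atleast_1d(angle_mean), angle_kappa),
        TransitionCoefficients(beta),
    )
    return working_from_natural(params)


def _canonical_order(params: HMMParameters) -> np.ndarray:
    """Permutation ordering states by ascending step-length mean."""
    return np.argsort(params.emission.mu[:, GAMMA_CHANNELS.index("step_length")])


def relabel_states(params: HMMParameters, perm=None) -> HMMParameters:
    """Apply the canonical state ordering to every parameter block."""
    if perm is None:
        perm = _canonical_order(params)
    em = params.emission
    beta = params.transition.beta[np.ix_(perm, perm)]
    return HMMParameters(
        EmissionParams(
            em.mu[perm], em.sigma[perm], em.angle_mean[perm], em.angle_kappa[perm]
        ),
        TransitionCoefficients(beta.copy()),
        params.initial_rule,
    )


def _hessian_covariance(w, fun_grad, step=1e-5):
    """Inverse observed information via central differences of the gradient."""
    k = w.size
    H = np.empty((k, k))
    for j in range(k):
        h = step * max(1.0, abs(w[j]))
        wp = w.copy()
        wp[j] += h
        _, gp = fun_grad(wp)
        wm = w.copy()
        wm[j] -= h
        _, gm = fun_grad(wm)
        H[:, j] = (gp - gm) / (2 * h)
    H = 0.5 * (H + H.T)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    return cov


def count_parameters_dims(n_states: int, p: int) -> int:
    """Free parameters: emission block + transition block (initial rule adds 0)."""
    return n_states * (2 * N_GAMMA + 2) + n_states * (n_states - 1) * (1 + p)


def fit(
    spec: ModelSpec,
    batches,
    restarts: int = 20,
    seed: int | None = None,
    initial_rule: str = "stationary",
    compute_cov: bool = True,
    maxiter: int = 1000,
    jitter: float = 0.1,
) -> FittedModel:
    """Maximum-likelihood fit by quasi-Newton optimization on the working scale.

    Runs ``restarts`` optimizations from jittered quantile-split starting
    values and keeps the best; states are then relabelled canonically
    (ascending step-length mean) and the working-scale covariance is taken
    as the inverse observed information at the optimum.
    """
    design_cols = spec.covariate_spec.design_columns
    packed = _as_packed(batches, design_cols)
    N, p = spec.n_states, spec.n_design
    k = count_parameters_dims(N, p)
    n_batches = packed.n_batches
    if n_batches == 0:
        raise ValueError("no observed batches")
    if n_batches < 10 * k:
        warnings.warn(
            f"only {n_batches} batches for {k} parameters; estimates may be unstable",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    obj = lambda w: _nll_and_grad(w, packed, N, p, initial_rule)  # noqa: E731

    best = None
    summary = []
    for r in range(restarts):
        w0 = _starting_values(spec, packed, rng, jitter=0.0 if r == 0 else jitter)
        try:
            res = optimize.minimize(
                obj,
                w0,
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": maxiter, "ftol": 1e-10, "gtol": 1e-6},
            )
        except (ValueError, np.linalg.LinAlgError) as exc:
            summary.append({"restart": r, "error": str(exc)})
            continue
        summary.append(
            {
                "restart": r,
                "loglik": -float(res.fun),
                "converged": bool(res.success),
                "n_iter": int(res.nit),
                "message": str(res.message),
            }
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError(f"all restarts failed: {summary}")

    params = natural_from_working(best.x, N, p, initial_rule)
    params = relabel_states(params)
    w_hat = working_from_natural(params)
    cov = _hessian_covariance(w_hat, obj) if compute_cov else None
    return FittedModel(
        params=params,
        spec=spec,
        loglik=-float(best.fun),
        k=k,
        n_batches=n_batches,
        converged=bool(best.success),
        working=w_hat,
        cov=cov,
        restarts_summary=summary,
    )
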