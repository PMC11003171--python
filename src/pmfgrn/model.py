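"""Generative model and mean-field variational family.

The observation model factorizes single-cell expression as

    W_n ~ Normal(d_n * U_n V^T, sigma_obs^2),   V = A . B  (elementwise),

with per-cell TF activity U (positive, lognormal prior), interaction
probabilities A in (0,1) (logistic-normal prior centered at the clipped,
logit-transformed prior-knowledge matrix), signed interaction strengths B
(normal prior), per-cell depth d in (0,1) (logistic-normal prior, variance 9
on the logit scale) and a single observation noise scale sigma_obs
(standard-normal prior on the log scale).

The variational family mirrors the priors factor-by-factor: a Normal on each
unconstrained coordinate (log U, logit d, logit A, B, log sigma_obs).  All
log-densities returned here are densities over the *constrained* variables:
change-of-variable Jacobians are included in both the prior and the
variational density, so the two are directly comparable and the Jacobians
cancel exactly inside ELBO-style differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit as _logit

from .config import HyperparameterConfig
from .containers import ExpressionMatrix, PriorNetwork

LOG_2PI = float(np.log(2.0 * np.pi))

# clamps keeping the logit/exp transforms numerically safe
MEAN_CLAMP = 15.0
SCALE_MIN = 1e-4
SCALE_MAX = 10.0


# ---------------------------------------------------------------------------
# prior construction
# ---------------------------------------------------------------------------

def clip_prior(value, a_min: float, a_max: float):
    """Clip prior-knowledge entries into [a_min, a_max] before the logit.

    ``clip(x) = max(min(x, a_max), a_min)``; binary prior entries become
    a_max (edge present) or a_min (edge absent), so the prior never places a
    point mass at 0 or 1.
    """
    if not (0.0 < a_min < a_max < 1.0):
        raise ValueError("require 0 < a_min < a_max < 1")
    return np.maximum(np.minimum(value, a_max), a_min)


def build_prior_logit_means(prior: PriorNetwork, a_min: float, a_max: float) -> np.ndarray:
    """Logit-scale prior means for A from a binary prior-knowledge matrix.

    Antisymmetric in the prior: with the default clip [0.005, 0.995] an edge
    maps to logit(0.995) ~ +5.29 and a non-edge to -5.29.
    """
    entries = np.asarray(prior.entries, dtype=float)
    if not np.isin(entries, (0.0, 1.0)).all():
        raise ValueError("prior-knowledge matrix must be binary")
    return _logit(clip_prior(entries, a_min, a_max))


def interaction_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Effective regulatory coefficients V = A . B (elementwise product)."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: A {A.shape} vs B {B.shape}")
    return A * B


# ---------------------------------------------------------------------------
# latent sample and variational state
# ---------------------------------------------------------------------------

@dataclass
class LatentSample:
    """One draw of all latent variables, on their constrained scales."""

    U: np.ndarray          # N x K, positive
    A: np.ndarray          # M x K, in (0,1)
    B: np.ndarray          # M x K, real
    d: np.ndarray          # N, in (0,1)
    sigma_obs: float       # positive scalar

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        self.sigma_obs = float(self.sigma_obs)
        if (self.U <= 0).any():
            raise ValueError("U must be strictly positive")
        if ((self.A <= 0) | (self.A >= 1)).any():
            raise ValueError("A must lie strictly inside (0, 1)")
        if ((self.d <= 0) | (self.d >= 1)).any():
            raise ValueError("d must lie strictly inside (0, 1)")
        if self.sigma_obs <= 0:
            raise ValueError("sigma_obs must be positive")


def _check_pos(x: np.ndarray, what: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if (x <= 0).any():
        raise ValueError(f"{what} must be strictly positive")
    return x


@dataclass
class VariationalState:
    """Mean-field variational parameters for (U, d, A, B, sigma_obs).

    Means live on the unconstrained scale (log U, logit d, logit A, B,
    log sigma_obs); scales are the standard deviations of the corresponding
    Normal factors and must be strictly positive.
    """

    U_mean: np.ndarray
    U_scale: np.ndarray
    d_mean: np.ndarray
    d_scale: np.ndarray
    A_mean: np.ndarray
    A_scale: np.ndarray
    B_mean: np.ndarray
    B_scale: np.ndarray
    o_mean: float
    o_scale: float

    def __post_init__(self) -> None:
        self.U_mean = np.asarray(self.U_mean, dtype=float)
        self.d_mean = np.asarray(self.d_mean, dtype=float)
        self.A_mean = np.asarray(self.A_mean, dtype=float)
        self.B_mean = np.asarray(self.B_mean, dtype=float)
        self.U_scale = _check_pos(self.U_scale, "U_scale")
        self.d_scale = _check_pos(self.d_scale, "d_scale")
        self.A_scale = _check_pos(self.A_scale, "A_scale")
        self.B_scale = _check_pos(self.B_scale, "B_scale")
        self.o_mean = float(self.o_mean)
        self.o_scale = float(self.o_scale)
        if self.o_scale <= 0:
            raise ValueError("o_scale must be strictly positive")
        n, k = self.U_mean.shape
        m, k2 = self.A_mean.shape
        if k2 != k:
            raise ValueError("U and A disagree on the number of TFs")
        for name, arr, shape in (
            ("U_scale", self.U_scale, (n, k)),
            ("d_mean", self.d_mean, (n,)),
            ("d_scale", self.d_scale, (n,)),
            ("A_scale", self.A_scale, (m, k)),
            ("B_mean", self.B_mean, (m, k)),
            ("B_scale", self.B_scale, (m, k)),
        ):
            if arr.shape != shape:
                raise ValueError(f"{name}: expected shape {shape}, got {arr.shape}")

    @property
    def shape(self) -> tuple[int, int, int]:
        """(N cells, M genes, K TFs)."""
        return (self.U_mean.shape[0], self.A_mean.shape[0], self.U_mean.shape[1])

    def copy(self) -> "VariationalState":
        return VariationalState(
            self.U_mean.copy(), self.U_scale.copy(),
            self.d_mean.copy(), self.d_scale.copy(),
            self.A_mean.copy(), self.A_scale.copy(),
            self.B_mean.copy(), self.B_scale.copy(),
            self.o_mean, self.o_scale,
        )


def init_state(n_cells: int, prior_logits: np.ndarray,
               config: HyperparameterConfig) -> VariationalState:
    """Initialize the variational posterior at the prior.

    q starts identical to p, so the initial KL term of the ELBO is zero and
    early optimization pressure comes from the likelihood alone.
    """
    prior_logits = np.asarray(prior_logits, dtype=float)
    m, k = prior_logits.shape
    return VariationalState(
        U_mean=np.full((n_cells, k), config.mu_u),
        U_scale=np.full((n_cells, k), config.sigma_u),
        d_mean=np.zeros(n_cells),
        d_scale=np.full(n_cells, np.sqrt(config.d_prior_var)),
        A_mean=prior_logits.copy(),
        A_scale=np.full((m, k), config.sigma_a),
        B_mean=np.zeros((m, k)),
        B_scale=np.full((m, k), config.sigma_b),
        o_mean=config.sigma_obs_prior_mean,
        o_scale=float(np.sqrt(config.sigma_obs_prior_var)),
    )


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def draw_unconstrained(state: VariationalState, rng: np.random.Generator):
    """Draw standard-normal innovations and the unconstrained coordinates.

    Draw order is fixed (U, d, A, B, o) so that seeded runs are reproducible.
    Returns (eps, raw) dicts keyed by block name.
    """
    eps = {
        "U": rng.standard_normal(state.U_mean.shape),
        "d": rng.standard_normal(state.d_mean.shape),
        "A": rng.standard_normal(state.A_mean.shape),
        "B": rng.standard_normal(state.B_mean.shape),
        "o": float(rng.standard_normal()),
    }
    raw = {
        "U": state.U_mean + state.U_scale * eps["U"],
        "d": state.d_mean + state.d_scale * eps["d"],
        "A": state.A_mean + state.A_scale * eps["A"],
        "B": state.B_mean + state.B_scale * eps["B"],
        "o": state.o_mean + state.o_scale * eps["o"],
    }
    return eps, raw


def constrain(raw: dict) -> LatentSample:
    """Map unconstrained coordinates to the model's support."""
    return LatentSample(
        U=np.exp(raw["U"]),
        A=expit(raw["A"]),
        B=raw["B"],
        d=expit(raw["d"]),
        sigma_obs=float(np.exp(raw["o"])),
    )


def variational_sample(state: VariationalState, seed: int) -> LatentSample:
    """Reparameterized draw from the variational posterior."""
    rng = np.random.default_rng(seed)
    _, raw = draw_unconstrained(state, rng)
    return constrain(raw)


# ---------------------------------------------------------------------------
# log-densities
# ---------------------------------------------------------------------------

def _normal_logpdf(x, mean, scale):
    x = np.asarray(x, dtype=float)
    z = (x - mean) / scale
    return -0.5 * (z * z) - np.log(scale) - 0.5 * LOG_2PI


def likelihood_logpdf(W, sample: LatentSample) -> float:
    """Gaussian observation log-likelihood, summed over all cells and genes.

    The mean of cell n is d_n * U_n V^T with V = A . B; a single sigma_obs is
    shared by every entry.
    """
    values = W.values if isinstance(W, ExpressionMatrix) else np.asarray(W, dtype=float)
    if np.isnan(values).any():
        raise ValueError("expression matrix contains NaN entries")
    V = interaction_matrix(sample.A, sample.B)
    mean = sample.d[:, None] * (sample.U @ V.T)
    if mean.shape != values.shape:
        raise ValueError(f"shape mismatch: W {values.shape} vs model mean {mean.shape}")
    return float(_normal_logpdf(values, mean, sample.sigma_obs).sum())


def _lognormal_term(U, mu, sigma):
    logU = np.log(U)
    return _normal_logpdf(logU, mu, sigma) - logU


def _logisticnormal_term(x, mu, sigma):
    return _normal_logpdf(_logit(x), mu, sigma) - np.log(x) - np.log1p(-x)


def prior_logpdf(sample: LatentSample, prior_logits: np.ndarray,
                 config: HyperparameterConfig) -> float:
    """Joint prior log-density of one latent sample (constrained scale).

    Sum of: lognormal over U, logistic-normal over d (variance 9 on the
    logit scale), logistic-normal over A centered at the clipped prior
    logits, Normal over B, and lognormal-type prior over sigma_obs (standard
    normal on log sigma_obs).  All change-of-variable Jacobians included.
    """
    prior_logits = np.asarray(prior_logits, dtype=float)
    if prior_logits.shape != sample.A.shape:
        raise ValueError("prior_logits shape does not match A")
    total = _lognormal_term(sample.U, config.mu_u, config.sigma_u).sum()
    total += _logisticnormal_term(sample.d, 0.0, np.sqrt(config.d_prior_var)).sum()
    total += _logisticnormal_term(sample.A, prior_logits, config.sigma_a).sum()
    total += _normal_logpdf(sample.B, 0.0, config.sigma_b).sum()
    log_o = np.log(sample.sigma_obs)
    total += float(
        _normal_logpdf(log_o, config.sigma_obs_prior_mean,
                       np.sqrt(config.sigma_obs_prior_var)) - log_o
    )
    return float(total)


def variational_logpdf(sample: LatentSample, state: VariationalState) -> float:
    """Variational log-density of a sample, on the constrained scale.

    Directly comparable with :func:`prior_logpdf`: both include the same
    Jacobian corrections, so their difference equals the corresponding
    difference of Normal densities in the unconstrained space.
    """
    total = _lognormal_term(sample.U, state.U_mean, state.U_scale).sum()
    total += _logisticnormal_term(sample.d, state.d_mean, state.d_scale).sum()
    total += _logisticnormal_term(sample.A, state.A_mean, state.A_scale).sum()
    total += _normal_logpdf(sample.B, state.B_mean, state.B_scale).sum()
    log_o = np.log(sample.sigma_obs)
    total += float(_normal_logpdf(log_o, state.o_mean, state.o_scale) - log_o)
    return float(total)
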