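"""Stochastic variational inference for the matrix-factorization model.

The variational parameters are optimized by stochastic gradient ascent on a
beta-weighted ELBO,

    E_q[ log p(W | U, V = A.B, sigma_obs, d)
         + beta * (log p(U, A, B, sigma_obs, d) - log q(...)) ],

estimated by reparameterized Monte Carlo.  Because every prior and every
variational factor is a Normal on the unconstrained coordinate (log U,
logit d, logit A, B, log sigma_obs), the gradient of each term with respect
to the variational means and scales is available in closed form, and the
whole gradient is computed analytically here (no autodiff dependency).

Cell minibatching follows the usual SVI recipe: the likelihood term and the
prior/entropy terms of the batch's local latents (rows of U, entries of d)
are scaled by N / batch_size, while global terms (A, B, sigma_obs) enter
unscaled, which keeps the minibatch objective an unbiased estimate of the
full ELBO.  A minibatch step updates the batch's local variational
parameters plus all global parameters.

Optimization uses Adam (learning rate 0.1, betas 0.9/0.99) with the global
gradient norm clipped at 1e-4 before the update.  Early stopping tracks
either a validation AUPRC callback or an importance-weighted estimate of
the marginal log-likelihood; the best-scoring checkpoint is restored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit as _logit
from scipy.special import logsumexp

from .config import HyperparameterConfig
from .containers import ExpressionMatrix, PriorNetwork
from .model import (
    LOG_2PI,
    MEAN_CLAMP,
    SCALE_MAX,
    SCALE_MIN,
    LatentSample,
    VariationalState,
    build_prior_logit_means,
    constrain,
    draw_unconstrained,
    init_state,
)

_BLOCKS = ("U", "d", "A", "B", "o")
_LOCAL = ("U", "d")


# ---------------------------------------------------------------------------
# trace bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class TraceStep:
    step: int
    elbo: float
    metric: float | None = None


@dataclass
class TrainingTrace:
    steps: list = field(default_factory=list)
    stopped_at: int = 0
    stop_reason: str = "max_steps"
    best_step: int = 0
    best_metric: float | None = None


# ---------------------------------------------------------------------------
# ELBO value (shared by the public estimators and the optimizer)
# ---------------------------------------------------------------------------

def _state_means_scales(state: VariationalState):
    means = {"U": state.U_mean, "d": state.d_mean, "A": state.A_mean,
             "B": state.B_mean, "o": state.o_mean}
    scales = {"U": state.U_scale, "d": state.d_scale, "A": state.A_scale,
              "B": state.B_scale, "o": state.o_scale}
    return means, scales


def _prior_means_scales(prior_logits: np.ndarray, config: HyperparameterConfig):
    pm = {"U": config.mu_u, "d": 0.0, "A": prior_logits, "B": 0.0,
          "o": config.sigma_obs_prior_mean}
    ps = {"U": config.sigma_u, "d": float(np.sqrt(config.d_prior_var)),
          "A": config.sigma_a, "B": config.sigma_b,
          "o": float(np.sqrt(config.sigma_obs_prior_var))}
    return pm, ps


def _elbo_value(values: np.ndarray, raw: dict, state: VariationalState,
                prior_logits: np.ndarray, config: HyperparameterConfig,
                idx: np.ndarray, beta: float) -> float:
    """beta-weighted ELBO integrand at unconstrained coordinates ``raw``.

    ``idx`` selects the cell minibatch; likelihood and local prior/entropy
    terms are scaled by N/len(idx).
    """
    n_total = values.shape[0]
    c = n_total / idx.size

    means, scales = _state_means_scales(state)
    pm, ps = _prior_means_scales(prior_logits, config)

    U = np.exp(raw["U"][idx])
    d = expit(raw["d"][idx])
    A = expit(raw["A"])
    V = A * raw["B"]
    sigma_obs = float(np.exp(raw["o"]))

    mean = d[:, None] * (U @ V.T)
    resid = values[idx] - mean
    loglik = float(
        -0.5 * np.sum(resid * resid) / sigma_obs**2
        - resid.size * (np.log(sigma_obs) + 0.5 * LOG_2PI)
    )

    def _block_kl_term(name: str, z) -> float:
        """log p(z) - log q(z) for one block, Normal vs Normal in raw space."""
        # prior means are scalars except for A (the prior-logit matrix)
        zp = (np.asarray(z) - pm[name]) / ps[name]
        logp = float(np.sum(-0.5 * zp * zp - np.log(ps[name]) - 0.5 * LOG_2PI))
        mu_q = means[name][idx] if name in _LOCAL else means[name]
        sd_q = scales[name][idx] if name in _LOCAL else scales[name]
        zq = (np.asarray(z) - mu_q) / sd_q
        logq = float(np.sum(-0.5 * zq * zq - np.log(sd_q) - 0.5 * LOG_2PI))
        return logp - logq

    local = _block_kl_term("U", raw["U"][idx]) + _block_kl_term("d", raw["d"][idx])
    global_ = (_block_kl_term("A", raw["A"]) + _block_kl_term("B", raw["B"])
               + _block_kl_term("o", raw["o"]))
    return loglik * c + beta * (c * local + global_)


def _resolve_indices(n_cells: int, cell_indices) -> np.ndarray:
    if cell_indices is None:
        return np.arange(n_cells)
    idx = np.asarray(cell_indices, dtype=int)
    if idx.size == 0:
        raise ValueError("cell_indices must be non-empty")
    if idx.min() < 0 or idx.max() >= n_cells:
        raise ValueError("cell_indices out of range")
    return idx


def elbo_at_sample(W, sample: LatentSample, state: VariationalState,
                   prior_logits: np.ndarray, config: HyperparameterConfig,
                   cell_indices=None, beta: float | None = None) -> float:
    """Batch-scaled ELBO integrand evaluated at a fixed latent sample.

    Averaging this over a disjoint partition of the cells into equal batches
    reproduces the full-batch value exactly (minibatch unbiasedness).
    """
    values = W.values if isinstance(W, ExpressionMatrix) else np.asarray(W, dtype=float)
    idx = _resolve_indices(values.shape[0], cell_indices)
    raw = {
        "U": np.log(sample.U),
        "d": _logit(sample.d),
        "A": _logit(sample.A),
        "B": np.asarray(sample.B, dtype=float),
        "o": float(np.log(sample.sigma_obs)),
    }
    b = config.beta if beta is None else beta
    return _elbo_value(values, raw, state, np.asarray(prior_logits, dtype=float),
                       config, idx, b)


def elbo_estimate(W, state: VariationalState, config: HyperparameterConfig,
                  prior_logits: np.ndarray, cell_indices=None,
                  n_samples: int = 1, seed: int = 0,
                  beta: float | None = None) -> float:
    """Monte-Carlo estimate of the beta-weighted ELBO.

    With ``cell_indices`` covering all cells this is the full estimate;
    otherwise the likelihood and local terms are scaled by N/batch size.
    """
    values = W.values if isinstance(W, ExpressionMatrix) else np.asarray(W, dtype=float)
    idx = _resolve_indices(values.shape[0], cell_indices)
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    prior_logits = np.asarray(prior_logits, dtype=float)
    b = config.beta if beta is None else beta
    total = 0.0
    for _ in range(n_samples):
        _, raw = draw_unconstrained(state, rng)
        total += _elbo_value(values, raw, state, prior_logits, config, idx, b)
    return total / n_samples


def iw_log_marginal(W, state: VariationalState, config: HyperparameterConfig,
                    prior_logits: np.ndarray, S: int, seed: int) -> float:
    """Importance-weighted estimate of log p(W).

    log( (1/S) sum_s exp(log p(W, z_s) - log q(z_s)) ), with the unweighted
    (beta = 1) joint and the log-sum-exp trick for stability.  At S = 1 this
    coincides exactly with the one-sample beta=1 ELBO estimate drawn from
    the same seed.
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    values = W.values if isinstance(W, ExpressionMatrix) else np.asarray(W, dtype=float)
    idx = np.arange(values.shape[0])
    rng = np.random.default_rng(seed)
    prior_logits = np.asarray(prior_logits, dtype=float)
    log_w = np.empty(S)
    for s in range(S):
        _, raw = draw_unconstrained(state, rng)
        log_w[s] = _elbo_value(values, raw, state, prior_logits, config, idx, 1.0)
    return float(logsumexp(log_w) - np.log(S))


# ---------------------------------------------------------------------------
# analytic gradients
# ---------------------------------------------------------------------------

def _value_and_grads(values: np.ndarray, params: dict, prior_logits: np.ndarray,
                     config: HyperparameterConfig, idx: np.ndarray,
                     rng: np.random.Generator):
    """One reparameterized draw: ELBO value and gradients w.r.t. means/scales.

    ``params`` holds means and *scales* (not rho); the softplus chain rule is
    applied by the caller.  Gradients of local blocks are returned on the
    batch rows only (full-shape arrays, zero outside the batch).
    """
    n_total = values.shape[0]
    c = n_total / idx.size
    beta = config.beta
    pm, ps = _prior_means_scales(prior_logits, config)

    # full-size draws keep the sample stream independent of batch composition
    eps = {
        "U": rng.standard_normal(params["U_mean"].shape),
        "d": rng.standard_normal(params["d_mean"].shape),
        "A": rng.standard_normal(params["A_mean"].shape),
        "B": rng.standard_normal(params["B_mean"].shape),
        "o": float(rng.standard_normal()),
    }
    raw = {k: params[f"{k}_mean"] + params[f"{k}_scale"] * eps[k] for k in _BLOCKS}

    Ub = np.exp(raw["U"][idx])
    db = expit(raw["d"][idx])
    A = expit(raw["A"])
    B = raw["B"]
    V = A * B
    sigma_obs = float(np.exp(raw["o"]))

    UVt = Ub @ V.T
    mean = db[:, None] * UVt
    resid = values[idx] - mean
    s2 = sigma_obs * sigma_obs
    loglik = float(-0.5 * np.sum(resid * resid) / s2
                   - resid.size * (np.log(sigma_obs) + 0.5 * LOG_2PI))

    G = (c / s2) * resid                       # dL/d(mean), batch x M
    dU_scaled = db[:, None] * Ub               # batch x K
    GV = G @ V                                 # batch x K
    GtdU = G.T @ dU_scaled                     # M x K

    dL = {
        "U": GV * dU_scaled,                   # batch rows
        "d": (G * UVt).sum(axis=1) * db * (1.0 - db),
        "A": GtdU * B * A * (1.0 - A),
        "B": GtdU * A,
        "o": float(c * (-resid.size + np.sum(resid * resid) / s2)),
    }

    value = loglik * c
    grads = {}
    for name in _BLOCKS:
        local = name in _LOCAL
        w = c if local else 1.0
        z = raw[name][idx] if local else raw[name]
        e = eps[name][idx] if local else eps[name]
        mu_q = params[f"{name}_mean"][idx] if local else params[f"{name}_mean"]
        sd_q = params[f"{name}_scale"][idx] if local else params[f"{name}_scale"]
        zp = (z - pm[name]) / ps[name]
        logp = float(np.sum(-0.5 * zp * zp - np.log(ps[name]) - 0.5 * LOG_2PI))
        logq = float(np.sum(-0.5 * e * e - np.log(sd_q) - 0.5 * LOG_2PI))
        value += beta * w * (logp - logq)

        dprior_dz = -beta * w * (z - pm[name]) / (ps[name] ** 2)
        g_core = dL[name] + dprior_dz          # d(value)/dz
        g_mean = g_core
        g_scale = g_core * e + beta * w / sd_q  # + entropy term d(-logq)/dscale

        if local:
            gm = np.zeros_like(params[f"{name}_mean"])
            gs = np.zeros_like(params[f"{name}_scale"])
            gm[idx] = g_mean
            gs[idx] = g_scale
            grads[f"{name}_mean"] = gm
            grads[f"{name}_scale"] = gs
        else:
            grads[f"{name}_mean"] = np.asarray(g_mean, dtype=float)
            grads[f"{name}_scale"] = np.asarray(g_scale, dtype=float)
    return value, grads


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

def _softplus(x):
    return np.logaddexp(0.0, x)


def _softplus_inv(y):
    y = np.asarray(y, dtype=float)
    return y + np.log(-np.expm1(-y))


_RHO_MIN = float(_softplus_inv(SCALE_MIN))
_RHO_MAX = float(_softplus_inv(SCALE_MAX))


class _Adam:
    """Adam ascent with per-row step counts for local parameter blocks."""

    def __init__(self, shapes: dict, lr: float, b1: float, b2: float,
                 eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}
        # per-cell step counters for local blocks, scalar for globals
        self.t_local = None
        self.t_global = 0

    def step(self, params: dict, grads: dict, idx: np.ndarray, n_cells: int):
        if self.t_local is None:
            self.t_local = np.zeros(n_cells, dtype=int)
        self.t_global += 1
        self.t_local[idx] += 1
        for key, g in grads.items():
            local = key.split("_")[0] in _LOCAL
            m, v = self.m[key], self.v[key]
            if local:
                gi = g[idx]
                m[idx] = self.b1 * m[idx] + (1 - self.b1) * gi
                v[idx] = self.b2 * v[idx] + (1 - self.b2) * gi * gi
                t = self.t_local[idx]
                bc1 = 1.0 - self.b1 ** t
                bc2 = 1.0 - self.b2 ** t
                if m.ndim == 2:
                    bc1 = bc1[:, None]
                    bc2 = bc2[:, None]
                update = self.lr * (m[idx] / bc1) / (np.sqrt(v[idx] / bc2) + self.eps)
                params[key] = params[key].copy()
                params[key][idx] += update
            else:
                self.m[key] = self.b1 * m + (1 - self.b1) * g
                self.v[key] = self.b2 * v + (1 - self.b2) * g * g
                bc1 = 1.0 - self.b1 ** self.t_global
                bc2 = 1.0 - self.b2 ** self.t_global
                update = self.lr * (self.m[key] / bc1) / (np.sqrt(self.v[key] / bc2) + self.eps)
                params[key] = params[key] + update


def _clip_global_norm(grads: dict, idx: np.ndarray, max_norm: float) -> float:
    """Scale all gradients so the global L2 norm is at most ``max_norm``."""
    sq = 0.0
    for key, g in grads.items():
        if key.split("_")[0] in _LOCAL:
            sq += float(np.sum(g[idx] ** 2))
        else:
            sq += float(np.sum(np.asarray(g) ** 2))
    norm = np.sqrt(sq)
    if norm > max_norm and norm > 0:
        scale = max_norm / norm
        for key in grads:
            grads[key] = grads[key] * scale
    return min(norm, max_norm)


def _params_from_state(state: VariationalState) -> dict:
    return {
        "U_mean": state.U_mean.copy(), "U_scale": state.U_scale.copy(),
        "d_mean": state.d_mean.copy(), "d_scale": state.d_scale.copy(),
        "A_mean": state.A_mean.copy(), "A_scale": state.A_scale.copy(),
        "B_mean": state.B_mean.copy(), "B_scale": state.B_scale.copy(),
        "o_mean": np.float64(state.o_mean), "o_scale": np.float64(state.o_scale),
    }


def _state_from_params(params: dict) -> VariationalState:
    return VariationalState(
        params["U_mean"], params["U_scale"],
        params["d_mean"], params["d_scale"],
        params["A_mean"], params["A_scale"],
        params["B_mean"], params["B_scale"],
        float(params["o_mean"]), float(params["o_scale"]),
    )


def _clamp(params: dict) -> None:
    for key in params:
        kind = key.split("_")[1]
        if kind == "mean":
            params[key] = np.clip(params[key], -MEAN_CLAMP, MEAN_CLAMP)
        else:
            params[key] = np.clip(params[key], SCALE_MIN, SCALE_MAX)


def align_to_prior(W: ExpressionMatrix, prior: PriorNetwork):
    """Restrict expression and prior to their shared genes (lexicographic)."""
    shared = sorted(set(W.gene_ids.tolist()) & set(prior.gene_ids.tolist()))
    if not shared:
        raise ValueError("expression matrix and prior share no genes")
    return W.subset_genes(shared), prior.subset_genes(shared)


def fit(W: ExpressionMatrix, prior: PriorNetwork, config: HyperparameterConfig,
        stopping_metric: str = "iw_log_marginal", metric_callback=None,
        instrument_grad_norm: bool = False):
    """Fit the variational posterior by minibatch gradient ascent on the ELBO.

    ``stopping_metric`` selects the early-stopping criterion evaluated every
    ``config.eval_interval`` steps: ``"iw_log_marginal"`` (computed on the
    training data with ``config.iw_samples`` importance samples) or
    ``"validation_auprc"``, in which case ``metric_callback(state) -> float``
    must be supplied (typically a held-out-prior AUPRC).  The state achieving
    the best metric is restored on return; ties keep the earliest checkpoint.

    Returns ``(VariationalState, TrainingTrace)``.  Fully deterministic given
    ``config.seed``.
    """
    if stopping_metric not in ("iw_log_marginal", "validation_auprc"):
        raise ValueError(f"unknown stopping metric: {stopping_metric!r}")
    if stopping_metric == "validation_auprc" and metric_callback is None:
        raise ValueError("validation_auprc stopping requires a metric_callback")

    W_al, prior_al = align_to_prior(W, prior)
    values = W_al.values
    n_cells = values.shape[0]
    prior_logits = build_prior_logit_means(prior_al, config.a_min, config.a_max)

    state0 = init_state(n_cells, prior_logits, config)
    trace = TrainingTrace()
    if config.max_steps == 0:
        return state0, trace

    params = _params_from_state(state0)
    # scales are optimized through a softplus reparameterization
    rho = {k: _softplus_inv(v) if k.endswith("scale") else None for k, v in params.items()}

    shapes = {k: np.shape(v) for k, v in params.items()}
    opt = _Adam(shapes, config.learning_rate, config.adam_beta1, config.adam_beta2)

    rng = np.random.default_rng(config.seed)
    batch_size = min(config.batch_size, n_cells)

    best = None  # (metric, step, params snapshot)
    evals_since_best = 0
    perm = rng.permutation(n_cells)
    cursor = 0
    stop_reason = "max_steps"
    stopped_at = config.max_steps
    grad_norms = [] if instrument_grad_norm else None

    for step in range(1, config.max_steps + 1):
        if batch_size == n_cells:
            idx = np.arange(n_cells)
        else:
            if cursor + batch_size > n_cells:
                perm = rng.permutation(n_cells)
                cursor = 0
            idx = perm[cursor:cursor + batch_size]
            cursor += batch_size

        value = 0.0
        agg = None
        for _ in range(config.elbo_mc_samples):
            v, g = _value_and_grads(values, params, prior_logits, config, idx, rng)
            value += v
            if agg is None:
                agg = g
            else:
                for k in agg:
                    agg[k] = agg[k] + g[k]
        value /= config.elbo_mc_samples
        for k in agg:
            agg[k] = agg[k] / config.elbo_mc_samples

        # chain rule through sigma = softplus(rho)
        grads = {}
        for key, g in agg.items():
            if key.endswith("scale"):
                grads[key] = g * expit(rho[key])
            else:
                grads[key] = g

        norm = _clip_global_norm(grads, idx, config.grad_clip_norm)
        if grad_norms is not None:
            grad_norms.append(norm)

        # step in (mean, rho) coordinates, then refresh scales
        step_params = {k: (params[k] if k.endswith("mean") else rho[k]) for k in params}
        opt.step(step_params, grads, idx, n_cells)
        for key in params:
            if key.endswith("mean"):
                params[key] = np.clip(step_params[key], -MEAN_CLAMP, MEAN_CLAMP)
            else:
                rho[key] = np.clip(step_params[key], _RHO_MIN, _RHO_MAX)
                params[key] = _softplus(rho[key])

        if step % config.eval_interval == 0 or step == config.max_steps:
            cur_state = _state_from_params(params)
            if stopping_metric == "validation_auprc":
                metric = float(metric_callback(cur_state))
            else:
                eval_seed = int((config.seed * 1_000_003 + step) % (2**31 - 1))
                metric = iw_log_marginal(values, cur_state, config, prior_logits,
                                         S=config.iw_samples, seed=eval_seed)
            trace.steps.append(TraceStep(step=step, elbo=float(value), metric=metric))
            if best is None or metric > best[0]:
                best = (metric, step, {k: np.copy(v) for k, v in params.items()})
                evals_since_best = 0
            else:
                evals_since_best += 1
                if evals_since_best >= config.patience:
                    stop_reason = "patience_exhausted"
                    stopped_at = step
                    break
    else:
        stopped_at = config.max_steps

    trace.stopped_at = stopped_at
    trace.stop_reason = stop_reason
    if best is not None:
        trace.best_step = best[1]
        trace.best_metric = best[0]
        params = best[2]
    final = _state_from_params(params)
    if grad_norms is not None:
        trace.grad_norms = grad_norms  # type: ignore[attr-defined]
    return final, trace
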