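"""Self-consistent synthetic fixtures drawn from the model's own generative
process.

A simulated dataset consists of a ground-truth binary network ``true_A``
with a prescribed edge density, signed strengths B ~ Normal(0, sigma_b^2),
per-cell TF activities U ~ lognormal(mu_u, sigma_u^2), per-cell depths with
logit(d) ~ Normal(0, depth_logit_sd^2), and observations

    W = Normal(d * U (A.B)^T, sigma_obs_true^2),  floored at 0, rounded,

so fixtures look like raw UMI count matrices while remaining exactly
consistent with the Gaussian observation model (the rounding is data realism
only).  A corrupted prior — true edges dropped at ``prior_fn_rate``, false
edges added at ``prior_fp_rate`` — stands in for the imperfect database or
chromatin-accessibility priors real analyses start from.

The generator emulates the factorized, static expression model; it does not
emulate dynamical trajectories, batch effects or zero inflation, so passing
recovery tests demonstrates correctness of the inference machinery rather
than performance on real single-cell data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .containers import ExpressionMatrix, PriorNetwork
from .evaluation import split_reference


@dataclass(frozen=True)
class SimulationConfig:
    n_cells: int = 500
    n_genes: int = 200
    n_tfs: int = 8
    edge_density: float = 0.05
    sigma_b: float = 1.0
    mu_u: float = 1.0          # log-TFA location; keeps expression O(1-100)
    sigma_u: float = 1.0
    sigma_obs_true: float = 0.5
    depth_logit_sd: float = 1.0
    prior_fp_rate: float = 0.005
    prior_fn_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cells, self.n_genes, self.n_tfs) < 1:
            raise ValueError("dimensions must be >= 1")
        if not (0.0 < self.edge_density < 1.0):
            raise ValueError("edge_density must lie in (0, 1)")
        for name in ("prior_fp_rate", "prior_fn_rate"):
            if not (0.0 <= getattr(self, name) < 1.0):
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.sigma_obs_true <= 0:
            raise ValueError("sigma_obs_true must be positive")
        if self.depth_logit_sd < 0:
            raise ValueError("depth_logit_sd must be non-negative")


@dataclass
class SyntheticDataset:
    W: ExpressionMatrix
    true_A: PriorNetwork
    true_B: np.ndarray
    true_U: np.ndarray
    true_d: np.ndarray
    prior: PriorNetwork       # corrupted prior handed to inference
    config: SimulationConfig = field(repr=False)


def _labels(prefix: str, n: int) -> np.ndarray:
    width = len(str(n - 1)) if n > 1 else 1
    return np.asarray([f"{prefix}{i:0{width}d}" for i in range(n)], dtype=object)


def corrupt_prior(true_A: PriorNetwork, fp_rate: float, fn_rate: float,
                  seed: int) -> PriorNetwork:
    """Imperfect prior: drop positives at fn_rate, add zeros->1 at fp_rate."""
    if not (0.0 <= fp_rate < 1.0 and 0.0 <= fn_rate < 1.0):
        raise ValueError("corruption rates must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    entries = true_A.entries.copy()
    pos = entries == 1
    drop = rng.random(entries.shape) < fn_rate
    add = rng.random(entries.shape) < fp_rate
    entries[pos & drop] = 0.0
    entries[(~pos) & add] = 1.0
    return PriorNetwork(entries, true_A.gene_ids.copy(), true_A.tf_ids.copy())


def simulate(config: SimulationConfig) -> SyntheticDataset:
    """Sample a complete synthetic dataset; fully deterministic given seed."""
    n, m, k = config.n_cells, config.n_genes, config.n_tfs
    n_edges = int(round(config.edge_density * m * k))
    if n_edges < 1:
        raise ValueError("edge_density * n_genes * n_tfs must be >= 1")
    rng = np.random.default_rng(config.seed)

    flat = rng.choice(m * k, size=n_edges, replace=False)
    A = np.zeros(m * k)
    A[flat] = 1.0
    A = A.reshape(m, k)

    B = config.sigma_b * rng.standard_normal((m, k))
    U = np.exp(config.mu_u + config.sigma_u * rng.standard_normal((n, k)))
    d = expit(config.depth_logit_sd * rng.standard_normal(n))

    mean = d[:, None] * (U @ (A * B).T)
    W_raw = mean + config.sigma_obs_true * rng.standard_normal((n, m))
    W = np.round(np.maximum(W_raw, 0.0))

    gene_ids = _labels("g", m)
    tf_ids = _labels("tf", k)
    cell_ids = _labels("c", n)
    true_A = PriorNetwork(A, gene_ids, tf_ids)
    prior = corrupt_prior(true_A, config.prior_fp_rate, config.prior_fn_rate,
                          seed=config.seed + 1)
    return SyntheticDataset(
        W=ExpressionMatrix(W, cell_ids, gene_ids),
        true_A=true_A,
        true_B=B,
        true_U=U,
        true_d=d,
        prior=prior,
        config=config,
    )


def make_beeline_style(config: SimulationConfig, prior_fraction: float = 0.5):
    """Simulate and split the true network into a prior half and an eval half.

    Mirrors benchmark practice where half the reference GRN seeds the prior
    and the other half is withheld as the gold standard.  Returns
    ``(W, prior_part, eval_part)``.
    """
    data = simulate(config)
    prior_part, eval_part = split_reference(
        data.true_A, prior_fraction, seed=config.seed + 2
    )
    return data.W, prior_part, eval_part
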