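"""Hyperparameter selection by prior-holdout validation, and cross-validation.

Matrix factorization is identifiable only up to a permutation of the latent
TF columns; the prior over A anchors column identity.  The selection
workflow exploits this: hold out the prior rows of a random 20% of genes
(set them to the no-information value, i.e. all zeros, whose logit-means
become logit(a_min) — the same low number for every entry), run each
candidate configuration with early stopping on the *validation AUPRC* — the
AUPRC of the posterior means on held-out rows against the full prior — then
refit the winning configuration on the unmodified prior with the
importance-weighted marginal likelihood as the stopping criterion.

The k-fold harness splits a gold standard's positive edges into a prior
portion and an evaluation portion per fold, runs the full selection
workflow inside the fold, and scores the fold's final network with keep-all
AUPRC against the held-out edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import HyperparameterConfig
from .containers import ExpressionMatrix, PriorNetwork
from .evaluation import ScoredNetwork, auprc, split_reference
from .inference import align_to_prior, fit
from .posterior import PosteriorSummary, summarize, summarize_A


@dataclass
class HoldoutSplit:
    modified_prior: PriorNetwork
    held_out_genes: set
    full_prior: PriorNetwork
    seed: int


@dataclass
class SearchRecord:
    config: HyperparameterConfig
    best_validation_auprc: float
    best_step: int


@dataclass
class SearchResult:
    records: list = field(default_factory=list)
    best_config: HyperparameterConfig | None = None
    split: HoldoutSplit | None = None

    @property
    def best_validation_auprc(self) -> float:
        return max(r.best_validation_auprc for r in self.records)


DEFAULT_GRID = tuple(
    HyperparameterConfig(sigma_a=sa, sigma_u=su, beta=b)
    for sa in (0.25, 0.5, 1.0, 2.0)
    for su in (0.25, 1.0)
    for b in (1.0, 2.0, 4.0)
)


def holdout_prior(prior: PriorNetwork, fraction: float, seed: int) -> HoldoutSplit:
    """Zero the prior rows of a random fraction of genes.

    Held-out rows keep their place in the matrix but lose all prior signal
    (their logit means collapse to logit(a_min)); the original rows are kept
    in ``full_prior`` for validation scoring.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    m = prior.n_genes
    n_hold = int(round(fraction * m))
    if n_hold == 0 or n_hold == m:
        raise ValueError(f"fraction {fraction} holds out {n_hold} of {m} genes")
    rng = np.random.default_rng(seed)
    rows = rng.choice(m, size=n_hold, replace=False)
    entries = prior.entries.copy()
    entries[rows, :] = 0.0
    modified = PriorNetwork(entries, prior.gene_ids.copy(), prior.tf_ids.copy())
    held = {prior.gene_ids[i] for i in rows}
    return HoldoutSplit(modified_prior=modified, held_out_genes=held,
                        full_prior=prior.copy(), seed=seed)


def validation_auprc(A_mean: np.ndarray, split: HoldoutSplit,
                     gene_ids=None) -> float:
    """AUPRC of posterior means on held-out rows against the full prior."""
    full = split.full_prior
    if gene_ids is None:
        gene_ids = full.gene_ids
    gene_ids = np.asarray(list(gene_ids), dtype=object)
    if A_mean.shape[0] != len(gene_ids):
        raise ValueError("A_mean rows do not match gene labels")
    held_idx = [i for i, g in enumerate(gene_ids) if g in split.held_out_genes]
    if not held_idx:
        raise ValueError("no held-out genes among the provided rows")
    pred = ScoredNetwork(A_mean[held_idx], gene_ids[held_idx], full.tf_ids)
    gold = full.subset_genes([gene_ids[i] for i in held_idx])
    return auprc(pred, gold, mode="keep_all")


def _validation_callback(split: HoldoutSplit, gene_ids, mc_samples: int, seed: int):
    def callback(state) -> float:
        A_mean, _ = summarize_A(state, S=mc_samples, seed=seed)
        return validation_auprc(A_mean, split, gene_ids=gene_ids)
    return callback


def search(W: ExpressionMatrix, prior: PriorNetwork, grid,
           fraction: float = 0.2, seed: int = 0,
           eval_mc_samples: int = 500) -> SearchResult:
    """Grid search scored by validation AUPRC on one shared holdout split.

    All configurations see the same split for comparability; ties keep the
    earliest configuration in grid order.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    W_al, prior_al = align_to_prior(W, prior)
    split = holdout_prior(prior_al, fraction, seed)
    result = SearchResult(split=split)
    best_idx, best_score = 0, -np.inf
    for i, config in enumerate(grid):
        callback = _validation_callback(
            split, prior_al.gene_ids, eval_mc_samples, seed=config.seed + 17
        )
        _, trace = fit(W_al, split.modified_prior, config,
                       stopping_metric="validation_auprc",
                       metric_callback=callback)
        score = trace.best_metric if trace.best_metric is not None else -np.inf
        result.records.append(SearchRecord(
            config=config, best_validation_auprc=float(score),
            best_step=trace.best_step,
        ))
        if score > best_score:
            best_idx, best_score = i, score
    result.best_config = grid[best_idx]
    return result


def final_fit(W: ExpressionMatrix, prior: PriorNetwork,
              best: HyperparameterConfig,
              summary_seed: int = 0) -> PosteriorSummary:
    """Refit the selected configuration on the full (unmodified) prior.

    Early stopping uses the importance-weighted marginal log-likelihood;
    returns the posterior summary with labels and provenance attached.
    """
    W_al, prior_al = align_to_prior(W, prior)
    state, trace = fit(W_al, prior_al, best, stopping_metric="iw_log_marginal")
    meta = {
        "config": best.to_dict(),
        "seed": best.seed,
        "stopping_step": trace.best_step,
        "stop_reason": trace.stop_reason,
        "stopping_metric": "iw_log_marginal",
        "best_metric": trace.best_metric,
    }
    return summarize(state, prior_al.gene_ids, prior_al.tf_ids, W_al.cell_ids,
                     S=best.summary_mc_samples, seed=summary_seed, meta=meta)


@dataclass
class CVFold:
    fold: int
    auprc: float
    best_config: HyperparameterConfig
    prior_part: PriorNetwork
    eval_part: PriorNetwork


def cross_validate(W: ExpressionMatrix, gold: PriorNetwork, n_folds: int = 5,
                   train_fraction: float = 0.8, grid=None, seed: int = 0,
                   holdout_fraction: float = 0.2,
                   eval_mc_samples: int = 500) -> list:
    """k independent random splits of the gold standard's positive edges.

    Per fold: ``train_fraction`` of the positives form the fold prior, the
    rest the evaluation standard; hyperparameters are selected with an inner
    prior holdout, the final network is refit on the whole fold prior and
    scored with keep-all AUPRC against the evaluation edges.
    """
    if n_folds < 1:
        raise ValueError("n_folds must be >= 1")
    grid = list(grid) if grid is not None else list(DEFAULT_GRID)
    folds = []
    for f in range(n_folds):
        fold_seed = seed + 1000 * f
        prior_part, eval_part = split_reference(gold, train_fraction, seed=fold_seed)
        result = search(W, prior_part, grid, fraction=holdout_fraction,
                        seed=fold_seed + 1, eval_mc_samples=eval_mc_samples)
        summary = final_fit(W, prior_part, result.best_config,
                            summary_seed=fold_seed + 2)
        pred = ScoredNetwork.from_summary(summary)
        score = auprc(pred, eval_part, mode="keep_all")
        folds.append(CVFold(fold=f, auprc=float(score),
                            best_config=result.best_config,
                            prior_part=prior_part, eval_part=eval_part))
    return folds
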