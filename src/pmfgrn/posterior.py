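"""Posterior summaries: edge probabilities, uncertainties and TF activities.

The variational posterior over each interaction A_mk is logistic-normal,
which has no closed-form mean or variance; both are estimated by simple
Monte Carlo.  The posterior mean is read as the probability that TF k
regulates gene m, and the posterior variance as the uncertainty attached to
that point estimate.  TF activity (the posterior over U) is lognormal, so
its mean exp(mu + sigma^2/2) is exact and used directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, ndtri

from .model import VariationalState


@dataclass
class PosteriorSummary:
    """Fitted-model outputs with labels and provenance."""

    A_mean: np.ndarray            # M x K, in (0,1)
    A_var: np.ndarray             # M x K, >= 0
    tfa: np.ndarray               # N x K, > 0
    B_mean: np.ndarray            # M x K
    gene_ids: np.ndarray
    tf_ids: np.ndarray
    cell_ids: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        m, k = self.A_mean.shape
        if self.A_var.shape != (m, k) or self.B_mean.shape != (m, k):
            raise ValueError("A_mean / A_var / B_mean shapes disagree")
        if self.tfa.shape[1] != k:
            raise ValueError("tfa has the wrong number of TF columns")
        if len(self.gene_ids) != m or len(self.tf_ids) != k:
            raise ValueError("label lengths do not match matrix shapes")
        if len(self.cell_ids) != self.tfa.shape[0]:
            raise ValueError("cell label length does not match tfa")
        if ((self.A_mean <= 0) | (self.A_mean >= 1)).any():
            raise ValueError("A_mean must lie in (0, 1)")
        if (self.A_var < 0).any():
            raise ValueError("A_var must be non-negative")


def summarize_A(state: VariationalState, S: int, seed: int):
    """Monte-Carlo posterior mean and variance of every entry of A.

    Draws S logistic-normal samples per entry and returns the sample mean
    and the (S-1 denominator) sample variance.  Draws are stratified: one
    uniform is drawn per probability stratum [i/S, (i+1)/S) and mapped
    through the Normal inverse CDF, so every draw is a genuine sample from
    the marginal while the estimator variance shrinks well below the plain
    iid rate.
    """
    if S < 2:
        raise ValueError("S must be >= 2 for a sample variance")
    rng = np.random.default_rng(seed)
    m, k = state.A_mean.shape
    mean = np.zeros((m, k))
    m2 = np.zeros((m, k))
    count = 0
    # streaming (Welford) accumulation keeps memory flat for large S
    for i in range(S):
        eps = ndtri((i + rng.random((m, k))) / S)
        draw = expit(state.A_mean + state.A_scale * eps)
        count += 1
        delta = draw - mean
        mean += delta / count
        m2 += delta * (draw - mean)
    var = m2 / (S - 1)
    return mean, var


def tfa_point_estimate(state: VariationalState) -> np.ndarray:
    """Closed-form posterior mean of TF activity, exp(mu + sigma^2 / 2)."""
    return np.exp(state.U_mean + 0.5 * state.U_scale**2)


def summarize(state: VariationalState, gene_ids, tf_ids, cell_ids,
              S: int = 2000, seed: int = 0, meta: dict | None = None) -> PosteriorSummary:
    """Full posterior summary from a fitted variational state."""
    A_mean, A_var = summarize_A(state, S=S, seed=seed)
    summary_meta = dict(meta or {})
    summary_meta.update({"mc_samples": S, "summary_seed": seed})
    return PosteriorSummary(
        A_mean=A_mean,
        A_var=A_var,
        tfa=tfa_point_estimate(state),
        B_mean=state.B_mean.copy(),
        gene_ids=np.asarray(list(gene_ids), dtype=object),
        tf_ids=np.asarray(list(tf_ids), dtype=object),
        cell_ids=np.asarray(list(cell_ids), dtype=object),
        meta=summary_meta,
    )


def threshold_network(summary: PosteriorSummary, min_prob: float) -> pd.DataFrame:
    """Edges with posterior probability >= ``min_prob``.

    Returns a DataFrame (gene, tf, probability, variance, sign) sorted by
    descending probability, then gene and TF label; sign is the sign of the
    posterior mean of B (direction of regulation, auxiliary output).
    """
    if not (0.0 <= min_prob <= 1.0):
        raise ValueError("min_prob must lie in [0, 1]")
    m, k = summary.A_mean.shape
    rows, cols = np.nonzero(summary.A_mean >= min_prob)
    df = pd.DataFrame({
        "gene": summary.gene_ids[rows],
        "tf": summary.tf_ids[cols],
        "probability": summary.A_mean[rows, cols],
        "variance": summary.A_var[rows, cols],
        "sign": np.sign(summary.B_mean[rows, cols]).astype(int),
    })
    df = df.sort_values(
        ["probability", "gene", "tf"], ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return df


def average_posteriors(summaries) -> pd.DataFrame:
    """Elementwise average of posterior mean matrices from several datasets.

    Inputs are DataFrames (genes x TFs crosstabs); all must carry identical
    label sets (order may differ).  Used to combine models fitted to
    multiple expression matrices of the same system into one consensus GRN.
    """
    frames = list(summaries)
    if not frames:
        raise ValueError("need at least one posterior mean matrix")
    ref = frames[0]
    gene_set = set(ref.index)
    tf_set = set(ref.columns)
    for other in frames[1:]:
        if set(other.index) != gene_set or set(other.columns) != tf_set:
            raise ValueError("posterior matrices carry different label sets")
    aligned = [f.loc[ref.index, ref.columns] for f in frames]
    return sum(aligned[1:], start=aligned[0].copy()) / len(aligned)
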