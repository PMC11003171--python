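"""Network evaluation metrics and robustness protocols.

AUPRC here is step-wise average precision with tied scores collapsed into a
single threshold group (no interpolation): over descending unique score
thresholds, AP = sum_k (R_k - R_{k-1}) * P_k.  A constant predictor thus
scores exactly the positive rate.  Two evaluation pair sets are supported:

* ``keep_all`` — every pair in the gold standard is evaluated; gold pairs
  absent from the predictions are ranked last (score -inf, tied among
  themselves);
* ``overlap`` — only pairs present in both predictions and gold standard.

Calibration follows a cumulative binning of posterior variances: bin j
contains the lowest j/n_bins fraction of entries by variance and is scored
with overlap AUPRC; a well-calibrated model's AUPRC declines with variance.

The perturbation protocols (prior shuffling, empty prior, false-positive
noise injection, cell downsampling, reference-network splitting) reproduce
the robustness battery used to stress GRN inference methods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import ExpressionMatrix, PriorNetwork
from .posterior import PosteriorSummary


@dataclass
class ScoredNetwork:
    """A dense genes x TFs score matrix with labels (any method's output)."""

    scores: np.ndarray
    gene_ids: np.ndarray
    tf_ids: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2:
            raise ValueError("scores must be 2-D (genes x TFs)")
        if not np.isfinite(self.scores).all():
            raise ValueError("scores must be finite")
        self.gene_ids = np.asarray(list(self.gene_ids), dtype=object)
        self.tf_ids = np.asarray(list(self.tf_ids), dtype=object)
        if len(self.gene_ids) != self.scores.shape[0]:
            raise ValueError("gene label count does not match scores")
        if len(self.tf_ids) != self.scores.shape[1]:
            raise ValueError("TF label count does not match scores")

    @classmethod
    def from_summary(cls, summary: PosteriorSummary) -> "ScoredNetwork":
        return cls(summary.A_mean, summary.gene_ids, summary.tf_ids)


@dataclass
class CalibrationCurve:
    bin_fractions: np.ndarray     # increasing, last = 1.0
    bin_auprc: np.ndarray         # NaN where undefined (no gold positives)
    bin_sizes: np.ndarray
    bin_defined: np.ndarray       # bool flags


def average_precision(scores: np.ndarray, labels: np.ndarray) -> float:
    """Tie-safe step-wise average precision of a flat score/label vector."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = labels.sum()
    if n_pos == 0:
        raise ValueError("average precision undefined: no positive labels")
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    y = labels[order]
    # threshold-group boundaries: last index of each unique descending score
    boundary = np.nonzero(np.diff(s) != 0)[0]
    ends = np.concatenate([boundary, [s.size - 1]])
    tp = np.cumsum(y)[ends]
    n_pred = ends + 1.0
    precision = tp / n_pred
    recall = tp / n_pos
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_recall) * precision))


def _pair_scores(network, pairs):
    """Score lookup for (gene, tf) pairs; -inf when the pair is absent."""
    gi = {g: i for i, g in enumerate(network.gene_ids.tolist())}
    ti = {t: i for i, t in enumerate(network.tf_ids.tolist())}
    out = np.full(len(pairs), -np.inf)
    for j, (g, t) in enumerate(pairs):
        ig = gi.get(g)
        it = ti.get(t)
        if ig is not None and it is not None:
            out[j] = network.scores[ig, it]
    return out


def auprc(pred: ScoredNetwork, gold: PriorNetwork, mode: str = "keep_all") -> float:
    """Average precision of a scored network against a binary gold standard.

    ``keep_all`` evaluates all gold pairs (missing predictions rank last);
    ``overlap`` evaluates only pairs present in both label sets.
    """
    if mode not in ("keep_all", "overlap"):
        raise ValueError(f"unknown AUPRC mode: {mode!r}")
    gold_pairs = [(g, t) for g in gold.gene_ids.tolist() for t in gold.tf_ids.tolist()]
    labels = np.asarray(gold.entries, dtype=float).reshape(-1)
    if mode == "overlap":
        pred_genes = set(pred.gene_ids.tolist())
        pred_tfs = set(pred.tf_ids.tolist())
        keep = [i for i, (g, t) in enumerate(gold_pairs)
                if g in pred_genes and t in pred_tfs]
        gold_pairs = [gold_pairs[i] for i in keep]
        labels = labels[keep]
    if labels.size == 0 or labels.sum() == 0:
        raise ValueError("no gold-standard positives among evaluated pairs")
    scores = _pair_scores(pred, gold_pairs)
    return average_precision(scores, labels)


def auprc_ratio(pred: ScoredNetwork, gold: PriorNetwork, mode: str = "keep_all") -> float:
    """AUPRC divided by the positive rate (the random-predictor baseline)."""
    gold_pairs_rate = float(np.mean(gold.entries)) if mode == "keep_all" else None
    if mode == "overlap":
        pred_genes = set(pred.gene_ids.tolist())
        pred_tfs = set(pred.tf_ids.tolist())
        keep_rows = [i for i, g in enumerate(gold.gene_ids.tolist()) if g in pred_genes]
        keep_cols = [j for j, t in enumerate(gold.tf_ids.tolist()) if t in pred_tfs]
        sub = gold.entries[np.ix_(keep_rows, keep_cols)]
        gold_pairs_rate = float(sub.mean())
    return auprc(pred, gold, mode=mode) / gold_pairs_rate


def calibration_curve(summary: PosteriorSummary, gold: PriorNetwork,
                      n_bins: int = 10) -> CalibrationCurve:
    """Cumulative-variance calibration of posterior edge probabilities.

    Entries are sorted by posterior variance ascending (stable tie-break by
    gene then TF label); bin j holds the lowest j/n_bins fraction and is
    scored with overlap AUPRC against the gold standard.  Bins whose gold
    overlap has no positives are flagged undefined (NaN), never zero.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    m, k = summary.A_mean.shape
    genes = summary.gene_ids
    tfs = summary.tf_ids
    flat_var = summary.A_var.reshape(-1)
    gene_col = np.repeat(np.arange(m), k)
    tf_col = np.tile(np.arange(k), m)
    order = sorted(
        range(m * k),
        key=lambda i: (flat_var[i], genes[gene_col[i]], tfs[tf_col[i]]),
    )
    order = np.asarray(order)
    n_total = m * k

    gold_index = {(g, t): gold.entries[i, j]
                  for i, g in enumerate(gold.gene_ids.tolist())
                  for j, t in enumerate(gold.tf_ids.tolist())}

    fractions = np.arange(1, n_bins + 1) / n_bins
    sizes = np.ceil(fractions * n_total).astype(int)
    bin_auprc = np.full(n_bins, np.nan)
    defined = np.zeros(n_bins, dtype=bool)
    flat_mean = summary.A_mean.reshape(-1)
    for b, size in enumerate(sizes):
        members = order[:size]
        scores, labels = [], []
        for i in members:
            key = (genes[gene_col[i]], tfs[tf_col[i]])
            if key in gold_index:
                scores.append(flat_mean[i])
                labels.append(gold_index[key])
        labels = np.asarray(labels, dtype=float)
        if labels.size and labels.sum() > 0:
            bin_auprc[b] = average_precision(np.asarray(scores), labels)
            defined[b] = True
    return CalibrationCurve(
        bin_fractions=fractions, bin_auprc=bin_auprc,
        bin_sizes=sizes, bin_defined=defined,
    )


def iou_top_edges(a: ScoredNetwork, b: ScoredNetwork, top_fraction: float = 0.25) -> float:
    """Intersection-over-union of the two networks' top-fraction edge sets.

    Each network keeps its top ``round(top_fraction * M * K)`` (gene, TF)
    pairs by score, ties broken by label order; the IoU of the two sets
    measures how similar the inferred GRNs are.
    """
    if not (0.0 < top_fraction <= 1.0):
        raise ValueError("top_fraction must lie in (0, 1]")
    if (set(a.gene_ids.tolist()) != set(b.gene_ids.tolist())
            or set(a.tf_ids.tolist()) != set(b.tf_ids.tolist())):
        raise ValueError("networks carry different label sets")

    def top_set(net: ScoredNetwork) -> set:
        m, k = net.scores.shape
        n_top = int(round(top_fraction * m * k))
        flat = [(-net.scores[i, j], net.gene_ids[i], net.tf_ids[j])
                for i in range(m) for j in range(k)]
        flat.sort()
        return {(g, t) for _, g, t in flat[:n_top]}

    ea, eb = top_set(a), top_set(b)
    union = ea | eb
    if not union:
        return 1.0
    return len(ea & eb) / len(union)


# ---------------------------------------------------------------------------
# perturbation protocols
# ---------------------------------------------------------------------------

def shuffle_prior(prior: PriorNetwork, seed: int) -> PriorNetwork:
    """Misassign prior rows: permute gene rows while labels keep position.

    The negative control for prior usefulness — the multiset of rows is
    preserved but row content no longer matches the gene labels.
    """
    if prior.n_genes < 2:
        raise ValueError("need at least 2 genes to shuffle")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(prior.n_genes)
    return PriorNetwork(prior.entries[perm], prior.gene_ids.copy(), prior.tf_ids.copy())


def empty_prior(prior: PriorNetwork) -> PriorNetwork:
    """The 'no prior' control: all entries zero, labels preserved."""
    return PriorNetwork(np.zeros_like(prior.entries), prior.gene_ids.copy(),
                        prior.tf_ids.copy())


def inject_noise(prior: PriorNetwork, noise_level: float, seed: int) -> PriorNetwork:
    """Add false-positive edges: noise_level x current positives new edges.

    New positives are placed uniformly at random over the zero entries
    (without replacement); original positives are untouched.  A 1%-dense
    prior at levels 1.0 / 2.5 / 5.0 becomes 2% / 3.5% / 6% dense.
    """
    if noise_level < 0:
        raise ValueError("noise_level must be >= 0")
    n_new = int(round(noise_level * prior.n_positives))
    entries = prior.entries.copy()
    if n_new == 0:
        return PriorNetwork(entries, prior.gene_ids.copy(), prior.tf_ids.copy())
    zeros = np.flatnonzero(entries.reshape(-1) == 0)
    if zeros.size < n_new:
        raise ValueError(
            f"cannot add {n_new} edges: only {zeros.size} zero entries available"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(zeros, size=n_new, replace=False)
    flat = entries.reshape(-1)
    flat[chosen] = 1.0
    return PriorNetwork(entries, prior.gene_ids.copy(), prior.tf_ids.copy())


def downsample_cells(W: ExpressionMatrix, fraction: float, seed: int) -> ExpressionMatrix:
    """Uniform without-replacement subsample of cells; genes unchanged."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    n_keep = int(round(fraction * W.n_cells))
    if n_keep == 0:
        raise ValueError("fraction selects zero cells")
    rng = np.random.default_rng(seed)
    rows = np.sort(rng.choice(W.n_cells, size=n_keep, replace=False))
    return ExpressionMatrix(W.values[rows], W.cell_ids[rows], W.gene_ids.copy())


def split_reference(gold: PriorNetwork, prior_fraction: float, seed: int):
    """Partition a reference network's positive edges into prior and eval.

    The prior part receives round(prior_fraction * P) positives; the parts
    are disjoint and their union is the reference's positive set.  At 0.5
    this is the BEELINE-style half/half split; at 0.8 the CV-style split.
    """
    if not (0.0 < prior_fraction < 1.0):
        raise ValueError("prior_fraction must lie in (0, 1)")
    pos = np.argwhere(gold.entries == 1)
    if pos.shape[0] < 2:
        raise ValueError("need at least 2 positive edges to split")
    n_prior = int(round(prior_fraction * pos.shape[0]))
    if n_prior == 0 or n_prior == pos.shape[0]:
        raise ValueError("prior_fraction leaves one side of the split empty")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(pos.shape[0])
    prior_entries = np.zeros_like(gold.entries)
    eval_entries = np.zeros_like(gold.entries)
    for i in perm[:n_prior]:
        prior_entries[pos[i, 0], pos[i, 1]] = 1.0
    for i in perm[n_prior:]:
        eval_entries[pos[i, 0], pos[i, 1]] = 1.0
    prior_part = PriorNetwork(prior_entries, gold.gene_ids.copy(), gold.tf_ids.copy())
    eval_part = PriorNetwork(eval_entries, gold.gene_ids.copy(), gold.tf_ids.copy())
    return prior_part, eval_part
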