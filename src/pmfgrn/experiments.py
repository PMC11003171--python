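"""Orchestration for the robustness experiment loops.

Thin drivers that repeat the core workflow (select hyperparameters, refit,
score) under systematic perturbations: growing false-positive noise in the
prior, or shrinking expression matrices, each repeated with distinct seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import ExpressionMatrix, PriorNetwork
from .evaluation import ScoredNetwork, auprc, downsample_cells, inject_noise
from .selection import final_fit, search


@dataclass
class SweepPoint:
    level: float
    repetition: int
    auprc: float
    extra: dict = field(default_factory=dict)


def noise_sweep(W: ExpressionMatrix, prior: PriorNetwork, gold: PriorNetwork,
                grid, noise_levels=(0.0, 1.0, 2.5, 5.0), n_reps: int = 1,
                mode: str = "keep_all", seed: int = 0,
                holdout_fraction: float = 0.2) -> list:
    """GRN inference under increasing false-positive noise in the prior."""
    points = []
    for level in noise_levels:
        for rep in range(n_reps):
            rep_seed = seed + 7919 * rep + int(level * 1000)
            noisy = inject_noise(prior, level, seed=rep_seed)
            result = search(W, noisy, grid, fraction=holdout_fraction,
                            seed=rep_seed + 1)
            summary = final_fit(W, noisy, result.best_config,
                                summary_seed=rep_seed + 2)
            score = auprc(ScoredNetwork.from_summary(summary), gold, mode=mode)
            points.append(SweepPoint(level=level, repetition=rep,
                                     auprc=float(score),
                                     extra={"prior_density": noisy.density}))
    return points


def downsample_sweep(W: ExpressionMatrix, prior: PriorNetwork, gold: PriorNetwork,
                     grid, fractions=(0.8, 0.6, 0.4, 0.2), n_reps: int = 5,
                     mode: str = "keep_all", seed: int = 0,
                     holdout_fraction: float = 0.2) -> list:
    """GRN inference on cell-axis subsamples of the expression matrix."""
    points = []
    for frac in fractions:
        for rep in range(n_reps):
            rep_seed = seed + 104729 * rep + int(frac * 1000)
            W_sub = downsample_cells(W, frac, seed=rep_seed)
            result = search(W_sub, prior, grid, fraction=holdout_fraction,
                            seed=rep_seed + 1)
            summary = final_fit(W_sub, prior, result.best_config,
                                summary_seed=rep_seed + 2)
            score = auprc(ScoredNetwork.from_summary(summary), gold, mode=mode)
            points.append(SweepPoint(level=frac, repetition=rep,
                                     auprc=float(score),
                                     extra={"n_cells": W_sub.n_cells}))
    return points
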