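"""Model and optimizer hyperparameters.

Fixed constants follow the published settings: interactions are clipped to
``[a_min, a_max] = [0.005, 0.995]`` before the logit transform, the signed
strength matrix B has prior scale ``sigma_b = 1``, log-TFA has prior mean
``mu_u = 0``, the per-cell depth logit has prior variance 9, and the log
observation noise has a standard-normal prior.  ``sigma_a``, ``sigma_u`` and
the ELBO weight ``beta`` are the searchable hyperparameters.

Optimization uses Adam with learning rate 0.1, betas (0.9, 0.99) and global
gradient-norm clipping at 1e-4.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass(frozen=True)
class HyperparameterConfig:
    # prior scales / locations
    sigma_a: float = 1.0          # prior scale of logit(A)
    sigma_u: float = 1.0          # prior scale of log(U)
    beta: float = 1.0             # ELBO weight on prior/entropy terms, >= 1
    a_min: float = 0.005
    a_max: float = 0.995
    sigma_b: float = 1.0          # prior scale of B
    mu_u: float = 0.0             # prior mean of log(U)
    d_prior_var: float = 9.0      # prior variance of logit(d)
    sigma_obs_prior_mean: float = 0.0   # prior on log(sigma_obs)
    sigma_obs_prior_var: float = 1.0
    # optimizer
    learning_rate: float = 0.1
    adam_beta1: float = 0.9
    adam_beta2: float = 0.99
    grad_clip_norm: float = 1e-4
    batch_size: int = 1024
    # Monte Carlo / stopping
    elbo_mc_samples: int = 1
    summary_mc_samples: int = 2000
    iw_samples: int = 64
    holdout_fraction: float = 0.2
    max_steps: int = 20_000
    patience: int = 20
    eval_interval: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.a_min < self.a_max < 1.0):
            raise ValueError("require 0 < a_min < a_max < 1")
        for name in ("sigma_a", "sigma_u", "sigma_b", "d_prior_var",
                     "sigma_obs_prior_var", "learning_rate", "grad_clip_norm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.beta < 1.0:
            raise ValueError("beta must be >= 1")
        if not (0.0 < self.holdout_fraction < 1.0):
            raise ValueError("holdout_fraction must lie in (0, 1)")
        for name in ("batch_size", "elbo_mc_samples", "summary_mc_samples",
                     "iw_samples"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def replace(self, **kwargs) -> "HyperparameterConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "HyperparameterConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown hyperparameter fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "HyperparameterConfig":
        with open(Path(path)) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)

    def to_yaml(self, path) -> None:
        with open(Path(path), "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
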