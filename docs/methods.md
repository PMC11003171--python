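# Methods

## Generative model

Cells are indexed `n = 1..N`, genes `m = 1..M`, TFs `k = 1..K`.  Each
cell's expression profile is modeled as

    W_n | U, V, sigma_obs, d  ~  Normal( d_n * U_n V^T , sigma_obs^2 ),
    V = A . B   (elementwise),

with mutually independent latent variables:

| latent | support | prior | role |
|---|---|---|---|
| `U_nk` | (0, ∞) | log U ~ Normal(mu_u, sigma_u²) | TF activity per cell |
| `A_mk` | (0, 1) | logit A ~ Normal(logit(clip(Ā_mk)), sigma_a²) | interaction probability |
| `B_mk` | ℝ | Normal(0, sigma_b²) | signed interaction strength |
| `d_n` | (0, 1) | logit d ~ Normal(0, 9) | sequencing depth factor |
| `sigma_obs` | (0, ∞) | log sigma_obs ~ Normal(0, 1) | global noise scale |

`Ā` is the binary prior-knowledge matrix; `clip(x) = max(min(x, a_max),
a_min)` with `a_min = 0.005`, `a_max = 0.995` keeps the logit finite.  The
clip makes the prior logit means antisymmetric: an edge maps to +5.29, a
non-edge to −5.29.  Raw UMI counts are used as-is (cast to reals, never
normalized); the depth factor `d_n` absorbs library-size variation.

The prior over `A` is what pins down the latent column identities — matrix
factorization is otherwise identifiable only up to a column permutation —
so an empty or shuffled prior is the natural negative control.

## Variational family and ELBO

The approximate posterior factorizes completely, one Normal per
unconstrained scalar coordinate (log U, logit d, logit A, B, log
sigma_obs).  All log-densities in the package are densities over the
*constrained* variables: change-of-variable Jacobians are included in both
the prior and the variational density, so the two are directly comparable
and the Jacobians cancel exactly inside ELBO-type differences and
importance weights.

The objective is the β-weighted ELBO

    E_q[ log p(W | ·) + β (log p(z) − log q(z)) ],   β ≥ 1,

estimated by reparameterized Monte Carlo (1 sample per step by default).
With cell minibatches, the likelihood and the prior/entropy terms of the
batch's local latents (rows of U, entries of d) are scaled by N/|batch|;
global terms enter unscaled.  This makes the minibatch objective exactly
unbiased for the full ELBO (verified to 1e−8 in the tests by averaging a
disjoint batch partition at a fixed latent sample).

Because every factor is Gaussian in the unconstrained space, the gradient
of each ELBO term with respect to the variational means and scales has a
closed form; the package computes the full reparameterized gradient
analytically (validated against central finite differences to 5e−6) rather
than depending on an autodiff framework.

## Optimization

Adam with learning rate 0.1 and betas (0.9, 0.99); the global gradient
norm is clipped to 1e−4 before each update.  Variational scales are
optimized through a softplus reparameterization, and for numerical safety
unconstrained means are clamped to [−15, 15] and scales to [1e−4, 10]
after each step.  `q` is initialized at the prior (Ã = prior logits,
σ̃_A = sigma_a, B̃ = 0, Ũ = mu_u, d̃ = 0, σ̃_d = 3, õ = 0, σ̃_o = 1), so the
KL term starts at zero and early optimization pressure comes from the
likelihood alone.

A minibatch step updates the batch's local variational parameters plus all
global parameters; Adam's bias-correction counters are tracked per cell
for local blocks.  Default batch size is 1024 cells (full batch when N is
smaller), evaluation every 100 steps, patience 20 evaluations, at most
20,000 steps.  The small-problem configurations used by the tests and the
acceptance script shorten this to ~2,000 steps with evaluation every 50,
which the ELBO traces show is past the point of diminishing returns at
N = 500, M = 200, K = 8.

Early stopping tracks one of two metrics every evaluation:

* **validation AUPRC** (hyperparameter search): average precision of the
  current posterior means on held-out prior rows against the full prior;
* **importance-weighted marginal log-likelihood** (final fit):
  log-sum-exp of `log p(W, z_s) − log q(z_s)` over S = 64 draws (β = 1
  joint), computed on the training data.

The best-scoring checkpoint is restored on return; metric ties keep the
earliest checkpoint for determinism.  At S = 1 the IW estimator coincides
bitwise with the one-sample unweighted ELBO drawn from the same seed
(shared code path), and its expectation is non-decreasing in S.

## Posterior summaries

`q(A)` is logistic-normal, which has no closed-form moments, so the
posterior mean and variance of each entry are estimated from S = 2000
draws by default.  Draws are *stratified*: one uniform per probability
stratum [i/S, (i+1)/S) mapped through the Normal inverse CDF.  Every draw
is a genuine sample from the marginal and the estimators remain the plain
sample mean and (S−1)-denominator sample variance, but the estimator error
falls well below the iid Monte Carlo rate — at S = 1e5 the moments agree
with 200-point Gauss-Hermite quadrature to ~1e−6 across means in [−4, 4]
and scales in [0.1, 2].

TF activity uses the exact lognormal posterior mean `exp(Ũ + σ̃_U²/2)`
instead of Monte Carlo, since the lognormal moments are closed-form.  The
sign of the posterior mean of `B` is reported with thresholded edge lists
as an auxiliary direction-of-regulation readout; it is not evaluated.
Posterior mean matrices from several expression datasets of the same
system can be averaged elementwise (labels must match exactly;
reconciliation is deliberately the caller's job so silent intersections
cannot hide errors).

## Hyperparameter selection and cross-validation

The selection workflow holds out a random 20% of genes by zeroing their
prior rows (their logit means collapse to logit(a_min), the same low
number for every entry — identical to the "no prior" control applied
per-row), shares that single split across all grid configurations for
comparability, trains each with validation-AUPRC stopping, and refits the
argmax configuration (ties: first in grid order) on the unmodified prior
with IW-stopping.  The default grid spans `sigma_a` ∈ {0.25, 0.5, 1, 2},
`sigma_u` ∈ {0.25, 1}, β ∈ {1, 2, 4}; the compact workflows in the tests
and acceptance script use the `sigma_a` axis alone, which is the dominant
dial for how strongly the prior pins the posterior.

Cross-validation splits the *positive edges* of a gold standard uniformly
at random (not stratified by gene or TF): `train_fraction` of positives
form the fold prior, the remainder the evaluation standard; each fold runs
the full selection workflow with an inner 80/20 prior holdout and is
scored with keep-all AUPRC against its evaluation edges.  Ratios 0.8 down
to 0.2 are supported for split-ratio experiments.

## Evaluation metrics

**Average precision** is step-wise (no interpolation): tied scores form a
single threshold group, so a constant predictor scores exactly the
positive rate.  The implementation is checked against an independent
brute-force threshold sweep on hundreds of tied instances.  Two pair sets
are supported: *keep-all* evaluates every gold-standard pair, ranking gold
pairs absent from the predictions last (score −∞, tied among themselves);
*overlap* evaluates only pairs present in both label sets.

**Calibration** sorts entries by posterior variance ascending (stable
tie-break by gene then TF label) into 10 cumulative bins — bin j holds the
lowest j/10 of variances, exactly ceil(j·MK/10) entries — and scores each
bin with overlap AUPRC; bins whose gold overlap has no positives are
flagged undefined rather than scored zero.

**IoU** keeps each network's top round(0.25·M·K) pairs by score over all
M·K entries (ties broken by label order) and reports intersection over
union of the two sets.

**Perturbations**: `inject_noise` adds round(level × positives) false
edges uniformly over zero entries (a 1%-dense prior at levels 1.0 / 2.5 /
5.0 becomes exactly 2% / 3.5% / 6% dense); `shuffle_prior` permutes rows
under fixed labels; `empty_prior` zeroes everything; `downsample_cells`
subsamples the cell axis without replacement; `split_reference` partitions
a reference network's positives into prior and evaluation parts.  Sweep
drivers rerun the full selection workflow per noise level or subsample
fraction with distinct seeds.

## Synthetic data

The generator samples from the model's own generative process: a binary
ground-truth network with exactly round(density·M·K) edges placed
uniformly, B ~ Normal(0, sigma_b²), U ~ lognormal(mu_u, sigma_u²),
logit(d) ~ Normal(0, depth_logit_sd²), then Gaussian observations floored
at 0 and rounded to integers so fixtures look like UMI matrices (the
rounding is data realism only; with zero noise and d ≡ 0.5 the count
matrix reconstructs exactly).  Defaults: 500 cells, 200 genes, 8 TFs, 5%
edge density, sigma_b = sigma_u = 1, sigma_obs_true = 0.5.  `mu_u = 1`
puts expected expression magnitudes at O(1–100); `depth_logit_sd = 1`
gives tamer depth variation than the prior's variance 9, which is a prior
over plausible depths rather than a typical spread.  The corrupted prior
drops each true edge with probability 0.2 and adds false edges at rate
0.005, emulating incomplete and partly wrong database priors.

What the generator does *not* emulate: dynamical trajectories, batch
effects, zero inflation/dropout, count overdispersion.  Passing recovery
tests therefore demonstrates the correctness of the inference machinery
under the model's own assumptions, not performance on real data.

## Known limitations

* Mean-field VI underestimates posterior variance; the calibration curve
  measures how informative the variances are despite this.
* When the prior confidently excludes a true edge, the `A·B` product
  creates a self-reinforcing saddle: with A pinned near 0 the likelihood
  gradient on B vanishes and vice versa, so such edges can stay
  confidently wrong.  Weakly-pinning configurations (small β, or the
  selection workflow's preference for validation-recoverable settings)
  mitigate but do not eliminate this; it is the main failure mode visible
  in calibration under heavily corrupted priors.
* A single shared `sigma_obs` ignores gene-specific noise scales.
* Support violations in density evaluation raise errors rather than
  returning −∞: reparameterized samples cannot leave the support, so a
  violation always indicates a bug.
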