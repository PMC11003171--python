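"""Robustness protocols: noisy priors, shuffled priors, downsampled cells.

Demonstrates the perturbation operations used to stress GRN inference:
injecting false-positive edges into the prior at controlled densities,
shuffling prior rows (a negative control that breaks the gene-to-row
assignment), and subsampling cells.
"""

import numpy as np

import pmfgrn as pg

rng = np.random.default_rng(0)
flat = np.zeros(1000 * 100)
flat[rng.choice(flat.size, 1000, replace=False)] = 1.0
prior = pg.PriorNetwork(flat.reshape(1000, 100),
                        [f"g{i}" for i in range(1000)],
                        [f"t{j}" for j in range(100)])
print(f"starting prior density: {prior.density:.1%}")
for level in (1.0, 2.5, 5.0):
    noisy = pg.inject_noise(prior, level, seed=1)
    print(f"  +{level:.0%} noise -> {noisy.density:.1%} non-zero edges")

shuffled = pg.shuffle_prior(prior, seed=2)
print(f"shuffled prior keeps {shuffled.n_positives} positives "
      f"but misassigns rows (negative control)")
print(f"empty prior density: {pg.empty_prior(prior).density:.0%}")

data = pg.simulate(pg.SimulationConfig(n_cells=200, n_genes=50, n_tfs=4,
                                       edge_density=0.1, seed=1))
for frac in (0.8, 0.6, 0.4, 0.2):
    sub = pg.downsample_cells(data.W, frac, seed=3)
    print(f"downsampled to {frac:.0%}: {sub.n_cells} cells")

prior_half, eval_half = pg.split_reference(data.true_A, 0.5, seed=4)
print(f"reference split: {prior_half.n_positives} prior edges / "
      f"{eval_half.n_positives} evaluation edges (disjoint halves)")
# These operations feed the sweep drivers (pmfgrn.noise_sweep,
# pmfgrn.downsample_sweep) that rerun the full selection workflow per level.
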