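"""Estimate the nonadditive variance captured by a trained network.

A probe matrix (a zero row stacked on the identity) extracts the per-marker
additive effects a_k = f(e_k) - f(0) from the trained model.  EBV = X a is
the model's own linear approximation; EGV = f(X) its full prediction.
n2 = 1 - corr(EGV, EBV)^2 is the share of the model's predicted genetic
variance that its linear approximation misses, and sigma2_NADL = n2 x
var(EGV) the nonadditive variance in trait units.
"""

import numpy as np

import gblupnet as gn
from gblupnet import deep, linearize

cfg = gn.SimulationConfig(
    n_individuals=800, n_markers=250, target_h2=0.25, target_d2=0.15, target_e2=0.10,
    pen_var=0.0, litter_var=0.0, factor_effect_sd=0.0, n_epistatic_pairs=60, seed=5,
)
genotypes = gn.simulate_genotypes(cfg)
phenotypes, truth = gn.simulate_phenotypes(genotypes, cfg)
y = gn.znormalize(phenotypes["phenotype"])
X = genotypes.dosages.astype(float)

train, val, test = np.arange(500), np.arange(500, 650), np.arange(650, 800)
net_cfg = deep.NetworkConfig(
    arch="mlp", hidden_sizes=(32, 16), l1=0.002, l2=0.05, learning_rate=1e-3,
    max_epochs=100, early_stop_patience=15, seed=5,
)
model = deep.build_model(net_cfg, X.shape[1])
deep.train(model, X[train], y[train], X[val], y[val])

res = linearize.linearize_model(model, X[test])
print(f"trait simulated with d2 = {truth.realized_d2:.2f}, e2 = {truth.realized_e2:.2f}")
print(f"prediction of the all-zero genotype y0 = {res.y0_hat:.3f}")
print(f"corr(EGV, EBV) on the test set = {np.corrcoef(res.egv, res.ebv)[0, 1]:.3f}")
print(f"n2 (nonadditive share of the model's genetic variance) = {res.n2:.3f}")
print(f"sigma2_uDL = {res.sigma2_u_dl:.4f}  ->  sigma2_NADL = {res.sigma2_na_dl:.4f}")
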