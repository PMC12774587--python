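# Methods

This note documents the models, the numerical choices, and the boundaries of
what the test suite demonstrates. It is the package's own account; every
number quoted here is computed by the tests, the examples, or
`scripts/acceptance.py`.

## Simulated populations

The simulator emulates a station-tested boar population: two haplotypes per
animal, markers laid out on 18 autosomes (optionally one sex chromosome for
QC exercises), allele frequencies uniform on a configurable MAF range
(default 0.05–0.5). Linkage is a first-order Markov copy process: each
haplotype allele is copied from the previous marker with probability
`ld_decay` (default 0.5), else drawn fresh; chromosome starts always draw
fresh. With equal frequencies at adjacent markers the adjacent-marker dosage
correlation equals `ld_decay` (verified by Monte Carlo at 0.9). This
single-parameter model reproduces the feature that matters downstream —
correlated markers feeding the relationship matrices and the networks — and
nothing else: there is no recombination map, mutation, pedigree, or
missingness.

Phenotypes are built as additive + dominance + epistatic + environmental +
residual:

- additive values are centered dosages times i.i.d. normal effects (the
  architecture VanRaden-1 `G` assumes);
- dominance values are centered heterozygosity indicators times normal
  effects with per-marker SD proportional to `1/(p_k q_k)`, which makes the
  dominance covariance exactly proportional to the `D` matrix the package
  builds, so the AD model is correctly specified on simulated data;
- epistatic values are sums over random marker pairs of products of centered
  dosages (the additive-by-additive construction `E_aa` targets; default 100
  pairs);
- the environment is the structure of the pre-correction model: random pen
  (default variance 0.3) and litter (0.2) effects with ~10 animals per pen
  and ~2 per litter, plus fixed month-of-birth, herd-year, parity-of-dam and
  compartment effects (level SD 0.2). Defaults follow the emulated study's
  design: a moderately heritable trait (default targets h² = 0.25,
  d² = 0.02, e² = 0) on the z-score scale, 13 birth years with the last two
  as the test generation.

Variance bookkeeping: the four genetic/residual components are centered and
Gram–Schmidt orthogonalized, then each is rescaled so its sample variance
equals its target share of a unit "pre-correctable" variance. Realized
shares therefore match targets exactly and variances add to machine
precision. The shares are defined against the genetic + residual variance
(what survives pre-correction), not the raw phenotypic variance that also
contains pen/litter/factor variance — the same convention as analyzing
pre-corrected, z-normalized phenotypes. A consequence of orthogonalization
is that the stored dominance/epistatic marker effects are generative values,
exact only up to the (small, O(1/√n)) orthogonalization correction; the
additive effect vector is exact.

## QC and pre-correction

Markers are kept when sample MAF > 0.05, when the exact Hardy–Weinberg test
p-value is ≥ 10⁻²⁵, and when they sit on autosomes (threshold directions are
stated explicitly because "excluded below/above" conventions vary). The HWE
test is the standard two-sided exact test on the heterozygote count
conditional on allele counts (sum of outcome probabilities not exceeding the
observed outcome's, no mid-p), computed in log space with a
brute-force-enumeration oracle in the tests. QC is order-independent and
refuses to return an empty marker set.

Pre-correction fits trait = month-of-birth + herd-year + parity +
compartment (fixed, treatment-coded, rank-deficient columns dropped with a
warning) + pen + litter (random) by REML, using the same solver as the
genomic models with one identity-block covariance (`Z Zᵀ`) per factor. The
pre-corrected phenotype is the residual after subtracting the fixed-effect
fit and both BLUPs; by the mixed-model equations it is exactly orthogonal to
the fixed-effect design. A caveat the tests encode: with a single pen or
litter level the factor is confounded with the intercept, its variance is
unidentifiable, and only the residuals are meaningful. z-normalization uses
the sample SD (n−1).

## Relationship matrices and REML

`G` is VanRaden method 1 verbatim: centered dosages, one global denominator
`Σ 2p_k(1−p_k)`, frequencies computed from the analyzed sample by default
(external frequencies accepted for train-only workflows). `D` uses the
heterozygosity coding `z ∈ {0,1}` centered at `2p_k q_k` with per-marker
denominator `2p_k²q_k²`, averaged over markers. **Scale property**: this
denominator makes `E[diag D] = mean((1−2p_kq_k)/(p_kq_k)) ≥ 2` under HWE
(≈3.4 on the default MAF spectrum), so the fitted σ²_d is per unit of `D`
and the dominance *share* of phenotypic variance is approximately
σ²_d × mean(diag D)/σ²_p. The tests assert the closed-form diagonal
expectation and state dominance-recovery truth on this coefficient scale.
`E_aa = (G ⊙ G)/v` with `v = tr(G ⊙ G)/n`, which fixes `trace(E_aa) = n`.
Matrices are dense float64; GCTA-convention binary triplets and CSV are
supported for interchange.

REML maximizes the restricted likelihood
`−½(log|V| + log|XᵀV⁻¹X| + yᵀPy)` by average-information steps with step
halving, an EM-REML fallback whenever the AI step cannot improve, and
components floored at `10⁻⁶ × var(y)`; components pinned at the floor with
negative score are frozen out of the update. Convergence is a change in
restricted log-likelihood below 10⁻⁶ (at most 100 iterations;
non-convergence is flagged, not raised). SEs come from the inverse AI
matrix, ratio SEs by the delta method on that covariance. Single-kernel fits
(the A model, and any one-matrix REML) are solved in the eigenbasis of the
kernel — mathematically identical, one O(n³) decomposition then O(n)
iterations; the tests check the two representations agree to 10⁻⁸.
Boundary behavior worth knowing: for a truly null component the constrained
estimate lands on the floor in roughly half of replicates (the standard
boundary asymptotics), never significantly above zero.

BLUP prediction uses train-only fits:
`û_test = σ²_c K_c[test,train] V_train⁻¹ (y_train − μ̂)` with the GLS
intercept, validated to 10⁻⁸ against a Henderson mixed-model-equation solve.

## Networks and training

The MLP/CNN/VAE run on a small numpy engine written for this package:
dense and valid-padding 1-D convolution layers with He-normal
initialization and L1/L2 kernel penalties (Keras-style `l1·Σ|w| + l2·Σw²`),
leaky-ReLU activations, non-overlapping max (default) or average pooling,
Adam (ε = 10⁻⁷), and a mini-batch MSE loop with early stopping that restores
the best-validation weights. All randomness flows through seeded numpy
generators, which makes training bit-reproducible in a fixed single-threaded
environment — the property the smoke-study determinism test asserts.

Hyperparameter presets bundle the studied configurations per population
line: MLP hidden sizes 96:64:32:16 (L1 0.01/L2 0.1 for the sire preset,
0.007/0.15 for the dam preset); CNN with one convolution (16 or 8 filters,
kernel 5, pooling 3) before a 64:32:16 stack; Adam at learning rate 10⁻⁵,
batch 32, MSE loss, raw 0/1/2 inputs without standardization. Values the
source material leaves open are explicit config with these defaults: leaky
slope 0.3, max pooling, penalties applied as kernel regularizers on all
dense/conv layers, max 500 epochs, patience 20. Tests and examples override
to larger learning rates and smaller architectures — at a few hundred
training animals, 10⁻⁵ with batch 32 barely moves the weights inside any
sane epoch budget; the override is a scale adaptation, not a claim about the
presets.

## Validation design and metrics

The test set is fixed by birth year (youngest two years by default); the
remaining pool is split into train/validation either by 10-fold
cross-validation repeated 5 times (50 splits, every pool animal validating
exactly 5 times) or by 50 random 80/20 fraction splits — both modes exist
because the two descriptions of the emulated design (k-fold text vs 80/20
table) cannot both be literal; reports name the mode used. Predictive
ability is sample Pearson `r`; splits-average reports mean ± sample SD over
splits, averaged-predictions correlates the per-animal mean prediction with
the test phenotypes. Splits with zero-variance predictions are excluded
with a warning, not imputed. For noisy split predictions the
averaged-predictions value stochastically dominates the splits-average (the
bagging property the acceptance suite checks at ≥95/100 simulated
ensembles).

## VAE augmentation

One VAE per population is trained on all training genotypes (per-bin models
are the other defensible reading; a single model is cheaper and is what this
package does). Equal-frequency quantile bins guarantee non-empty bins; tied
quantiles merge with a warning. The loss is per-sample squared
reconstruction error plus `kl_weight ×` KL to the standard normal (default
weight 1), with reparameterized sampling. Generation fits a diagonal
Gaussian to each bin's encoded means, samples `per_bin` latents, decodes,
and maps outputs to {0,1,2} by rounding and clipping (a per-marker 3-class
head is available as `output_mode="softmax"`); single-member bins sample
from that member's posterior. Synthetic phenotypes are exactly the bin-edge
midpoints, so an augmented batch adds at most `n_bins` distinct phenotype
values, and augmentation never touches validation or test sets. Encoder and
decoder default to symmetric dense stacks (256:64 to a 16-dimensional
latent space); these sizes are exposed configuration, chosen for desk-scale
data, not claims about the emulated study's (unpublished) settings.

## Probe linearization

The probe matrix stacks a zero row on the m×m identity with genotype codes
0 and 1 — deliberately the heterozygote step `f(e_k) − f(0)` at the all-zero
background, not the 0→2 span. For any model that is exactly linear the
extracted effects equal its weights to 10⁻⁶ and n² ≤ 10⁻¹⁰; pairwise
interactions are invisible to the probe by construction (no probe row sets
two markers), which is what makes `n² = 1 − corr(EGV, EBV)²` a measure of
the nonlinearity the model expresses *on the test genotypes*. n² is
invariant to affine rescaling of either vector, `σ²_NADL = n² σ²_uDL ≤
σ²_uDL` always, with σ²_uDL the n−1 sample variance of the test-set EGV.
Across splits, EBV/EGV are aggregated by per-animal averaging by default
(concatenation by flag) before the pooled n² and the comparison correlations
corr(avg_ebv, y_test) and corr(avg_egv, y_test) are computed. A caveat the
tests quantify: probe effects are one-unit secants at the zero-genotype
corner, which sits off the data manifold (mean dosage ≈ 1); for strongly
nonlinear, lightly regularized networks n² therefore carries an artifact
component even on purely additive traits. The pipeline-level acceptance
check is accordingly a *paired contrast* at matched total genetic variance —
a trait with d² = 0.15, e² = 0.10 versus a purely additive trait of equal
genetic variance, same seeds — where the nonadditive arm shows the larger
pooled n² in ≥9/10 repetitions.

## Problem sizes and what the tests show

The default desk profiles are: REML recovery at n = 1,200 animals ×
m = 2,000 markers (20 seeds per scenario; 2-SE coverage of the true h² and
of the model-scale dominance coefficient is scale-free), the paired n²
contrast at n = 700 × m = 200 with 3 splits per arm, the bit-reproducibility
smoke study at n = 500 × m = 300 with 6 splits, and the acceptance-script
study at n = 1,500 × m = 1,000 with 10 splits. At these sizes the deep
models roughly match or trail GBLUP on a mostly additive trait — consistent
with the emulated study's finding that the deep advantage is small and
arrives mainly through the bagged (averaged-predictions) ensemble, which
beats the splits-average by a wide relative margin here as well. Passing
tests demonstrate correctness of the machinery and reproduction of the
design's qualitative phenomena at desk scale; they do not demonstrate
field-scale predictive performance, which in the emulated study required
~15,000 animals and 36,000 markers per line.

## Known limitations

- The linkage model is first-order Markov; long-range LD and population
  structure (beyond two lines as separate simulations) are absent.
- Missing genotypes are rejected, not imputed; sample-level QC (call rate,
  relatedness) is out of scope.
- The dominance-matrix scale property above means σ²_d is not directly a
  variance share; conversions go through the mean diagonal of `D`.
- n² cannot be decomposed into dominance versus epistatic parts, and it
  inherits the probe-corner artifact described above.
- Dense O(n³) REML limits multi-kernel fits to a few thousand animals on
  one CPU; the eigen fast path applies only to single-kernel models.
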