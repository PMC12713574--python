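# Methods

This note documents the models, algorithms and design choices behind
`gwadl`, in the order the pipeline runs them.

## Scope and intent

The package implements a genomic-prediction strategy for structured plant
populations: preselect SNP markers by multilocus GWAS P-value ("enrichment"),
feed them to a tuned two-hidden-layer regression network, and benchmark the
result against GBLUP and against networks given genomically spaced
(unenriched) markers. Because realistic inputs (hundreds of genotypes,
millions of SNPs) are not shippable, a structured-population simulator with
known ground truth is a first-class component: every end-to-end claim the
test suite makes is made against simulated data whose generating model is
described below.

## Panel construction (`gwadl.geno`)

Dosages count the panel-wide minor allele, so MAF and the additive coding
are consistent everywhere downstream. Missing calls are `nan`. Variant
filtering keeps biallelic SNPs with missing rate strictly below 5% and MAF
strictly above 5% (both read as strict inequalities); mean imputation then
replaces each missing call with the variant's observed-call mean, the only
operation allowed to produce fractional dosages. MAF is computed on observed
calls only. Coordinates are 1-based as in VCF; chromosomes sort lexically.

## Trait preparation (`gwadl.pheno`)

Traits are Box-Cox transformed, with the exponent lambda chosen on the fixed
grid [-5, 5] in steps of 0.1 to maximize the Shapiro-Wilk W statistic of the
transformed values (scipy's Royston implementation of W). Non-positive
traits are shifted by `1 - min(y)` first; ties in W break toward the lambda
closest to 1 (the gentlest transform).

Broad-sense heritability uses the repeatability method on a balanced
one-way ANOVA with genotype as the factor:

    Vg = (MS(G) - MS(E)) / r,   Ve = MS(E)
    H2indiv = Vg / (Vg + Ve)
    H2geno  = Vg / (Vg + Ve / r)

where r is the number of replicate blocks per genotype. Genotypes lacking
the full complement of blocks are dropped (the formulas assume balance);
a negative Vg is truncated to zero and flagged. Both heritabilities are
invariant to affine rescaling of the trait.

## Association scan (`gwadl.scan`)

Population structure is corrected with the top-k principal components of the
column-standardized dosage matrix (k = 2 by default, matching a two-deme
population). The single-marker step is exact OLS of the trait on
[intercept | PCs | pseudo-QTN dosages | marker], vectorized through the
Frisch-Waugh projection so a 5,000-marker scan is a single pass of linear
algebra; markers collinear with the fixed design receive p = 1.

The multilocus scan is FarmCPU-style: it alternates

1. a fixed step (the OLS scan above, conditioning on current pseudo-QTNs),
2. a binning step (best-p marker per genome bin, bins ranked by that p, over
   bin sizes {5e5, 5e6, 5e7} bp and candidate counts {10, 50, 100}),
3. a random step that scores each (bin size, count) candidate set by the
   REML likelihood of a variance-component model whose kinship is built from
   those candidates alone, adopting the likelihood-maximizing set, and
4. collinearity pruning (pairwise dosage r^2 capped at 0.7; the smaller-p
   member survives),

until the pseudo-QTN set repeats or 10 iterations elapse. After every fixed
step each pseudo-QTN's own p-value is re-derived by testing it with the
other pseudo-QTNs as covariates (leave-one-out), both so it keeps competing
in the next binning step and so the final report carries a real p-value for
it.

Two guards keep the scan calibrated under the null. A marker only becomes a
pseudo-QTN candidate if its fixed-step p < 0.01, and the scan only *starts*
accumulating pseudo-QTNs once some marker beats 0.01/m. Without the second
gate, pseudo-QTNs picked from null noise mutually condition one another and
inflate each other's significance; with it, a null scan reduces to plain
covariate-adjusted OLS, whose Bonferroni family error is the nominal 5%.

Marker selection for prediction is either by enrichment (p < 1e-4, the
"above background" band) or by spacing (every floor(m/n)-th marker).
Bonferroni thresholds are alpha/m; the reporting helper truncates to two
significant figures (0.05 / 5,641,729 prints as 8.8e-9).

## GBLUP (`gwadl.gblup`)

The kinship matrix is VanRaden method 1 on the chosen marker subset:
`K = ZZ' / (2 * sum p_j (1-p_j))` with columns centered at `2 p_j`, `p_j`
the observed minor-allele frequency. Variance components of
`y = Xb + u + e`, `u ~ N(0, sg^2 K)`, `e ~ N(0, se^2 I)` are estimated by
REML profiled to the ratio `delta = se^2/sg^2` on the eigenbasis of K
projected off X; a 65-point coarse grid brackets the mode and golden-section
search over log delta refines it to 1e-8. Boundary optima (pure noise,
noise-free) return at the bracket edge rather than erroring.

Prediction uses the conditional mean
`u_test = K_ts (K_tt + delta I)^{-1} (y - Xb)`, which is algebraically a
ridge regression on centered marker effects (the rrBLUP identity); the test
suite verifies the identity to 1e-6 on random instances rather than assuming
it. Cross-validation uses seeded random folds (sizes differ by at most one),
refits the variance components per fold (statistically cleaner than a single
global fit; the alternative would leak test information), and reports
fold-level accuracy as the squared Pearson correlation between observed and
predicted values; the `1 - MSE/Var` definition is computed alongside.

## The prediction network (`gwadl.network`)

A fully connected feed-forward regressor with two hidden layers and a single
linear output, trained by mini-batch SGD (batch 32, learning rate 0.005,
momentum 0.9, global gradient-norm clipping at 10) on

    MSE + l1 * sum|w| + l2 * sum w^2

with one shared dropout rate on the input and both hidden layers (inverted
dropout, so evaluation needs no rescaling). Activations: tanh, relu, or
maxout with two linear pieces per unit. Inputs are standardized per feature;
the target is standardized internally and predictions un-scaled. Training
stops when the 3-epoch moving average of the full-data training MSE improves
on the previous window by less than 1% (relative; an absolute mode exists),
or at 200 epochs. All randomness (initialization, shuffling, dropout masks)
comes from one seeded generator, so a seed fully determines the fit.

The hyperparameter grid factorizes the canonical 3,840-model search:
3 activations x {40, 126, 213, 300}^2 hidden widths x 4 L1 levels x 4 L2
levels x 5 dropout levels, with `random_grid(n)` for seeded desk-scale
subsampling. Grid search scores each configuration by mean 5-fold CV MSE on
shared seeded folds — the same fold protocol GBLUP uses, so method
comparisons are paired.

Variable importance follows Gedeon's weight-magnitude measure: each layer's
absolute weights are normalized over their inputs, the normalized magnitudes
are multiplied along every input-to-output path and summed, and the result
is renormalized to sum to one. Maxout layers contribute the element-wise
maximum of their two pieces' magnitudes. All-zero columns contribute zero.
The measure is invariant to hidden-unit relabeling. Importance should be
read off a well-fit model — in the pipeline it is computed on the CV-selected
best configuration, which is also how the importance-recovery acceptance
check is run.

## Simulator (`gwadl.simulate`)

Genotypes follow the Balding-Nichols model: ancestral frequency
p ~ U(0.05, 0.95) per locus, per-deme frequencies
Beta(p(1-F)/F, (1-p)(1-F)/F) with F the target Fst, dosages Binomial(2, f)
at the individual's deme frequency. LD is emulated by block-copying: within
a block of `ld_block_len` markers (default 20) each column copies the
previous one, redrawing each individual with probability 0.05, so r decays
geometrically along the block. "Confounded" markers — zero causal effect,
per-deme frequencies fixed by config (the default exercise uses 0.77 vs
0.016) — are appended to test structure correction. Columns are re-oriented
to the panel-wide minor allele after drawing.

Phenotypes combine a sparse QTN term (effects drawn standard-normal or fixed
by config, scaled so the sparse share of genetic variance is
`1 - polygenic_fraction`) with a polygenic background of 1,000 tiny-effect
loci (implemented as real loci rather than a matrix-normal draw, so
marker-based methods can in principle capture it). The residual variance is
set from the *realized* genetic variance so the realized H2indiv equals its
target; H2geno then follows from r. An optional deme-mean shift creates
structure-trait confounding. Everything is a deterministic function of the
config seed, and exported fixtures (VCF + phenotype TSV + truth JSON)
round-trip losslessly and byte-identically.

Default study conditions: 313 individuals in two equal demes at Fst 0.1,
5,000 SNPs on 10 chromosomes at 10 kb spacing, 8 QTNs with a 15% polygenic
background, H2indiv 0.47 over r = 3 blocks. Prediction experiments use
H2geno = 0.6 (H2indiv = 1/3). What the simulator does *not* emulate: family
or pedigree relatedness within demes (individuals are exchangeable given
their deme), realistic LD decay with physical distance, allele-frequency
spectra from demography, genotyping error, and within-genotype environmental
covariance beyond a single residual term. Tests passing on these simulations
therefore validate the machinery and its statistical calibration, not
performance on any particular real population.

## Method comparison (`gwadl.evaluate`)

Fold-level R^2 values (paired across methods through the shared fold seed)
are compared by one-way ANOVA followed by Tukey's HSD on the studentized
range distribution, with a compact-letter display (insert-and-absorb
algorithm); the letters are checked for consistency against the pairwise
significance matrix. Heritable variance explained is
`HVE = 100 * R^2 / H2geno`; values above 100% are possible (enrichment
selects markers partly on the same data, which inflates accuracy) and are
reported as-is.

## Numerical and design notes

- Heritability denominators use H2geno (line level), since prediction
  operates on genotype means across blocks; this choice changes every HVE
  percentage and is therefore stated prominently.
- The scan's REML scoring reuses the GBLUP module's spectral REML.
- Fold partitions are pure random (unstratified).
- The enrichment cutoff, PCA rank, bin grid, collinearity cap, grid levels
  and early-stopping tolerances are all config-exposed with the defaults
  above.
- Problem sizes in the test suite (300 x 5,000 panels, 10-seed batteries,
  12-config grids) are chosen as the smallest designs at which the
  statistical claims are stable; they are deliberately far below the scale
  of real resequencing panels.

## Known limitations

- The multilocus scan is FarmCPU-*style*: the alternation, binning,
  pseudo-QTN substitution and elimination are reproduced from their public
  description, not from any released codebase, and exact p-value trails will
  differ from other implementations.
- A network whose markers tag a diffuse polygenic signal can recover much of
  what GBLUP recovers: early-stopped SGD on standardized inputs behaves like
  spectral ridge regression, and a polygenic signal is aligned with the top
  singular directions of the marker matrix. The enriched-vs-spaced contrast
  is therefore reproduced here as a strong ordering (enriched network ~
  heritability ceiling; spaced network well below both the enriched network
  and GBLUP on the same markers), not as a categorical inability of
  networks to exploit relatedness.
- The Shapiro-Wilk statistic is used only to *rank* lambdas; its absolute
  value at large n is not interpreted.
- Maxout uses two linear pieces (the canonical choice); deeper piece counts
  are out of scope.
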