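# Methods

## Model

`tadborder` models the probability that a genomic bin lies at a 3D domain
border as a binomial GLM with logit link: ln(P/(1−P)) = β₀ + β·X, one row
per bin, one column per genomic feature.  A slope βᵢ is the change in
border log-odds per unit of feature *i holding all other features fixed*;
this conditional interpretation is the entire point of the joint model, in
contrast to the marginal enrichment test.  Statistical interactions enter
as product columns Xᵢ·Xⱼ, so a pair of proteins can matter only through
co-occurrence (βᵢ ≈ βⱼ ≈ 0, βᵢⱼ ≠ 0).

Assumptions worth keeping in mind: bins are treated as independent
Bernoulli trials given X (spatial autocorrelation between neighboring bins
is ignored — border windows spanning many bins make successes locally
dependent in reality); effects are additive on the log-odds scale unless
product terms are supplied; and the border definition itself (junction ±
half a window) is taken as ground truth.

## Estimation

**IRLS (default).**  The likelihood is maximized by iteratively reweighted
least squares with a step-halving safeguard (a step is halved until the
log-likelihood does not decrease).  Convergence is declared when the
largest absolute coefficient change falls below `tol = 1e-8`, within
`max_iter = 100` iterations; both are arguments.  Standard errors come
from the inverse observed information at the optimum.  The design is rank-
checked up front (pivoted QR); dependent columns are reported by name.
Coefficients exceeding 100 in absolute value, or failure to converge, raise
a convergence error carrying the last iterate — on a binary design this is
essentially always (quasi-)separation.

*Exact row collapsing.*  When every feature column is in {0, 1} and p ≤ 22,
rows are collapsed to unique (pattern, y) combinations with frequency
weights before fitting.  The weighted Bernoulli likelihood is identical to
the row-level one, so estimates, standard errors, log-likelihood, AIC and
deviance are unchanged to machine precision (tested); fits on 10⁶-row
matrices then take milliseconds, which is what makes the replicated
million-row studies below affordable.

**L1 path.**  For large correlated feature sets the lasso-penalized fit
minimizes (1/N)·Σ loss + λ‖β‖₁ with an unpenalized intercept (the solver
behind the path is scikit-learn's saga coordinate-style optimizer; the
λ→C mapping, λ_max = max|xⱼᵀ(y−ȳ)|/N, the 100-point log-spaced path down to
10⁻⁴·λ_max, stratified seeded k-fold assignment and the mean cross-validated
binomial deviance used to select λ are implemented here).  Features are not
standardized by default: coordinate-mode values already share the [0, 1]
scale, and unscaled slopes keep their per-full-bin-occupancy meaning; a
flag enables standardization for quantitative data.  An L1 fit reports no
standard errors or p-values; a feature is called influential iff its
coefficient is nonzero.  Under full shrinkage the intercept is set to its
closed form logit(ȳ) (the iterative solver can stop prematurely there).

## Inference and diagnostics

- **Wald:** W = β̂/σ̂, two-sided p-values from the standard normal, 95%
  intervals β̂ ± z₀.₉₇₅σ̂.  Bonferroni significance divides α by the number
  of slope coefficients in the model at hand (for interaction models,
  marginal and product terms count jointly).
- **LRT:** D = 2(lnL_full − lnL_reduced), referenced to χ²₁; preferred when
  sparseness makes Wald standard errors unreliable.  A constant (e.g.
  all-zero) column is short-circuited to D = 0, p = 1, since the two models
  coincide.  On non-sparse data Wald and LRT p-values agree to within an
  order of magnitude (tested).
- **Fit quality:** AIC = −2lnL + 2(p+1), and a deviance ratio.  For
  ungrouped Bernoulli data the saturated-model deviance is identically
  zero, so the ratio is defined against the intercept-only (null) deviance:
  D_fit/D_null, with the complementary "fraction of null deviance
  explained" available behind a flag.

## Binning

Coordinates are 0-based half-open everywhere; chromosome names are matched
exactly.  Bins tile each chromosome (last bin may be short).  Border
points are TAD junctions; when consecutive TADs are separated by a gap,
both gap edges count (conservative reading), and chromosome-terminal TAD
edges are excluded by default (`include_chrom_ends` flips this).  A bin is
a border bin if it overlaps the window [junction − w/2, junction + w/2) at
all; overlapping windows are unioned.  Coordinate features store the
fraction of the bin covered by the union of intervals (partial overlap of
x% gives x/100, overlapping peaks never double-count); quantitative
features store the length-weighted mean with uncovered bases contributing
zero.  Both encoders are implemented with exact integer interval
arithmetic and are tested against per-base brute-force oracles.  Default
pairings are 50-bp bins with a 1-kb window (fly-scale) and 1-kb bins with
a 20-kb window (human-scale); both are ordinary parameters.

For the enrichment test's contingency table, "feature present" means a
coordinate value strictly greater than zero.

## Synthetic data

The generator replaces real accession-bound matrices while preserving the
statistical regime of binned ChIP-seq occupancy data:

- **Sparsity** defaults to 97% zeros (real 1-kb matrices run 99.4%; 50-bp
  fly matrices similar), achieved exactly in expectation by thresholding
  latent Gaussians at the sparsity quantile.
- **Correlation** defaults to a mean pairwise Pearson correlation of 0.25
  between occupancy columns (real data: ~0.28 fly, ~0.19 human), calibrated
  through a one-factor latent model with *graded* loadings
  (profile 0.6…1.0, scaled by root-finding on the exact bivariate-normal
  orthant probability).  Graded loadings make pairwise correlations
  heterogeneous — some pairs ~0.1, some ~0.6 — the way protein complexes
  share sites while unrelated factors do not; an equicorrelated option
  exists.  The heterogeneity matters for the method comparison: with
  perfectly uniform correlation every non-causal feature is equally
  confounded with the causal set and the comparison degenerates.
- **Values are binary** occupancy indicators: at high-resolution bins a
  50-bp bin is nearly always fully covered by a peak or untouched.
  Quantitative mode generates dense unit-variance correlated Gaussians
  (log-ratio-like signal).

Two response generators: the **logistic** generator draws slopes from
N(0, 1) and the intercept from N(−4.5, 1) — the intercept mean keeps
borders rare (~1%), matching real border counts — computes Z = β₀ + Xβ,
P = 1/(1+e^(−Z)) and Bernoulli Y, retaining all truth for scoring; and the
**threshold** generator, deliberately non-linear and non-additive so
method comparisons do not favor the logistic model: Y ~ Bernoulli(p₁) if
any causal feature value ≥ 0.5, else Bernoulli(p₀), with (p₀, p₁) solved
by 1-D root finding from a target odds ratio and marginal border rate
(satisfied to 10⁻¹⁰).  `add_border_noise` perturbs internal TAD junctions
by rounded N(0, sd) draws, moving shared junctions as one and clipping so
boundary order is preserved.

What the generator does **not** emulate: peak-width autocorrelation along
the genome (each row is exchangeable), chromosome-level covariate shifts,
the heavy-tailed block structure of real colocalization networks, and any
sequence composition.  Passing simulation studies therefore demonstrate
correctness and calibration of the estimators under a realistic sparsity/
correlation regime, not performance guarantees on any particular real
dataset.

## Study designs and problem sizes

All studies are seeded end-to-end; per-replicate seeds are spawned from the
study seed.  Replicates whose fit fails (quasi-separation) are excluded
and counted.

- **Marginal recovery:** 6 features, n = 10⁶ rows per replicate (the
  bootstrap scale of the original analyses; at 200k rows slope standard
  errors are √5 larger and the pooled R² attenuates mechanically by
  var(β)/(var(β)+SE²)), 100 replicates, pooled true-vs-estimated slope R².
  Run in coordinate and quantitative modes.
- **Interaction recovery:** the 6-feature design expanded with all 15
  product columns, slopes drawn for all 21 columns; R² over the product
  terms only.
- **Rare-peak recovery:** one feature constrained to exactly 50 peaks of
  2 kb (40 bins) placed uniformly; R² pooled over all slopes of that
  regime, with the rare slope's own pairs kept for inspection (its
  individual error sd is ~0.35 — 50 peaks simply carry little
  information — which is visible in the pooled scatter as a widened band).
- **Border-noise robustness:** a full genomic simulation — 60 Mb across 3
  chromosomes at 50-bp bins, abutting TADs of 30–150 kb, six proteins with
  junction-peak probabilities 0.9…0.15, 800-bp peaks jittered 150 bp around
  junctions plus uniform background — fit from true junctions and from
  junctions shifted by N(0, 2 kb); R² between the two slope vectors.
- **Method comparison:** 11 features, n = 10⁶ rows, 100 replicates per
  odds ratio; causal subset drawn uniformly with size uniform on {1, 2, 3};
  border rate 0.01; threshold response.  Scores are betas (joint model and
  enrichment test) and impurity importances (random forest, 500 trees by
  default, √p features per split; subsampled rows in tests for runtime).
  Rank-first means the single top-scoring feature is causal, with any tie
  at the top counted as failure.  Type-I error is family-wise per
  replicate — at least one non-causal feature with p < α = 10⁻⁵ — the only
  reading consistent with error rates of tens of percent at that α.

The qualitative contrasts reproduce robustly: the enrichment test's
family-wise error vastly exceeds the joint model's at equal α; both rank
causal features first at low odds ratios where random forests fail on
sparse data.  The *exact* rates (e.g. the enrichment test's error
percentage) are emergent properties of the feature-correlation structure
and the row count, and shift by tens of points between plausible synthetic
structures; they should be read as regime-level, not point, reproductions.

## Numerical choices and degenerate inputs

Probabilities are clipped to [1e-12, 1−1e-12] inside likelihoods; IRLS
working weights floored at 1e-10.  The latent-correlation calibration is
cached per (p, sparsity, target, structure).  Infeasible sparsity/
correlation targets, constant features in the enrichment test, one-class
labels, all-zero designs, overlapping TADs and malformed input files all
raise typed errors early; a failed feature inside `enrichment_scan` is
reported in its result row rather than aborting the scan.  Motif scanning
matches IUPAC consensus exactly (no mismatch tolerance), reports
reverse-strand hits in forward coordinates, keeps overlapping hits
(fractional encoding absorbs pileups), and enumerates SNP variants only at
concrete bases — ambiguity codes have no defined alternative allele, which
is also why a 13-mer with four N positions yields 27 mutated motifs.

## Limitations

Hi-C contact-matrix processing (normalization, domain calling) and
ChIP-seq peak calling are upstream of this package; it consumes their BED
output.  The model ignores spatial dependence between bins, so p-values
are anti-conservative to an unquantified degree on real genomes — rank
betas, not p-values, across features.  L1 estimates are biased by
construction and carry no uncertainty; use IRLS on a pre-selected feature
set for interpretable effect sizes.
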