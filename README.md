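# tadborder

Identify genomic features — DNA-binding proteins, functional elements,
sequence motifs — that positively or negatively influence the borders of
3D chromatin domains (TADs), from TAD coordinates and feature coordinates
or signal alone.

## The problem

Hi-C experiments partition genomes into topologically associating domains.
Many proteins (CTCF, cohesin, BEAF-32, CP190, ...) are *enriched* at TAD
borders, but enrichment is marginal evidence: when two proteins colocalize,
both appear enriched even if only one actually drives border formation.
`tadborder` implements the joint-modelling alternative: a multiple logistic
regression over all candidate features at once,

```
ln[ P(Y=1|X) / (1 − P(Y=1|X)) ] = β₀ + β·X
```

where each genomic bin (50 bp or 1 kb) contributes one row, `Y` flags bins
inside a window centered on a TAD junction, and `X` holds per-bin feature
values — fractional interval occupancy in [0, 1] (coordinate mode) or mean
signal such as log(ChIP/Input) (quantitative mode).  Because βᵢ measures the
effect of feature *i conditional on all others*, colocalized passengers get
β ≈ 0 while true drivers keep β > 0 (or β < 0 for features that counteract
borders).  The package provides:

- **Enrichment test** (`enrichment_test`, `enrichment_scan`): the classical
  2×2 contingency analysis recast as a simple logistic regression whose slope
  is exactly ln(odds ratio) for a binary feature, with Wald inference
  W = β̂/σ̂ and Bonferroni correction.
- **Multiple logistic regression** (`BorderLogit` / `fit_logistic_irls`):
  maximum likelihood by iteratively reweighted least squares, Wald and
  likelihood-ratio tests (D = 2(lnL_M1 − lnL_M2) ~ χ²₁), two-way interaction
  terms (`expand_interactions`), deviance ratio and AIC diagnostics, and an
  L1-regularized path with cross-validated penalty (`fit_logistic_l1`) for
  large correlated feature sets such as motif databases.
- **Binning** (`make_bins`, `label_borders`, `encode_*_feature`): BED/bedGraph
  → bin-by-feature design matrix.
- **Motif analysis** (`scan_motif`, `snp_effect_analysis`): IUPAC consensus
  scanning on both strands and joint estimation of wild-type versus
  single-base-variant motif effects on borders.
- **Simulation & benchmarking** (`simulate`, `benchmark`, `studies`):
  sparse correlated synthetic matrices, logistic and non-additive threshold
  response generators, and a harness comparing the joint model against the
  enrichment test and random forests (recovery R², rank-first rate,
  family-wise type-I error, ROC AUC).

## Worked example

The classical border-enrichment contingency table — 500 border bins with the
feature, 5,000 without; 2,000 / 200,000 outside borders:

```python
import numpy as np
import tadborder as tb

table = tb.ContingencyTable(a=500, b=5000, c=2000, d=200000)
tb.odds_ratio(table)                      # 10.0

Y = np.concatenate([np.ones(5500), np.zeros(202000)])
x = np.concatenate([np.ones(500), np.zeros(5000), np.ones(2000), np.zeros(200000)])
res = tb.enrichment_test(Y, x, feature="CTCF")
```

prints `beta=2.3026  se=0.0520  W=44.27  CI=[2.201, 2.405]` — the slope of
the simple logistic regression equals ln(10), the log odds ratio, and the
feature is ~10-fold enriched at borders.

Fitting the joint model on a simulated sparse genome (four proteins, ~3%
occupancy each, rare borders):

```python
X = tb.synth_feature_matrix(500_000, 4, sparsity=0.97, correlation=0.25, seed=1)
ds = tb.simulate_logistic_response(X, seed=2)   # draws true betas, simulates Y
matrix = tb.assemble_matrix(None, ds.Y, {f"P{j+1}": X[:, j] for j in range(4)})
fit = tb.fit_logistic_irls(matrix)
print(fit.summary())
```

```
Border multiple logistic regression
  estimator: irls    n_obs: 500000    features: 4
  log-likelihood: -113313.1410    AIC: 226636.2819
  deviance ratio (fitted/null): 0.992347
  converged: True in 8 iterations
           beta        se           W       p_value    ci_low   ci_high  significant
const -2.700148  0.006072 -444.712583  0.000000e+00 -2.712049 -2.688248         True
P1     0.169631  0.036939    4.592210  4.385774e-06  0.097232  0.242030         True
P2    -0.589288  0.054319  -10.848743  2.021877e-27 -0.695751 -0.482826         True
P3    -0.503755  0.057940   -8.694472  3.484471e-18 -0.617315 -0.390195         True
P4    -2.647797  0.140767  -18.809775  6.280434e-79 -2.923695 -2.371898         True
```

The generating truth for this seed was β = (0.189, −0.523, −0.413, −2.441):
every estimate sits within its 95% interval, positive and negative drivers
are recovered with their signs, and the Wald column gives per-feature
significance against the Bonferroni threshold.

## Command line

Each step is also a `tadborder` subcommand writing TSV plus a run manifest:

```bash
tadborder bin --tads tads.bed --peaks ctcf.bed --peaks beaf32.bed \
          --chrom-sizes genome.sizes --bin-size 50 --border-window 1000 \
          --out matrix.tsv
tadborder enrich --matrix matrix.tsv --alpha 1e-5 --out enrich.tsv
tadborder mlr    --matrix matrix.tsv --alpha 1e-5 --out mlr.tsv
tadborder motif-snp --fasta genome.fa --tads tads.bed \
          --motif CCANNAGNNGGCA --position 1 --out snp.tsv
```

`simulate` and `benchmark` subcommands generate synthetic datasets and run
the method comparison.

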