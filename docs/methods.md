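# Methods

## Model

PCCA couples two sample-matched data matrices through their principal
components. For genotype dosages `X` (n × p SNPs, standardized per SNP by
`(g − 2p̂)/√(2p̂(1−p̂))`, the usual genotype-PCA convention) and expression
`Y` (n × m genes, quantile-normalized, standardized, residualized against
known confounders), let `U_X` and `U_Y` be the orthonormal left singular
vectors of the top k and j components. The coupling is the SVD of the small
cross-product `M = U_Xᵀ U_Y = U_M diag(ρ) V_Mᵀ`. Because orthonormal score
matrices are their own whitening, `ρ` are exactly the canonical correlations
of the two PC sets, and the sample coordinates are `C_X = U_X U_M[:, :l]`
and `C_Y = U_Y V_M[:, :l]`. The assumptions are the usual linear-projection
ones: population structure enters expression additively as mean shifts, and
enough of it lies inside the top-j expression PC subspace to be picked up by
the correlation maximization.

Full-feature CCA (`full_cca`) is provided for contrast and for the
LDA-style confounder correction. With more features than samples and no
regularization its leading correlations are identically 1 — whitening makes
any two full-rank column spaces of centered matrices coincide — which is why
the PCA-first construction exists. The `ridge` argument adds a constant to
the covariance eigenvalues before whitening (`σ² → σ² + ridge`), shrinking
the whitening toward the identity; pseudoinverse tolerance is
`1e-10 × σ_max`.

A linear-regression coupling (`regression_link`) is also included: the
fitted values of `U_X` regressed on `U_Y` have SVD `U_Y V_M diag(ρ) U_Mᵀ`,
so its top-l coordinates reproduce `C_Y` up to scaling — the two couplings
give near-identical visualizations, a useful robustness check.

## Preprocessing

The expression pipeline runs in a fixed order: transcript → gene TPM
aggregation (sum), mean-TPM filter (keep mean ≥ 0.1; the boundary is kept),
region filter (drop non-autosomal genes and genes with TSS inside the MHC
interval, default chr6:28,477,797–33,448,354, GRCh38), quantile
normalization, per-gene standardization, residualization against
[intercept | one-hot batch | gender], re-standardization. Notes on the open
choices:

- **Quantile normalization dialect.** Each sample is mapped to the mean
  order-statistic reference ("average distribution"); ties within a sample
  receive the mean of the reference values their positions span. Held-out
  samples (in cross-validation) are mapped through the *training* reference
  by quantile interpolation.
- **Variance convention.** Standardization divides by the population sd
  (ddof 0); reported summary variances elsewhere use ddof 1.
- **Residualization.** The one-hot batch block plus an intercept is rank
  deficient by construction; the regression uses a least-squares
  pseudoinverse and warns. Residualized genes are re-standardized before PCA
  so per-gene variances are comparable at scoring time.
- **Genotypes.** Variant filtering keeps biallelic SNPs with MAF ≥ 0.05
  (inclusive), MAF computed on non-missing calls of the current sample set
  (hence idempotent); missing dosages are then mean-imputed per SNP.
- An alternative confounder correction projects the expression PC scores
  orthogonally to their top canonical directions against the confounder
  matrix (the CCA/LDA connection) instead of residualizing.

## Gene scores and significance

The score of gene g is its **variance in the projection**: with the
orthonormal coordinate matrix `C_Y`, project the standardized expression
matrix onto the coordinate plane (`Ŷ = C_Y C_Yᵀ Y`) and take the population
variance of gene g's column, computable in closed form as
`‖(L diag(σ))[g, :] V_M[:, :l]‖² / n`. For a unit-variance gene this is the
fraction of its variance lying in the projection plane (a number in [0, 1]),
which makes scores directly comparable across genes. A distinct quantity,
`gene_projection_loadings`, returns the matrix `B = L diag(1/σ) V_M[:, :l]`
with the defining identity `Y B = C_Y`; it maps expression to coordinates
and decomposes the projection into per-gene contributions, but it is not the
score: weighting by `1/σ` would down-weight exactly the high-variance
structure components the method is designed to find, and under that reading
strongly population-shifted genes are barely distinguishable from the
permutation null.

Significance: each permutation shuffles the rows of `U_X` jointly (the
columns' mutual structure is preserved), refits the k × j SVD, and
recomputes every gene's score — one shared set of permutations drives all
genes, so arbitrarily many permutations are cheap (each costs one small SVD
plus one m × j × l product). The p-value is the strict-exceedance count
`#{perm > obs}/n_perm` (a gene beating every permutation gets p = 0; a
`pseudocount` option gives `(c+1)/(n+1)` instead). The z-score is
`(obs − mean_perm)/sd_perm`; the sd (not variance) is used because a z-score
requires sd units. Per-iteration RNG streams come from
`SeedSequence(seed, spawn_key=(t,))`, so results do not depend on execution
order. FDR control uses Benjamini–Hochberg–Yekutieli with the harmonic
penalty `c(m)`, appropriate because the shared permutation fit correlates
the tests arbitrarily. Default `n_perm` is 100,000 from the CLI; the test
suite uses 2,000–5,000, which at the simulated sizes (hundreds of genes) is
enough granularity for BHY at 5%.

## Cross-validation

Leave-one-out refits *everything* per fold on n − 1 samples: the quantile
reference (when the input is TPM), per-feature centering/scaling, both PCAs
and the coupling; the held-out sample is then mapped through the training
statistics (`u = x L diag(1/σ)`, rotated by `V_M` / `U_M`). Reconstruction
error is, by default, measured in projection space — the squared distance
between the held-out sample's expression-side and genotype-side coordinates,
averaged per sample so in-sample and held-out errors are on the same scale;
when ρ is near 1 these should agree. An `--reconstruction=expression` mode
instead reconstructs the standardized expression vector from its
l-dimensional projection and measures the squared error there. Folds run in
a fixed order and are deterministic. When population labels are supplied the
report records, per fold, the nearest training-centroid population of the
held-out coordinates — computed within the fold, so sign or rotation
differences between folds cannot contaminate the comparison.

## eQTL utilities

Known eQTL effects are removed on the standardized scale: a reported
genotype–expression correlation `r_g` converts to the slope
`β_g = r_g / √(2 f_a (1 − f_a))` (the dosage has variance `2f(1−f)` under
Hardy–Weinberg and the expression is unit-variance), the expected population
mean is `y_gk = 2 β_g f_k`, and every sample in population k has it
subtracted before re-standardization. When a gene appears in several
population-level summary tables, the record with the larger |r_g| wins.

The cis scan is plain OLS of each gene on
[intercept | dosage | covariates], dosages in raw 0/1/2 coding
(mean-imputed), SNPs paired with a gene when they lie on the same
chromosome within a closed 1 Mb window of the TSS (strand ignored) and have
MAF ≥ 0.05. The t statistic on the dosage coefficient has n − c − 2 degrees
of freedom. eGenes are genes whose minimum nominal cis p-value clears a
cutoff; `compare_strategies` partitions eGene sets obtained under different
covariate choices (genotype PCs vs PCCA coordinates). Latent-factor
confounder estimation (PEER-style) is deliberately not implemented: the scan
accepts any user-supplied covariate matrix, and the synthetic pipeline
passes known batch indicators instead.

## Synthetic data

`synthetic_data` emulates a multi-population RNA-seq cohort with lab
batches. Genotypes follow the Balding–Nichols model: per SNP, ancestral
frequency `p₀ ~ U(0.05, 0.95)` and population frequencies
`Beta(p₀(1−F)/F, (1−p₀)(1−F)/F)` with F the FST divergence; dosages are
Binomial(2, p_k); degenerate Beta draws are resampled with a warning. SNPs
and genes sit at fixed spacings on two synthetic chromosomes; each cis gene
uses the SNP nearest its TSS.

Expression is built on a latent standardized scale: for a shifted gene, a
centered per-population shift vector scaled to root-mean-square
`pop_effect_size` (so "a 0.8-sd shift" is exact, not an expectation); batch
shifts `N(0, batch_effect_size)` per gene × batch cell; `cis_beta × dosage`
for cis genes; `N(0, noise_sd)` noise. Values are emitted as
`tpm_scale · exp(log_dispersion · z)` with `log_dispersion = 0.5`, keeping
per-gene cross-sample variability in the range typical of gene-level
RNA-seq quantifications; much larger dispersions make the marginal TPM
distributions so heavy-tailed that moment-based standardization reflects the
upper tail rather than the latent structure. The truth object records all
latent quantities.

Defaults (4 populations × 60 samples, 3,000 SNPs, FST 0.1, 600 genes, 10%
shifted at 0.8 sd, 4 batches at 1.0 sd, 5% cis genes) are chosen so the full
test suite runs in minutes on one CPU while preserving the qualitative
regime of a real multi-population cohort: batch dominates raw expression
PCA, population structure is crisp in genotype PCA, and the shifted-gene
signal is strong but not trivial. What the generator does **not** emulate —
linkage disequilibrium, admixture gradients, trans-eQTL networks,
count-level sampling noise, library-size effects — bounds what passing tests
show: they validate the linear-algebraic machinery and the statistical
calibration of the tests under the stated generative model, not robustness
to every artifact of real RNA-seq data.

## Numerical choices

- Sign convention: every singular vector is flipped so its
  largest-magnitude entry is positive; outputs are bit-stable across runs.
- PCA routes through the n × n Gram matrix when features outnumber samples;
  Gram and direct SVD routes agree to ~1e-8 after sign fixing.
- Tied canonical correlations leave the within-block rotation arbitrary; a
  warning is emitted and no canonical ordering is forced.
- ρ values are clipped to [0, 1] against roundoff.
- Samples are always matched by id; an order mismatch between matrices is an
  error, never a silent reindex.

## Known limitations

- The permutation test's granularity is 1/n_perm; with very many genes and
  BHY correction, detection effectively requires near-zero p-values, so
  n_perm must scale with the gene count.
- With two populations the second canonical direction is noise-dominated and
  its orientation is unstable between refits; quantities compared across
  fits (e.g. LOO displacement) should use ≥ 3 populations or l = 1.
- The cis scan loops over pairs in Python; it is meant for desk-scale
  analyses (10⁴–10⁵ pairs), not genome-wide scans over millions of SNPs.
- Sparse, regularized, and >2-matrix CCA variants are out of scope.
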