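# pcca

Population structure in gene expression via coupled PCA and canonical
correlation analysis.

PCA of a genotype dosage matrix cleanly separates human populations, but PCA
of a gene-expression matrix from the same individuals usually does not: the
directions of maximal expression variance are dominated by technical batch
and broad regulatory programs, not ancestry. This package implements
**PCCA** (principal component correlation analysis), a linear projection
that reveals the population structure hiding in expression data by coupling
the two data types, together with the statistics needed to use it: a
permutation test scoring each gene's contribution to the projection,
leave-one-out cross-validation of the whole fit, removal of known cis-eQTL
population-mean effects, and covariate-aware cis-eQTL scans that compare
genotype-PC covariates against PCCA-coordinate covariates. A synthetic-data
module generates multi-population genotypes (Balding–Nichols model) and
expression with population, batch and cis-genetic components, with full
ground truth, so the entire pipeline is testable without any downloads.

It is aimed at statistical geneticists and computational biologists working
with matched genotype + RNA-seq cohorts spanning multiple populations
(e.g. GEUVADIS-style designs).

## The method

Let `X` (n samples × SNPs) be the standardized genotype dosage matrix and
`Y` (n samples × genes) the quantile-normalized, standardized,
confounder-residualized expression matrix. Take the top PC score matrices

- `U_X` — first *k* genotype PCs (default k = 5),
- `U_Y` — first *j* expression PCs (default j = 30),

both orthonormal over the same samples, and form the k × j matrix

```
M = U_Xᵀ U_Y,     M = U_M diag(ρ) V_Mᵀ  (SVD)
```

The singular values `ρ` are the canonical correlations of the two PC sets,
and the PCCA coordinates of the samples are

```
C_X = U_X U_M[:, :l],     C_Y = U_Y V_M[:, :l]      (default l = 2)
```

`C_Y` is a projection of the *expression* data that clusters samples by
population even when expression PC1–PC2 do not. Because the PC scores are
orthonormal they are their own whitening, so the coupling never inverts a
feature-space covariance — the step that makes naive full-feature CCA
overfit catastrophically when features outnumber samples (with p, q > n the
leading "canonical correlations" of full CCA are exactly 1 for any data).

Each gene g is scored by its variance in the projection: with
`P = C_Y C_Yᵀ`, `score_g = ‖P y_g‖² / n`, the fraction of the
(unit-variance) gene's variance lying in the projection plane. Significance
comes from a permutation test that shuffles the rows of `U_X`, refits the
coupling, and recomputes all scores; p-values are the fraction of permuted
scores exceeding the observed score, and genes are called at FDR 5% with
the Benjamini–Hochberg–Yekutieli adjustment (valid under the strong
dependence the shared fit induces).

## Worked example

Simulate a four-population cohort (240 samples, 3,000 SNPs, 600 genes, 10%
of genes carrying a 0.8-sd population shift, lab batches), run the pipeline,
and score genes:

```python
import numpy as np
from pcca.synthetic_data import SimulationConfig, simulate_dataset
from pcca import preprocess as pp
from pcca.pcca_core import pca, pcca_fit
from pcca.significance import score_significance

ds = simulate_dataset(SimulationConfig(seed=0))
expr = pp.preprocess_expression(ds.expression, metadata=ds.metadata,
                                gene_annotation=ds.gene_annotation)
geno = pp.preprocess_genotypes(ds.genotypes, ds.snp_annotation, maf_min=0.05)
pX = pca(pp.standardize_dosages(geno), 5)
pY = pca(expr.values, 30)
model = pcca_fit(pX.scores, pY.scores, 2)
print("rho:", np.round(model.rho[:2], 3))

table = score_significance(expr, pX.scores, pY, l=2, n_perm=5000, seed=0, fdr=0.05)
print("significant genes:", int(table["significant"].sum()))
```

Output:

```
rho: [0.938 0.914]
significant genes: 44
```

The two canonical correlations near 0.9 say the top genotype and expression
PC subspaces share two strongly correlated directions — the population
structure. Of the 44 genes significant at BHY FDR 5%, all 44 are planted
population-shifted genes (60 were planted), i.e. the test recovers most of
the true signal with no false positives on this draw.

The same pipeline is available from the shell:

```sh
pcca simulate --seed 0 --out-dir sim/
pcca preprocess --expression sim/expression_tpm.tsv --metadata sim/metadata.tsv \
     --gene-annotation sim/gene_annotation.tsv --out std.tsv
pcca fit --expression std.tsv --genotypes sim/genotypes.vcf --out-dir fit/
pcca significance --expression std.tsv --genotypes sim/genotypes.vcf \
     --n-perm 100000 --seed 0 --out scores.tsv
```

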