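"""Expression and genotype preprocessing.

The expression pipeline runs in a fixed, logged order: aggregate transcripts
to genes -> mean-TPM filter -> region filter (MHC, non-autosomes) ->
quantile normalization -> per-gene standardization -> confounder
residualization -> re-standardization. Genotypes are filtered to biallelic
SNPs above a MAF threshold, mean-imputed, and scaled with the usual
genotype-PCA convention sqrt(2 p (1 - p)).

Standardization uses the population variance convention (divide by n);
reported summary variances elsewhere use n - 1. Both are recorded in output
metadata by the CLI.
"""

from __future__ import annotations

import logging
import warnings
from typing import Optional

import numpy as np
import pandas as pd

from .containers import ConfounderMatrix, ExpressionMatrix, GenotypeMatrix

logger = logging.getLogger("pcca")

#: Default MHC interval (GRCh38 coordinates, chr6).
DEFAULT_MHC_REGION = ("6", 28_477_797, 33_448_354)

_AUTOSOMES = {str(i) for i in range(1, 23)}


def _norm_chrom(c: str) -> str:
    c = str(c)
    return c[3:] if c.lower().startswith("chr") else c


# ---------------------------------------------------------------------------
# expression


def aggregate_transcripts_to_genes(
    transcript_tpm: ExpressionMatrix, tx2gene: pd.Series
) -> ExpressionMatrix:
    """Sum transcript-level TPM into gene-level TPM per sample."""
    if transcript_tpm.state != "tpm":
        raise ValueError("transcript aggregation expects TPM-state input")
    missing = transcript_tpm.gene_ids.difference(tx2gene.index)
    if len(missing):
        raise ValueError(f"transcripts missing from tx2gene map: {missing.tolist()[:10]}")
    genes = tx2gene.reindex(transcript_tpm.gene_ids)
    agg = transcript_tpm.values.T.groupby(genes.to_numpy()).sum().T
    agg.columns.name = None
    logger.info("aggregated %d transcripts into %d genes", len(genes), agg.shape[1])
    return ExpressionMatrix(agg, "tpm")


def filter_transcripts_by_mean_tpm(
    matrix: ExpressionMatrix, threshold: float = 0.1
) -> ExpressionMatrix:
    """Drop features whose cross-sample mean TPM is strictly below ``threshold``."""
    if matrix.state != "tpm":
        raise ValueError("mean-TPM filter expects TPM-state input")
    keep = matrix.values.mean(axis=0) >= threshold
    logger.info("mean-TPM filter >= %g: kept %d / %d features", threshold, keep.sum(), len(keep))
    return ExpressionMatrix(matrix.values.loc[:, keep], "tpm")


def filter_genes_by_region(
    matrix: ExpressionMatrix,
    annotation: pd.DataFrame,
    mhc_region: tuple = DEFAULT_MHC_REGION,
    autosomes_only: bool = True,
) -> ExpressionMatrix:
    """Remove genes on non-autosomes and genes with TSS inside the MHC interval."""
    missing = matrix.gene_ids.difference(annotation.index)
    if len(missing):
        raise ValueError(f"genes missing from annotation: {missing.tolist()[:10]}")
    ann = annotation.loc[matrix.gene_ids]
    chrom = ann["chromosome"].map(_norm_chrom)
    keep = pd.Series(True, index=matrix.gene_ids)
    if autosomes_only:
        keep &= chrom.isin(_AUTOSOMES)
    mhc_chrom, mhc_start, mhc_end = mhc_region
    in_mhc = (chrom == _norm_chrom(mhc_chrom)) & ann["tss"].between(mhc_start, mhc_end)
    keep &= ~in_mhc
    logger.info("region filter: kept %d / %d genes", keep.sum(), len(keep))
    return ExpressionMatrix(matrix.values.loc[:, keep], matrix.state)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force all samples to share the mean-order-statistic reference distribution.

    Each sample's values are replaced by the cross-sample mean of the sorted
    values at the same rank; ties within a sample receive the mean of the
    reference values their positions span.
    """
    if matrix.state != "tpm":
        raise ValueError("quantile normalization expects TPM-state input")
    V = matrix.values.to_numpy(dtype=float)
    if np.isnan(V).any():
        raise ValueError("quantile normalization requires a complete matrix")
    reference = quantile_reference(V)
    out = np.empty_like(V)
    for i in range(V.shape[0]):
        out[i] = _apply_quantile_reference(V[i], reference)
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.sample_ids, columns=matrix.gene_ids),
        "quantile_normalized",
    )


def quantile_reference(values: np.ndarray) -> np.ndarray:
    """Mean across samples of the per-sample order statistics."""
    return np.sort(values, axis=1).mean(axis=0)


def _apply_quantile_reference(row: np.ndarray, reference: np.ndarray) -> np.ndarray:
    order = np.argsort(row, kind="stable")
    sorted_vals = row[order]
    assigned = reference.astype(float).copy()
    # average the reference over each run of tied values
    start = 0
    m = len(row)
    for i in range(1, m + 1):
        if i == m or sorted_vals[i] != sorted_vals[start]:
            if i - start > 1:
                assigned[start:i] = assigned[start:i].mean()
            start = i
    out = np.empty(m)
    out[order] = assigned
    return out


def map_to_quantile_reference(new_sample: pd.Series, reference: np.ndarray) -> pd.Series:
    """Map a held-out sample through an existing training reference distribution.

    The reference may have a different length than the sample; ranks are
    matched by quantile interpolation.
    """
    row = new_sample.to_numpy(dtype=float)
    m = len(row)
    from scipy.stats import rankdata

    ranks = rankdata(row, method="average")  # 1..m, ties averaged
    q = (ranks - 1) / max(m - 1, 1)
    ref_q = np.linspace(0.0, 1.0, len(reference))
    mapped = np.interp(q, ref_q, reference)
    return pd.Series(mapped, index=new_sample.index)


def standardize_genes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Center and scale each gene to mean 0 and (population) variance 1."""
    V = matrix.values
    mean = V.mean(axis=0)
    sd = V.std(axis=0, ddof=0)
    zero = sd[sd < 1e-12]
    if len(zero):
        raise ValueError(f"zero-variance genes cannot be standardized: {zero.index.tolist()[:10]}")
    out = (V - mean) / sd
    return ExpressionMatrix(out, "standardized")


# ---------------------------------------------------------------------------
# genotypes


def snp_maf(geno: GenotypeMatrix) -> pd.Series:
    """Minor-allele frequency per SNP over non-missing dosages of the current samples."""
    p = geno.values.mean(axis=0, skipna=True) / 2.0
    return np.minimum(p, 1.0 - p)


def filter_variants(
    geno: GenotypeMatrix,
    annotation: Optional[pd.DataFrame] = None,
    maf_min: float = 0.05,
) -> GenotypeMatrix:
    """Keep biallelic SNPs with MAF >= ``maf_min`` (boundary inclusive).

    MAF is recomputed on the current sample set from non-missing dosages, so
    the operation is idempotent. Indels and multi-allelic records are removed
    via the annotation's ``is_biallelic_snp`` flag when an annotation is
    given.
    """
    keep = pd.Series(True, index=geno.snp_ids)
    if annotation is not None:
        missing = geno.snp_ids.difference(annotation.index)
        if len(missing):
            raise ValueError(f"SNPs missing from annotation: {missing.tolist()[:10]}")
        keep &= annotation.loc[geno.snp_ids, "is_biallelic_snp"].astype(bool)
    maf = snp_maf(geno)
    keep &= (maf >= maf_min) & (maf > 0)
    logger.info("variant filter MAF >= %g: kept %d / %d", maf_min, keep.sum(), len(keep))
    return GenotypeMatrix(geno.values.loc[:, keep])


def impute_missing_genotypes(geno: GenotypeMatrix) -> GenotypeMatrix:
    """Mean-impute missing dosages per SNP (after MAF filtering on non-missing calls)."""
    if not geno.has_missing():
        return geno
    means = geno.values.mean(axis=0, skipna=True)
    return GenotypeMatrix(geno.values.fillna(means))


def standardize_dosages(geno: GenotypeMatrix) -> pd.DataFrame:
    """Center dosages at 2p and scale by sqrt(2 p (1 - p)), the genotype-PCA convention."""
    if geno.has_missing():
        raise ValueError("impute missing genotypes before standardization")
    p = geno.values.mean(axis=0) / 2.0
    denom = np.sqrt(2.0 * p * (1.0 - p))
    zero = denom[denom < 1e-12]
    if len(zero):
        raise ValueError(f"monomorphic SNPs cannot be scaled: {zero.index.tolist()[:10]}")
    return (geno.values - 2.0 * p) / denom


# ---------------------------------------------------------------------------
# confounders


def build_confounder_matrix(metadata: pd.DataFrame) -> ConfounderMatrix:
    """One-hot encode batch plus a single binary gender column.

    With b batch levels the result is samples x (b + 1). A batch containing a
    single sample is perfectly confounded with that sample and triggers a
    warning.
    """
    for col in ("batch", "gender"):
        if col not in metadata.columns:
            raise ValueError(f"metadata lacks required column {col!r}")
        if metadata[col].isna().any():
            raise ValueError(f"missing values in metadata column {col!r}")
    batch = metadata["batch"].astype(str)
    counts = batch.value_counts()
    singletons = counts[counts == 1].index.tolist()
    if singletons:
        warnings.warn(
            f"batches with a single sample are perfectly confounded: {singletons}",
            stacklevel=2,
        )
    onehot = pd.get_dummies(batch, prefix="batch").astype(float)
    levels = sorted(metadata["gender"].astype(str).unique())
    if len(levels) > 2:
        raise ValueError(f"gender must be binary; saw levels {levels}")
    gender = (metadata["gender"].astype(str) == levels[-1]).astype(float)
    values = onehot.copy()
    values["gender"] = gender
    values.index = metadata.index
    return ConfounderMatrix(values, batch_columns=list(onehot.columns))


def regress_out_confounders(
    matrix: ExpressionMatrix, confounders: ConfounderMatrix
) -> ExpressionMatrix:
    """Replace each gene by its least-squares residual against [intercept | confounders]."""
    C = confounders.values.reindex(matrix.sample_ids)
    if C.isna().any().any():
        raise ValueError("confounder matrix does not cover all expression samples")
    n = matrix.n_samples
    design = np.column_stack([np.ones(n), C.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        warnings.warn(
            "confounder design is rank-deficient; residualizing via pseudoinverse",
            stacklevel=2,
        )
    Y = matrix.values.to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(design, Y, rcond=None)
    resid = Y - design @ coef
    return ExpressionMatrix(
        pd.DataFrame(resid, index=matrix.sample_ids, columns=matrix.gene_ids),
        "residualized",
    )


def orthogonal_confounder_projection(
    expr_pcs: pd.DataFrame, confounders: ConfounderMatrix, d: int
) -> pd.DataFrame:
    """Remove the top-d confounder-associated canonical directions from PC scores.

    CCA between orthonormal expression PC scores and a categorical confounder
    matrix recovers discriminant-like directions; projecting the scores
    orthogonally to the span of the top d expression-side canonical variates
    strips the batch-separating structure while leaving the rest of the
    subspace intact.
    """
    from .pcca_core import full_cca

    scores = expr_pcs.to_numpy(dtype=float)
    C = confounders.values.reindex(expr_pcs.index).to_numpy(dtype=float)
    try:
        rho, (zx, _zy) = full_cca(scores, C, l=d, ridge=0.0)
    except ValueError as err:
        raise ValueError(
            f"requested d={d} exceeds the available canonical directions ({err})"
        ) from err
    T = zx[:, :d]
    Q, _ = np.linalg.qr(T)
    corrected = scores - Q @ (Q.T @ scores)
    return pd.DataFrame(corrected, index=expr_pcs.index, columns=expr_pcs.columns)


# ---------------------------------------------------------------------------
# pipeline helpers


def preprocess_expression(
    expr: ExpressionMatrix,
    metadata: Optional[pd.DataFrame] = None,
    gene_annotation: Optional[pd.DataFrame] = None,
    tx2gene: Optional[pd.Series] = None,
    min_mean_tpm: float = 0.1,
    mhc_region: tuple = DEFAULT_MHC_REGION,
    autosomes_only: bool = True,
    restandardize: bool = True,
) -> ExpressionMatrix:
    """Run the fixed expression pipeline end to end.

    aggregate -> transcript filter -> region filter -> quantile normalize ->
    standardize -> residualize against [batch one-hot | gender] ->
    re-standardize. Steps whose inputs are not supplied are skipped (and
    logged).
    """
    if tx2gene is not None:
        expr = aggregate_transcripts_to_genes(expr, tx2gene)
    expr = filter_transcripts_by_mean_tpm(expr, min_mean_tpm)
    if gene_annotation is not None:
        expr = filter_genes_by_region(expr, gene_annotation, mhc_region, autosomes_only)
    else:
        logger.info("no gene annotation supplied; skipping region filter")
    expr = quantile_normalize(expr)
    expr = standardize_genes(expr)
    if metadata is not None:
        conf = build_confounder_matrix(metadata.loc[expr.sample_ids])
        expr = regress_out_confounders(expr, conf)
        if restandardize:
            expr = standardize_genes(expr)
    else:
        logger.info("no metadata supplied; skipping confounder residualization")
    return expr


def preprocess_genotypes(
    geno: GenotypeMatrix,
    annotation: Optional[pd.DataFrame] = None,
    maf_min: float = 0.05,
) -> GenotypeMatrix:
    """Variant filter then mean-imputation, ready for standardize_dosages/PCA."""
    geno = filter_variants(geno, annotation, maf_min)
    return impute_missing_genotypes(geno)
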