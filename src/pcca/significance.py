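"""Per-gene projection-variance scores, permutation significance, FDR control.

The PCCA expression coordinates are a linear map of the standardized
expression matrix: C_Y = Y B with B = L diag(1/sigma) V_M[:, :l]. Each
gene's score is its variance *in the projection*: project the expression
matrix onto the plane spanned by the (orthonormal) coordinate vectors,
Yhat = C_Y C_Y' Y, and take the per-gene variance of Yhat. For a
standardized gene the score is the fraction of that gene's variance lying
in the projection plane, computable directly from the PCA factors as
|| (L diag(sigma))[g, :] V_M[:, :l] ||^2 / n. Significance comes from a
permutation test that jointly shuffles the rows of the genotype score
matrix, refits the coupling, and recomputes every gene's score; one shared
set of permutations drives all genes.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, PCADecomposition, PCCAModel
from .pcca_core import _scores_frame

_STANDARDIZED_MEAN_TOL = 1e-6
_STANDARDIZED_VAR_TOL = 1e-3


def gene_projection_loadings(model: PCCAModel, pca_Y: PCADecomposition) -> pd.DataFrame:
    """The genes x l matrix B with Y B = C_Y for the centered expression matrix."""
    if model.j != pca_Y.k:
        raise ValueError(
            f"model was fitted with j={model.j} expression PCs but the PCA has k={pca_Y.k}"
        )
    L = pca_Y.loadings.to_numpy(dtype=float)
    sv = pca_Y.singular_values
    B = (L / sv) @ model.V_M[:, : model.l]
    return pd.DataFrame(B, index=pca_Y.feature_ids, columns=model.C_Y.columns)


def _gene_variances(expr) -> pd.Series:
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    mean = values.mean(axis=0)
    var = values.var(axis=0, ddof=0)
    if (mean.abs() > _STANDARDIZED_MEAN_TOL).any() or (
        (var - 1.0).abs() > _STANDARDIZED_VAR_TOL
    ).any():
        raise ValueError("expression matrix is not standardized (per-gene mean 0, variance 1)")
    return var


def gene_score(model: PCCAModel, pca_Y: PCADecomposition, expr) -> pd.Series:
    """Variance of each gene in the PCCA projection.

    The projection of the expression matrix onto the coordinate plane is
    Yhat = C_Y C_Y' Y; the score of gene g is the (population) variance of
    column g of Yhat, equal to || (L diag(sigma))[g, :] V_M[:, :l] ||^2 / n.
    Requires a standardized expression matrix so scores are comparable
    across genes (each is then the fraction of the gene's unit variance
    captured by the projection, a number in [0, 1]).
    """
    _gene_variances(expr)  # validates standardization
    if model.j != pca_Y.k:
        raise ValueError(
            f"model was fitted with j={model.j} expression PCs but the PCA has k={pca_Y.k}"
        )
    n = pca_Y.scores.shape[0]
    W = (pca_Y.loadings.to_numpy(dtype=float) * pca_Y.singular_values) @ model.V_M[:, : model.l]
    score = (W**2).sum(axis=1) / n
    return pd.Series(score, index=pca_Y.feature_ids, name="score")


def empirical_p(observed: np.ndarray, null_scores: np.ndarray) -> np.ndarray:
    """p = #{null > observed} / #null — the strict-exceedance permutation p-value.

    A gene whose observed score beats every permuted score gets p = 0 under
    this convention.
    """
    observed = np.atleast_1d(np.asarray(observed, dtype=float))
    null_scores = np.atleast_2d(np.asarray(null_scores, dtype=float))
    return (null_scores > observed[None, :]).sum(axis=0) / null_scores.shape[0]


def permutation_test(
    expr,
    scores_x,
    pca_Y: PCADecomposition,
    l: int = 2,
    n_perm: int = 100_000,
    seed: int = 0,
    exhaustive: bool = False,
    pseudocount: bool = False,
) -> pd.DataFrame:
    """Permutation significance of per-gene projection variance.

    Each iteration jointly permutes the rows of the genotype score matrix
    (keeping its columns' mutual structure), refits the k x j SVD coupling,
    and recomputes all gene scores. Per-iteration RNG streams are derived
    from the master seed via counter-based spawning, so results are
    reproducible regardless of execution order.

    Returns a table with ``score``, ``p_value`` (strict exceedance; see
    ``pseudocount`` for the (c+1)/(n+1) variant) and ``z_score``
    ((observed - null mean) / null sd).
    """
    Ux_df = _scores_frame(scores_x)
    Ux = Ux_df.to_numpy(dtype=float)
    if not Ux_df.index.equals(pca_Y.sample_ids):
        raise ValueError("sample ids/order differ between genotype scores and expression PCA")
    Uy = pca_Y.scores.to_numpy(dtype=float)
    Lsig = pca_Y.loadings.to_numpy(dtype=float) * pca_Y.singular_values
    _gene_variances(expr)  # validates standardization
    n, k = Ux.shape

    def scores_for(Ux_rows: np.ndarray) -> np.ndarray:
        M = Ux_rows.T @ Uy
        _, _, Vmt = np.linalg.svd(M, full_matrices=False)
        W = Lsig @ Vmt[:l].T
        return (W**2).sum(axis=1) / n

    observed = scores_for(Ux)

    if exhaustive:
        if n > 8:
            raise ValueError("exhaustive enumeration is limited to n <= 8 samples")
        perms = [np.asarray(p) for p in itertools.permutations(range(n))]
        n_perm = len(perms)
    else:
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        perms = None

    count = np.zeros(len(observed))
    total = np.zeros(len(observed))
    total_sq = np.zeros(len(observed))
    for t in range(n_perm):
        if exhaustive:
            perm = perms[t]
        else:
            rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(t,)))
            perm = rng.permutation(n)
        sp = scores_for(Ux[perm])
        count += sp > observed
        total += sp
        total_sq += sp * sp

    if pseudocount:
        p = (count + 1.0) / (n_perm + 1.0)
    else:
        p = count / n_perm
    mean = total / n_perm
    if n_perm > 1:
        sd = np.sqrt(np.clip((total_sq - n_perm * mean**2) / (n_perm - 1), 0.0, None))
    else:
        sd = np.full_like(mean, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (observed - mean) / sd
    return pd.DataFrame(
        {"score": observed, "p_value": p, "z_score": z},
        index=pca_Y.feature_ids.rename("gene_id"),
    )


def bhy_adjust(p_values, fdr: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg–Yekutieli adjustment, valid under arbitrary dependence.

    adjusted_(i) = min_{j >= i} min(1, m c(m) p_(j) / j) with the harmonic
    penalty c(m) = sum_{i=1..m} 1/i. Returns (adjusted, significant) where
    significance means adjusted <= fdr.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m * c_m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    return adjusted, adjusted <= fdr


def score_significance(
    expr,
    scores_x,
    pca_Y: PCADecomposition,
    l: int = 2,
    n_perm: int = 100_000,
    seed: int = 0,
    fdr: float = 0.05,
    pseudocount: bool = False,
) -> pd.DataFrame:
    """Full gene score table: score, permutation p, z, BHY-adjusted p, flag.

    Sorted by score descending.
    """
    table = permutation_test(
        expr, scores_x, pca_Y, l=l, n_perm=n_perm, seed=seed, pseudocount=pseudocount
    )
    adjusted, significant = bhy_adjust(table["p_value"].to_numpy(), fdr=fdr)
    table["p_adjusted"] = adjusted
    table["significant"] = significant
    return table.sort_values("score", ascending=False)
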