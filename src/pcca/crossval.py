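"""Leave-one-out cross-validation of the whole PCCA fit.

Every fold refits everything the model learns from data — quantile
reference (when the input is raw TPM), per-feature centering and scaling,
both PCAs and the CCA coupling — on n - 1 samples, then maps the held-out
individual through the training statistics. Reconstruction error is, by
default, measured in projection space: when the canonical correlations are
near 1 a sample's expression-side coordinates should agree with its
genotype-side coordinates, so the per-sample error is the squared distance
between the two l-vectors. An alternative mode reconstructs the
standardized expression vector from its l-dimensional projection instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GenotypeMatrix
from .pcca_core import pca, pcca_fit, project_new_sample
from .preprocess import map_to_quantile_reference, quantile_normalize, quantile_reference


@dataclass
class CrossValReport:
    """Per-sample held-out coordinates and errors plus the two mean errors."""

    records: pd.DataFrame
    train_error: float
    test_error: float


def reconstruction_error(original: np.ndarray, reconstructed: np.ndarray) -> float:
    """Squared Frobenius norm of the difference, per row (so train/test compare)."""
    a = np.atleast_2d(np.asarray(original, dtype=float))
    b = np.atleast_2d(np.asarray(reconstructed, dtype=float))
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.sum((a - b) ** 2) / a.shape[0])


def loo_crossvalidate(
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    k: int = 5,
    j: int = 30,
    l: int = 2,
    reconstruction: str = "projection",
    populations: Optional[pd.Series] = None,
) -> CrossValReport:
    """Hold out each sample in turn, refit, and project it into the model.

    When ``expr.state == "tpm"`` the quantile-normalization reference is
    rebuilt per fold from training samples only and the held-out sample is
    mapped through that training reference. ``populations`` (a Series
    indexed by sample id) additionally records, per fold, which population
    training centroid the held-out expression coordinates land nearest —
    computed within the fold so coordinate sign/rotation differences between
    folds cannot leak in. Folds run in a fixed deterministic order.
    """
    if reconstruction not in ("projection", "expression"):
        raise ValueError("reconstruction must be 'projection' or 'expression'")
    if not expr.sample_ids.equals(geno.sample_ids):
        raise ValueError("expression and genotype matrices must share sample ids and order")
    if geno.has_missing():
        raise ValueError("impute missing genotypes before cross-validation")
    n = expr.n_samples
    if n < max(k, j) + 2:
        raise ValueError(f"need at least max(k, j) + 2 = {max(k, j) + 2} samples, got {n}")
    if populations is not None:
        populations = populations.reindex(expr.sample_ids)
        if populations.isna().any():
            raise ValueError("populations does not cover every sample")

    rows = []
    fold_train_errors = []
    for sid in expr.sample_ids:
        tr_expr = expr.values.drop(index=sid)
        ho_expr = expr.values.loc[sid]
        tr_geno = geno.values.drop(index=sid)
        ho_geno = geno.values.loc[sid]

        if expr.state == "tpm":
            qn = quantile_normalize(ExpressionMatrix(tr_expr, "tpm"))
            reference = quantile_reference(tr_expr.to_numpy(dtype=float))
            tr_expr = qn.values
            ho_expr = map_to_quantile_reference(ho_expr, reference)

        pX = pca(tr_geno, k, center=True, scale=True)
        pY = pca(tr_expr, j, center=True, scale=True)
        model = pcca_fit(pX.scores, pY.scores, l)
        c_x, c_y = project_new_sample(model, pX, pY, ho_expr, ho_geno)

        if reconstruction == "projection":
            e_train = reconstruction_error(model.C_Y.to_numpy(), model.C_X.to_numpy())
            e_test = float(np.sum((c_y - c_x) ** 2))
        else:
            e_train = _expression_train_error(model, pY, tr_expr)
            e_test = _expression_test_error(model, pY, ho_expr, c_y)
        fold_train_errors.append(e_train)

        row = {"sample_id": sid, "error": e_test, "fold_train_error": e_train}
        for d in range(l):
            row[f"cx{d + 1}"] = c_x[d]
            row[f"cy{d + 1}"] = c_y[d]
        if populations is not None:
            centroids = model.C_Y.groupby(populations.drop(index=sid)).mean()
            dists = np.linalg.norm(centroids.to_numpy() - c_y[None, :], axis=1)
            row["nearest_population"] = centroids.index[int(np.argmin(dists))]
        rows.append(row)

    records = pd.DataFrame(rows).set_index("sample_id")
    return CrossValReport(
        records=records,
        train_error=float(np.mean(fold_train_errors)),
        test_error=float(records["error"].mean()),
    )


def _standardize_like_pca(pY, values: np.ndarray) -> np.ndarray:
    out = values - pY.center.to_numpy()
    if pY.scale is not None:
        out = out / pY.scale.to_numpy()
    return out


def _expression_train_error(model, pY, tr_expr: pd.DataFrame) -> float:
    Xstd = _standardize_like_pca(pY, tr_expr.to_numpy(dtype=float))
    Uhat = model.C_Y.to_numpy() @ model.V_M[:, : model.l].T
    Xhat = (Uhat * pY.singular_values) @ pY.loadings.to_numpy().T
    return reconstruction_error(Xstd, Xhat)


def _expression_test_error(model, pY, ho_expr: pd.Series, c_y: np.ndarray) -> float:
    x = _standardize_like_pca(pY, ho_expr.reindex(pY.feature_ids).to_numpy(dtype=float))
    u_hat = c_y @ model.V_M[:, : model.l].T
    x_hat = (u_hat * pY.singular_values) @ pY.loadings.to_numpy().T
    return float(np.sum((x - x_hat) ** 2))
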