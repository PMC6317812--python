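"""PCA, the PCCA coupling, naive full CCA and projection utilities.

The coupling is deliberately simple: take orthonormal PC score matrices
U_X (n x k, genotype) and U_Y (n x j, expression) over the same samples,
form M = U_X' U_Y, and take its SVD M = U_M diag(rho) V_M'. The singular
values are the canonical correlations of the two score sets, and the sample
coordinates are C_X = U_X U_M[:, :l] and C_Y = U_Y V_M[:, :l]. Because the
score matrices are orthonormal they are their own whitening, so no
covariance inversion — the step that makes full-feature CCA overfit when
features outnumber samples — is ever needed.

All singular vectors follow one sign convention: each column is flipped so
its largest-magnitude entry is positive, which keeps outputs stable across
runs and backends.
"""

from __future__ import annotations

import warnings
from typing import Optional, Union

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GenotypeMatrix, PCADecomposition, PCCAModel

#: defaults used throughout: genotype PCs, expression PCs, canonical pairs
DEFAULT_K = 5
DEFAULT_J = 30
DEFAULT_L = 2

_PINV_RTOL = 1e-10


def _fix_signs(U: np.ndarray, V: Optional[np.ndarray] = None) -> tuple:
    """Flip each column of U (and the matching column of V) so the
    largest-magnitude entry of the U column is positive."""
    U = U.copy()
    V = None if V is None else V.copy()
    for col in range(U.shape[1]):
        idx = int(np.argmax(np.abs(U[:, col])))
        if U[idx, col] < 0:
            U[:, col] *= -1
            if V is not None:
                V[:, col] *= -1
    return (U, V) if V is not None else (U, None)


def _as_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, (ExpressionMatrix, GenotypeMatrix)):
        return matrix.values
    if isinstance(matrix, PCADecomposition):
        return matrix.scores
    if isinstance(matrix, pd.DataFrame):
        return matrix
    return pd.DataFrame(np.asarray(matrix, dtype=float))


# ---------------------------------------------------------------------------
# PCA


def pca(
    matrix,
    k: int,
    center: bool = True,
    scale: bool = False,
) -> PCADecomposition:
    """Top-k SVD of a (centered, optionally scaled) samples x features matrix.

    When features outnumber samples the decomposition goes through the n x n
    Gram matrix; both routes agree to numerical precision after sign fixing.
    Scores are the left singular vectors (orthonormal columns).
    """
    df = _as_frame(matrix)
    X = df.to_numpy(dtype=float)
    n, p = X.shape
    kmax = min(n - 1 if center else n, p)
    if k > kmax:
        raise ValueError(f"k={k} exceeds achievable maximum {kmax} for a {n} x {p} matrix")
    mu = X.mean(axis=0) if center else np.zeros(p)
    Xc = X - mu
    if scale:
        sd = Xc.std(axis=0, ddof=0)
        if np.any(sd < 1e-12):
            bad = df.columns[sd < 1e-12].tolist()[:10]
            raise ValueError(f"constant features cannot be scaled: {bad}")
        Xc = Xc / sd
        scale_series = pd.Series(sd, index=df.columns)
    else:
        scale_series = None

    if p > n:
        G = Xc @ Xc.T
        w, V = np.linalg.eigh(G)
        order = np.argsort(w)[::-1][:k]
        sv = np.sqrt(np.clip(w[order], 0.0, None))
        U = V[:, order]
        with np.errstate(divide="ignore", invalid="ignore"):
            L = Xc.T @ U / np.where(sv > 0, sv, np.inf)
    else:
        U, sv, Vt = np.linalg.svd(Xc, full_matrices=False)
        U, L = U[:, :k], Vt[:k].T
        sv = sv[:k]
    U, L = _fix_signs(U, L)
    pcs = [f"PC{i + 1}" for i in range(k)]
    return PCADecomposition(
        scores=pd.DataFrame(U, index=df.index, columns=pcs),
        singular_values=np.asarray(sv, dtype=float),
        loadings=pd.DataFrame(L, index=df.columns, columns=pcs),
        center=pd.Series(mu, index=df.columns),
        scale=scale_series,
    )


# ---------------------------------------------------------------------------
# PCCA


def _scores_frame(scores) -> pd.DataFrame:
    if isinstance(scores, PCADecomposition):
        return scores.scores
    if isinstance(scores, pd.DataFrame):
        return scores
    return pd.DataFrame(np.asarray(scores, dtype=float))


def _check_orthonormal(U: np.ndarray, name: str, tol: float = 1e-6) -> None:
    gram = U.T @ U
    if np.max(np.abs(gram - np.eye(U.shape[1]))) > tol:
        raise ValueError(f"{name} does not have orthonormal columns (required for PCCA)")


def pcca_fit(scores_x, scores_y, l: int = DEFAULT_L) -> PCCAModel:
    """Couple two orthonormal PC score matrices by the SVD of their cross-product.

    Samples are matched by id (an order mismatch is an error, never silently
    reindexed). Canonical correlations ``rho`` come back clipped to [0, 1]
    and non-increasing; a tie between adjacent correlations leaves the
    within-block ordering arbitrary and triggers a warning.
    """
    Ux_df = _scores_frame(scores_x)
    Uy_df = _scores_frame(scores_y)
    if not Ux_df.index.equals(Uy_df.index):
        raise ValueError(
            "sample ids/order differ between the two score matrices; "
            "align them by sample_id before fitting"
        )
    Ux = Ux_df.to_numpy(dtype=float)
    Uy = Uy_df.to_numpy(dtype=float)
    _check_orthonormal(Ux, "genotype scores")
    _check_orthonormal(Uy, "expression scores")
    k, j = Ux.shape[1], Uy.shape[1]
    if l > min(k, j):
        raise ValueError(f"l={l} exceeds min(k={k}, j={j})")

    M = Ux.T @ Uy
    Um, s, Vmt = np.linalg.svd(M, full_matrices=False)
    Vm = Vmt.T
    Um, Vm = _fix_signs(Um, Vm)
    rho = np.clip(s, 0.0, 1.0)
    if np.any(np.abs(np.diff(rho)) < 1e-12):
        warnings.warn(
            "tied canonical correlations: the within-block ordering is arbitrary",
            stacklevel=2,
        )
    cols = [f"cca{i + 1}" for i in range(l)]
    C_X = pd.DataFrame(Ux @ Um[:, :l], index=Ux_df.index, columns=cols)
    C_Y = pd.DataFrame(Uy @ Vm[:, :l], index=Uy_df.index, columns=cols)
    return PCCAModel(rho=rho, U_M=Um, V_M=Vm, C_X=C_X, C_Y=C_Y, k=k, j=j, l=l)


def full_cca(
    X, Y, l: int, ridge: float = 0.0
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Canonical correlation analysis on the raw feature matrices.

    Columns are centered, each matrix is whitened through the pseudoinverse
    square root of its covariance (singular values below 1e-10 x sigma_max
    treated as zero) and the canonical correlations are the singular values
    of the whitened cross-product. ``ridge`` > 0 adds ridge to the covariance
    eigenvalues, shrinking the whitening toward the identity.

    With more columns than samples and ridge=0 this is the textbook
    overfitting pathology: the leading correlations are exactly 1.
    """
    X = np.asarray(_as_frame(X).to_numpy(dtype=float))
    Y = np.asarray(_as_frame(Y).to_numpy(dtype=float))
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of samples")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    Ux, sx, _ = np.linalg.svd(Xc, full_matrices=False)
    Uy, sy, _ = np.linalg.svd(Yc, full_matrices=False)
    if ridge < 0:
        raise ValueError("ridge must be nonnegative")
    if ridge == 0:
        kx = sx > _PINV_RTOL * sx[0]
        ky = sy > _PINV_RTOL * sy[0]
        Wx, Wy = Ux[:, kx], Uy[:, ky]
        if l > min(Wx.shape[1], Wy.shape[1]):
            raise ValueError(
                f"l={l} exceeds the {min(Wx.shape[1], Wy.shape[1])} usable directions "
                "(rank collapse with ridge=0)"
            )
    else:
        Wx = Ux * (sx / np.sqrt(sx**2 + ridge))
        Wy = Uy * (sy / np.sqrt(sy**2 + ridge))
    Um, s, Vmt = np.linalg.svd(Wx.T @ Wy, full_matrices=False)
    rho = np.clip(s, 0.0, 1.0)
    Um, Vm = _fix_signs(Um, Vmt.T)
    Zx = Wx @ Um[:, :l]
    Zy = Wy @ Vm[:, :l]
    return rho, (Zx, Zy)


def project_new_sample(
    model: PCCAModel,
    pca_X: PCADecomposition,
    pca_Y: PCADecomposition,
    new_expr: pd.Series,
    new_geno: pd.Series,
) -> tuple[np.ndarray, np.ndarray]:
    """Map a held-out sample into the fitted coordinates of both sides.

    The new vectors are centered/scaled with the TRAINING statistics, mapped
    to PC scores via loadings and singular values (u = x L diag(1/sigma)),
    then rotated by U_M (genotype) / V_M (expression). Returns (c_x, c_y),
    each of length l.
    """
    u_x = _project_to_scores(pca_X, new_geno)
    u_y = _project_to_scores(pca_Y, new_expr)
    c_x = u_x @ model.U_M[:, : model.l]
    c_y = u_y @ model.V_M[:, : model.l]
    return c_x, c_y


def _project_to_scores(decomp: PCADecomposition, x: pd.Series) -> np.ndarray:
    feats = decomp.feature_ids
    missing = feats.difference(x.index)
    if len(missing):
        raise ValueError(f"new sample lacks training features: {missing.tolist()[:10]}")
    v = x.reindex(feats).to_numpy(dtype=float) - decomp.center.to_numpy()
    if decomp.scale is not None:
        v = v / decomp.scale.to_numpy()
    u = v @ decomp.loadings.to_numpy()
    sv = decomp.singular_values
    with np.errstate(divide="ignore"):
        return u / np.where(sv > 0, sv, np.inf)


def regression_link(scores_x, scores_y, l: int = DEFAULT_L) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Alternative coupling: regress U_X on U_Y and decompose the fitted values.

    Returns ``(coords, fitted)`` where ``fitted`` is the projection of the
    genotype scores onto the expression-score column space and ``coords``
    holds the top-l SVD coordinates of the fitted values (left singular
    vectors scaled by singular values) — an expression-side projection that
    closely matches the PCCA coordinates.
    """
    Ux_df = _scores_frame(scores_x)
    Uy_df = _scores_frame(scores_y)
    if not Ux_df.index.equals(Uy_df.index):
        raise ValueError("sample ids/order differ between the two score matrices")
    Ux = Ux_df.to_numpy(dtype=float)
    Uy = Uy_df.to_numpy(dtype=float)
    _check_orthonormal(Uy, "expression scores")
    if l > min(Ux.shape[1], Uy.shape[1]):
        raise ValueError("l exceeds the available dimensions")
    fitted = Uy @ (Uy.T @ Ux)
    U, s, _ = np.linalg.svd(fitted, full_matrices=False)
    U, _ = _fix_signs(U)
    coords = pd.DataFrame(
        U[:, :l] * s[:l],
        index=Ux_df.index,
        columns=[f"reg{i + 1}" for i in range(l)],
    )
    fitted_df = pd.DataFrame(fitted, index=Ux_df.index, columns=Ux_df.columns)
    return coords, fitted_df


def variance_explained_curve(matrix) -> np.ndarray:
    """Cumulative fraction of variance explained per component count (elbow curve)."""
    X = _as_frame(matrix).to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    s = np.linalg.svd(Xc, compute_uv=False)
    total = float(np.sum(s**2))
    if total == 0:
        raise ValueError("matrix has no variance")
    frac = np.cumsum(s**2) / total
    return frac[s > _PINV_RTOL * s[0]]


def subsample_features(matrix, p: float, seed: Union[int, np.random.Generator]):
    """Keep each feature independently with probability ``p`` (for the
    few-SNPs / few-genes robustness experiments)."""
    if not (0 < p <= 1):
        raise ValueError("inclusion probability must be in (0, 1]")
    df = _as_frame(matrix)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    keep = rng.random(df.shape[1]) < p
    if not keep.any():
        raise ValueError("subsampling kept zero features; increase p")
    kept = df.columns[keep]
    sub = df.loc[:, kept]
    if isinstance(matrix, ExpressionMatrix):
        return ExpressionMatrix(sub, matrix.state), list(kept)
    if isinstance(matrix, GenotypeMatrix):
        return GenotypeMatrix(sub), list(kept)
    return sub, list(kept)
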