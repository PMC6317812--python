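"""In-memory containers shared across the package.

Matrices are pandas DataFrames oriented samples x features throughout; all
joins between genotype, expression and metadata are done by sample id, never
by row position.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

EXPRESSION_STATES = ("tpm", "quantile_normalized", "standardized", "residualized")


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dups[:10]}")


@dataclass
class ExpressionMatrix:
    """Samples x genes (or transcripts) expression matrix.

    ``state`` tracks where the matrix sits in the normalization pipeline:
    raw TPM, quantile-normalized, standardized (per-gene mean 0 / variance 1)
    or residualized against confounders.
    """

    values: pd.DataFrame
    state: str = "tpm"

    def __post_init__(self) -> None:
        if self.state not in EXPRESSION_STATES:
            raise ValueError(
                f"unknown expression state {self.state!r}; expected one of {EXPRESSION_STATES}"
            )
        _check_unique(self.values.index, "sample ids")
        _check_unique(self.values.columns, "feature ids")

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.state)


@dataclass
class GenotypeMatrix:
    """Samples x SNPs dosage matrix.

    Dosage counts the VCF ALT allele (0/1/2); missing genotypes are NaN until
    imputation. Minor-allele frequency is derived downstream as
    ``min(p, 1 - p)`` with ``p = mean(dosage) / 2``.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "sample ids")
        _check_unique(self.values.columns, "snp ids")

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def snp_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def has_missing(self) -> bool:
        return bool(self.values.isna().any().any())

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.values.copy())


@dataclass
class ConfounderMatrix:
    """Samples x q design matrix of known confounders.

    Under the default encoding the columns are one indicator per batch level
    plus one binary gender column, so q = n_batches + 1.
    """

    values: pd.DataFrame
    batch_columns: list = field(default_factory=list)

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index


@dataclass
class PCADecomposition:
    """Thin SVD of a centered (optionally scaled) data matrix.

    ``scores`` holds the left singular vectors (n x k, orthonormal columns),
    ``loadings`` the right singular vectors (features x k), and
    ``singular_values`` the non-increasing singular values. ``center`` and
    ``scale`` record the per-feature statistics applied before the SVD so new
    samples can be mapped into the same coordinate system.
    """

    scores: pd.DataFrame
    singular_values: np.ndarray
    loadings: pd.DataFrame
    center: pd.Series
    scale: Optional[pd.Series] = None

    @property
    def k(self) -> int:
        return self.scores.shape[1]

    @property
    def sample_ids(self) -> pd.Index:
        return self.scores.index

    @property
    def feature_ids(self) -> pd.Index:
        return self.loadings.index


@dataclass
class PCCAModel:
    """CCA coupling of two orthonormal PC score matrices.

    With U_X (n x k genotype scores) and U_Y (n x j expression scores), the
    model is the SVD of M = U_X' U_Y: canonical correlations ``rho``,
    rotations ``U_M`` (k x min(k,j)) and ``V_M`` (j x min(k,j)), and sample
    coordinates C_X = U_X U_M[:, :l], C_Y = U_Y V_M[:, :l].
    """

    rho: np.ndarray
    U_M: np.ndarray
    V_M: np.ndarray
    C_X: pd.DataFrame
    C_Y: pd.DataFrame
    k: int
    j: int
    l: int

    def to_dict(self) -> dict:
        return {
            "rho": self.rho.tolist(),
            "U_M": self.U_M.tolist(),
            "V_M": self.V_M.tolist(),
            "C_X": {"index": self.C_X.index.tolist(), "values": self.C_X.to_numpy().tolist()},
            "C_Y": {"index": self.C_Y.index.tolist(), "values": self.C_Y.to_numpy().tolist()},
            "k": self.k,
            "j": self.j,
            "l": self.l,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "PCCAModel":
        cols = [f"cca{i + 1}" for i in range(d["l"])]
        return cls(
            rho=np.asarray(d["rho"], dtype=float),
            U_M=np.asarray(d["U_M"], dtype=float),
            V_M=np.asarray(d["V_M"], dtype=float),
            C_X=pd.DataFrame(d["C_X"]["values"], index=d["C_X"]["index"], columns=cols),
            C_Y=pd.DataFrame(d["C_Y"]["values"], index=d["C_Y"]["index"], columns=cols),
            k=d["k"],
            j=d["j"],
            l=d["l"],
        )

    @classmethod
    def from_json(cls, path) -> "PCCAModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
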