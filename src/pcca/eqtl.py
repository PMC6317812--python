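"""eQTL-effect removal and covariate-aware cis-eQTL scanning.

Two roles. First, given an external eQTL summary table (lead SNP correlation
r_g and allele frequencies per population), convert the correlation to a
standardized-scale effect beta_g = r_g / sqrt(2 f_a (1 - f_a)), subtract the
per-population expected mean 2 beta_g f_k from each e-gene, re-standardize,
and let the caller re-project — the check that known cis-eQTLs are not what
drives the population structure. Second, a plain OLS cis scan (gene on
[intercept | dosage | covariates], SNPs within a closed 1 Mb TSS window,
MAF >= 0.05) used to compare covariate strategies: genotype PCs versus PCCA
coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, GenotypeMatrix
from .preprocess import _norm_chrom, impute_missing_genotypes, snp_maf, standardize_genes

DEFAULT_CIS_WINDOW = 1_000_000


@dataclass
class EqtlEffectRecord:
    """One external eQTL record: gene, lead SNP, correlation, frequencies."""

    gene_id: str
    snp_id: str
    r_g: float
    f_a: float
    f_k: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if abs(self.r_g) > 1:
            raise ValueError(f"|r_g| > 1 for gene {self.gene_id}")
        for f in (self.f_a, *self.f_k.values()):
            if not (0 < f < 1):
                raise ValueError(f"allele frequencies must lie in (0, 1); got {f}")

    @property
    def beta_g(self) -> float:
        return derive_effect(self.r_g, self.f_a)

    def y_gk(self) -> dict[str, float]:
        """Expected population mean expression 2 beta_g f_k per population."""
        b = self.beta_g
        return {pop: 2.0 * b * f for pop, f in self.f_k.items()}


def derive_effect(r_g: float, f_a: float) -> float:
    """Standardized effect size from a genotype-expression correlation.

    For unit-variance expression and a dosage with variance 2 f (1 - f) under
    Hardy-Weinberg, the regression slope is beta = r / sqrt(2 f (1 - f)).
    """
    if not (0 < f_a < 1):
        raise ValueError("allele frequency must lie strictly inside (0, 1)")
    return r_g / np.sqrt(2.0 * f_a * (1.0 - f_a))


def remove_population_means(
    expr: ExpressionMatrix,
    records: Sequence[EqtlEffectRecord],
    populations: pd.Series,
) -> ExpressionMatrix:
    """Subtract each e-gene's expected per-population mean, then re-standardize.

    Every sample in population k has y_gk = 2 beta_g f_k subtracted from gene
    g. Records for genes absent from the matrix are skipped with a warning;
    an unlabeled sample is an error.
    """
    if expr.state != "standardized":
        raise ValueError("remove_population_means expects a standardized expression matrix")
    populations = populations.reindex(expr.sample_ids)
    if populations.isna().any():
        bad = expr.sample_ids[populations.isna()].tolist()[:10]
        raise ValueError(f"samples without a population label: {bad}")
    V = expr.values.copy()
    pops_present = set(populations.unique())
    for rec in records:
        if rec.gene_id not in V.columns:
            warnings.warn(f"eQTL record for absent gene {rec.gene_id!r}; skipping", stacklevel=2)
            continue
        missing_pops = pops_present - set(rec.f_k)
        if missing_pops:
            raise ValueError(
                f"record for gene {rec.gene_id} lacks frequencies for populations {sorted(missing_pops)}"
            )
        shift = populations.map(rec.y_gk()).astype(float)
        V[rec.gene_id] = V[rec.gene_id] - shift
    return standardize_genes(ExpressionMatrix(V, "standardized"))


def dedupe_records(records: Sequence[EqtlEffectRecord]) -> list[EqtlEffectRecord]:
    """One record per gene; when a gene appears in several population-level
    tables, the record with the larger |r_g| wins."""
    best: dict[str, EqtlEffectRecord] = {}
    for rec in records:
        cur = best.get(rec.gene_id)
        if cur is None or abs(rec.r_g) > abs(cur.r_g):
            best[rec.gene_id] = rec
    return list(best.values())


# ---------------------------------------------------------------------------
# cis scan


def select_cis_pairs(
    gene_annotation: pd.DataFrame,
    snp_annotation: pd.DataFrame,
    window: int = DEFAULT_CIS_WINDOW,
    maf_min: float = 0.05,
    genotypes: Optional[GenotypeMatrix] = None,
) -> dict[str, list[str]]:
    """Pair each gene with SNPs on the same chromosome within ``window`` bp of
    its TSS (closed interval at the boundary) and MAF >= ``maf_min``.

    MAF comes from ``genotypes`` when given, otherwise from a ``maf`` column
    in the SNP annotation.
    """
    snps = snp_annotation.copy()
    if genotypes is not None:
        maf = snp_maf(genotypes)
        snps = snps.loc[snps.index.intersection(maf.index)]
        snps["maf"] = maf.reindex(snps.index)
    elif "maf" not in snps.columns:
        raise ValueError("supply genotypes or a 'maf' column in the SNP annotation")
    snps = snps[snps["maf"] >= maf_min]
    snps = snps.assign(_chrom=snps["chromosome"].map(_norm_chrom))

    pairs: dict[str, list[str]] = {}
    by_chrom = {c: g.sort_values("position") for c, g in snps.groupby("_chrom")}
    for gene_id, row in gene_annotation.iterrows():
        chrom = _norm_chrom(row["chromosome"])
        tss = int(row["tss"])
        group = by_chrom.get(chrom)
        if group is None:
            pairs[gene_id] = []
            continue
        pos = group["position"].to_numpy()
        lo = np.searchsorted(pos, tss - window, side="left")
        hi = np.searchsorted(pos, tss + window, side="right")
        pairs[gene_id] = group.index[lo:hi].tolist()
    return pairs


def cis_scan(
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    pairs: Mapping[str, Sequence[str]],
    covariates: Optional[pd.DataFrame] = None,
    strategy: str = "pc",
) -> pd.DataFrame:
    """OLS of each gene on each cis SNP with fixed covariates.

    Per pair: gene ~ [intercept | dosage | covariates]; the t statistic is on
    the dosage coefficient with n - c - 2 degrees of freedom. Dosages are
    used in raw 0/1/2 coding (mean-imputed when missing).
    """
    geno = impute_missing_genotypes(geno)
    if not expr.sample_ids.equals(geno.sample_ids):
        raise ValueError("expression and genotype matrices must share sample ids and order")
    n = expr.n_samples
    if covariates is not None:
        C = covariates.reindex(expr.sample_ids)
        if C.isna().any().any():
            raise ValueError("covariate matrix does not cover all samples")
        C = C.to_numpy(dtype=float)
    else:
        C = np.empty((n, 0))
    c = C.shape[1]
    df_resid = n - c - 2
    if df_resid <= 0:
        raise ValueError(f"need n > c + 2 samples (n={n}, c={c})")

    rows = []
    ones = np.ones(n)
    for gene_id, snp_ids in pairs.items():
        if gene_id not in expr.values.columns:
            continue
        y = expr.values[gene_id].to_numpy(dtype=float)
        for snp_id in snp_ids:
            g = geno.values[snp_id].to_numpy(dtype=float)
            D = np.column_stack([ones, g, C])
            DtD = D.T @ D
            try:
                DtD_inv = np.linalg.inv(DtD)
            except np.linalg.LinAlgError:
                DtD_inv = np.linalg.pinv(DtD)
            beta = DtD_inv @ (D.T @ y)
            resid = y - D @ beta
            sigma2 = float(resid @ resid) / df_resid
            se = float(np.sqrt(sigma2 * DtD_inv[1, 1]))
            t = beta[1] / se if se > 0 else np.inf * np.sign(beta[1])
            p = 2.0 * stats.t.sf(abs(t), df_resid)
            rows.append(
                {
                    "gene_id": gene_id,
                    "snp_id": snp_id,
                    "beta": beta[1],
                    "se": se,
                    "t_stat": t,
                    "p_value": p,
                    "n_used": n,
                    "strategy": strategy,
                }
            )
    return pd.DataFrame(
        rows, columns=["gene_id", "snp_id", "beta", "se", "t_stat", "p_value", "n_used", "strategy"]
    )


def count_egenes(results: pd.DataFrame, alpha: float) -> int:
    """Number of genes whose minimum nominal cis p-value is <= alpha."""
    if results.empty:
        return 0
    min_p = results.groupby("gene_id")["p_value"].min()
    return int((min_p <= alpha).sum())


@dataclass
class StrategyComparison:
    shared: set
    pc_only: set
    pcca_only: set

    @property
    def counts(self) -> dict[str, int]:
        return {
            "shared": len(self.shared),
            "pc_only": len(self.pc_only),
            "pcca_only": len(self.pcca_only),
        }


def compare_strategies(
    results_pc: pd.DataFrame, results_pcca: pd.DataFrame, alpha: float
) -> StrategyComparison:
    """Partition eGenes at ``alpha`` into shared / PC-only / PCCA-only sets."""
    universe_pc = set(results_pc["gene_id"])
    universe_pcca = set(results_pcca["gene_id"])
    if universe_pc != universe_pcca:
        raise ValueError("the two scans were run on different gene universes")
    eg_pc = _egene_set(results_pc, alpha)
    eg_pcca = _egene_set(results_pcca, alpha)
    return StrategyComparison(
        shared=eg_pc & eg_pcca,
        pc_only=eg_pc - eg_pcca,
        pcca_only=eg_pcca - eg_pc,
    )


def _egene_set(results: pd.DataFrame, alpha: float) -> set:
    min_p = results.groupby("gene_id")["p_value"].min()
    return set(min_p.index[min_p <= alpha])


def qq_points(p_values) -> tuple[np.ndarray, np.ndarray]:
    """Sorted (-log10 expected-uniform, -log10 observed) pairs for a Q-Q plot."""
    p = np.sort(np.asarray(p_values, dtype=float))
    m = p.size
    expected = (np.arange(1, m + 1) - 0.5) / m
    with np.errstate(divide="ignore"):
        return -np.log10(expected), -np.log10(np.clip(p, 1e-300, None))
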