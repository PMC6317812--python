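"""Synthetic genotype and expression data with recorded ground truth.

Genotypes follow the Balding–Nichols model: each SNP draws an ancestral
frequency p0 ~ Uniform(0.05, 0.95) and per-population frequencies from
Beta(p0 (1 - F) / F, (1 - p0) (1 - F) / F) with F the divergence (FST)
parameter; dosages are Binomial(2, p_k). Expression is built on a latent
standardized scale as population mean shift + batch shift + cis-genetic
dosage effect + Gaussian noise, then mapped onto a TPM-like positive scale
as tpm_scale * exp(log_dispersion * z) so the full normalization path
(quantile normalization, standardization) is exercised; the dispersion
factor keeps per-gene cross-sample variability in the range typical of
gene-level RNA-seq quantifications. Everything planted — population labels, batch
labels, shifted genes with their shift vectors, cis gene-SNP pairs — is
recorded in a :class:`SimulationTruth` so recovery can be checked exactly.

The generator emulates a multi-population RNA-seq cohort with lab batches
(four populations, a few labs, a minority of genes carrying population mean
shifts, a small set of cis-eQTLs). Default sizes are desk scale: a few
hundred samples, thousands of SNPs, hundreds of genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GenotypeMatrix


@dataclass
class SimulationConfig:
    n_populations: int = 4
    samples_per_population: int = 60
    n_snps: int = 3000
    fst: float = 0.1
    n_genes: int = 600
    frac_pop_genes: float = 0.1
    pop_effect_size: float = 0.8
    n_batches: int = 4
    batch_effect_size: float = 1.0
    cis_fraction: float = 0.05
    cis_beta: float = 0.5
    noise_sd: float = 1.0
    seed: int = 0
    tpm_scale: float = 30.0
    log_dispersion: float = 0.5
    n_chromosomes: int = 2
    snp_spacing: int = 5_000
    gene_spacing: int = 25_000

    def __post_init__(self) -> None:
        for name in ("frac_pop_genes", "cis_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if not (0 < self.fst < 1):
            raise ValueError("fst must lie in (0, 1)")
        for name in ("n_populations", "samples_per_population", "n_snps", "n_genes", "n_batches"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class SimulationTruth:
    ancestral_freqs: np.ndarray = field(default_factory=lambda: np.empty(0))
    pop_freqs: Optional[pd.DataFrame] = None  # populations x snps
    populations: Optional[pd.Series] = None
    batches: Optional[pd.Series] = None
    shifted_genes: dict = field(default_factory=dict)  # gene -> {pop: shift}
    cis_pairs: list = field(default_factory=list)  # (gene_id, snp_id, beta)
    gender: Optional[pd.Series] = None


@dataclass
class SimulatedDataset:
    genotypes: GenotypeMatrix
    snp_annotation: pd.DataFrame
    expression: ExpressionMatrix
    gene_annotation: pd.DataFrame
    metadata: pd.DataFrame
    truth: SimulationTruth
    config: SimulationConfig


def _positions(n: int, n_chromosomes: int, spacing: int) -> tuple[np.ndarray, np.ndarray]:
    chroms = np.array([str(1 + i % n_chromosomes) for i in range(n)])
    pos = np.empty(n, dtype=int)
    for c in np.unique(chroms):
        mask = chroms == c
        pos[mask] = spacing * (1 + np.arange(mask.sum()))
    return chroms, pos


def simulate_genotypes(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame, SimulationTruth]:
    """Balding–Nichols genotypes for ``n_populations`` diverged populations."""
    rng = np.random.default_rng(config.seed)
    F = config.fst
    p0 = rng.uniform(0.05, 0.95, config.n_snps)
    a = p0 * (1.0 - F) / F
    b = (1.0 - p0) * (1.0 - F) / F
    pk = rng.beta(a, b, size=(config.n_populations, config.n_snps))
    degenerate = ~np.isfinite(pk) | (pk <= 0.0) | (pk >= 1.0)
    for _ in range(5):
        if not degenerate.any():
            break
        warnings.warn(
            f"resampling {int(degenerate.sum())} degenerate Beta draws", stacklevel=2
        )
        resampled = rng.beta(
            np.broadcast_to(a, pk.shape)[degenerate],
            np.broadcast_to(b, pk.shape)[degenerate],
        )
        pk[degenerate] = resampled
        degenerate = ~np.isfinite(pk) | (pk <= 0.0) | (pk >= 1.0)
    pk = np.clip(pk, 1e-6, 1.0 - 1e-6)

    pops = [f"pop{i + 1}" for i in range(config.n_populations)]
    sample_ids = []
    pop_labels = []
    dosage_blocks = []
    for i, pop in enumerate(pops):
        n_k = config.samples_per_population
        sample_ids.extend(f"{pop}_s{s + 1:03d}" for s in range(n_k))
        pop_labels.extend([pop] * n_k)
        dosage_blocks.append(rng.binomial(2, pk[i], size=(n_k, config.n_snps)))

    snp_ids = [f"snp{i + 1:06d}" for i in range(config.n_snps)]
    chroms, positions = _positions(config.n_snps, config.n_chromosomes, config.snp_spacing)
    annotation = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chromosome": chroms,
            "position": positions,
            "ref": "A",
            "alt": "G",
            "is_biallelic_snp": True,
        }
    ).set_index("snp_id", drop=False)

    index = pd.Index(sample_ids, name="sample_id")
    geno = GenotypeMatrix(
        pd.DataFrame(np.vstack(dosage_blocks).astype(float), index=index, columns=snp_ids)
    )
    truth = SimulationTruth(
        ancestral_freqs=p0,
        pop_freqs=pd.DataFrame(pk, index=pops, columns=snp_ids),
        populations=pd.Series(pop_labels, index=index, name="population"),
    )
    return geno, annotation, truth


def _centered_unit_rms(raw: np.ndarray) -> np.ndarray:
    """Center a shift vector and scale it to unit root-mean-square."""
    v = raw - raw.mean()
    rms = np.sqrt(np.mean(v**2))
    return v / rms if rms > 0 else v


def simulate_expression(
    genotypes: GenotypeMatrix,
    truth: SimulationTruth,
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, SimulationTruth]:
    """Expression on a TPM-like scale with planted population, batch and cis effects.

    Population shifts are drawn per shifted gene as a centered vector over
    populations scaled to root-mean-square ``pop_effect_size`` (so the
    planted between-population spread is exactly the stated effect size in
    noise-sd units); batch shifts are N(0, batch_effect_size) per
    gene-by-batch cell; cis genes add ``cis_beta`` x dosage of their nearest
    SNP. Values are emitted as tpm_scale * exp(log_dispersion * z); truth
    records the latent (pre-transform) quantities. Uses a dedicated RNG
    stream so genotypes are reproducible on their own.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(1,)))
    n = genotypes.n_samples
    if truth.populations is None or not genotypes.sample_ids.equals(truth.populations.index):
        raise ValueError("truth/genotypes mismatch: simulate genotypes first")
    gene_ids = [f"gene{i + 1:05d}" for i in range(config.n_genes)]
    chroms, tss = _positions(config.n_genes, config.n_chromosomes, config.gene_spacing)
    gene_annotation = pd.DataFrame(
        {"gene_id": gene_ids, "chromosome": chroms, "tss": tss, "strand": "+"}
    ).set_index("gene_id", drop=False)

    batches = pd.Series(
        [f"lab{rng.integers(config.n_batches) + 1}" for _ in range(n)],
        index=genotypes.sample_ids,
        name="batch",
    )
    gender = pd.Series(
        np.where(rng.random(n) < 0.5, "female", "male"),
        index=genotypes.sample_ids,
        name="gender",
    )

    Z = rng.normal(0.0, config.noise_sd, size=(n, config.n_genes))
    pops = list(truth.pop_freqs.index)
    pop_idx = truth.populations.map({p: i for i, p in enumerate(pops)}).to_numpy()

    n_shifted = int(round(config.frac_pop_genes * config.n_genes))
    shifted = rng.choice(config.n_genes, size=n_shifted, replace=False) if n_shifted else np.array([], dtype=int)
    shifted_genes = {}
    if config.pop_effect_size > 0:
        for gi in shifted:
            shift = config.pop_effect_size * _centered_unit_rms(rng.normal(size=len(pops)))
            Z[:, gi] += shift[pop_idx]
            shifted_genes[gene_ids[gi]] = dict(zip(pops, shift))

    if config.batch_effect_size > 0 and config.n_batches > 1:
        batch_levels = sorted(batches.unique())
        batch_idx = batches.map({b: i for i, b in enumerate(batch_levels)}).to_numpy()
        batch_shift = rng.normal(0.0, config.batch_effect_size, size=(len(batch_levels), config.n_genes))
        Z += batch_shift[batch_idx, :]

    cis_pairs = []
    n_cis = int(round(config.cis_fraction * config.n_genes))
    if n_cis:
        non_shifted = np.setdiff1d(np.arange(config.n_genes), shifted)
        pool = non_shifted if len(non_shifted) >= n_cis else np.arange(config.n_genes)
        cis_genes = rng.choice(pool, size=n_cis, replace=False)
        cis_pairs = _plant_cis(Z, cis_genes, gene_annotation, genotypes, config, gene_ids)
    truth = replace(
        truth,
        batches=batches,
        shifted_genes=shifted_genes,
        cis_pairs=cis_pairs,
        gender=gender,
    )

    tpm = config.tpm_scale * np.exp(config.log_dispersion * Z)
    expr = ExpressionMatrix(
        pd.DataFrame(tpm, index=genotypes.sample_ids, columns=gene_ids), "tpm"
    )
    return expr, gene_annotation, truth


def _plant_cis(Z, cis_genes, gene_annotation, genotypes, config, gene_ids):
    """Add cis effects in place; each cis gene uses the SNP nearest its TSS."""
    snp_meta_chroms, snp_meta_pos = _positions(
        config.n_snps, config.n_chromosomes, config.snp_spacing
    )
    snp_ids = np.asarray(genotypes.snp_ids)
    pairs = []
    for gi in cis_genes:
        gene_id = gene_ids[gi]
        chrom = gene_annotation.loc[gene_id, "chromosome"]
        tss = gene_annotation.loc[gene_id, "tss"]
        mask = snp_meta_chroms == chrom
        if not mask.any():
            continue
        cand_pos = snp_meta_pos[mask]
        cand_ids = snp_ids[mask]
        snp_id = cand_ids[int(np.argmin(np.abs(cand_pos - tss)))]
        dosage = genotypes.values[snp_id].to_numpy(dtype=float)
        Z[:, gi] += config.cis_beta * dosage
        pairs.append((gene_id, snp_id, config.cis_beta))
    return pairs


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Full bundle: genotypes, expression, annotations, metadata, ground truth."""
    geno, snp_ann, truth = simulate_genotypes(config)
    expr, gene_ann, truth = simulate_expression(geno, truth, config)
    metadata = pd.DataFrame(
        {
            "sample_id": geno.sample_ids,
            "population": truth.populations.to_numpy(),
            "batch": truth.batches.to_numpy(),
            "gender": truth.gender.to_numpy(),
        },
        index=pd.Index(geno.sample_ids, name="sample_id"),
    )
    return SimulatedDataset(geno, snp_ann, expr, gene_ann, metadata, truth, config)


def emit_eqtl_summary(
    truth: SimulationTruth,
    genotypes: GenotypeMatrix,
    expr,
) -> list:
    """Realized summary records for the planted cis pairs.

    Computes the realized genotype-expression correlation r_g on the
    supplied expression matrix (pass the standardized matrix for records
    destined for :func:`pcca.eqtl.remove_population_means`) and the realized
    overall (f_a) and per-population (f_k) dosage frequencies.
    """
    from .eqtl import EqtlEffectRecord

    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    records = []
    for gene_id, snp_id, _beta in truth.cis_pairs:
        dosage = genotypes.values[snp_id]
        y = values[gene_id]
        r = float(np.corrcoef(dosage.to_numpy(dtype=float), y.to_numpy(dtype=float))[0, 1])
        f_a = float(dosage.mean() / 2.0)
        f_k = {
            pop: float(dosage[truth.populations == pop].mean() / 2.0)
            for pop in truth.pop_freqs.index
        }
        records.append(
            EqtlEffectRecord(
                gene_id=gene_id,
                snp_id=snp_id,
                r_g=float(np.clip(r, -1.0, 1.0)),
                f_a=float(np.clip(f_a, 1e-9, 1 - 1e-9)),
                f_k={p: float(np.clip(f, 1e-9, 1 - 1e-9)) for p, f in f_k.items()},
            )
        )
    return records
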