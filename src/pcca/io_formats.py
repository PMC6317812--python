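"""Readers and writers for the external formats the pipeline touches.

Genotypes come from VCF (via cyvcf2) or a plain samples x SNPs dosage TSV;
expression, metadata, annotations and result tables are TSV. Output tables
carry ``#``-prefixed comment headers recording version, seed and parameters,
which the readers skip. No numerics live here.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GenotypeMatrix

logger = logging.getLogger("pcca")

_SAMPLE_ROW_NAMES = {"sample_id", "sample", "samples"}
_FEATURE_ROW_NAMES = {"gene_id", "gene", "transcript_id", "transcript", "feature_id", "snp_id"}

_SINGLE_NT = {"A", "C", "G", "T"}


def _check_header_duplicates(path) -> None:
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            seen = set()
            dups = [f for f in fields if f in seen or seen.add(f)]
            if dups:
                raise ValueError(f"duplicate column ids in {path}: {dups[:10]}")
            return


# ---------------------------------------------------------------------------
# genotypes


def read_genotypes_vcf(
    path, samples: Optional[Sequence[str]] = None
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read a VCF into a dosage matrix plus a SNP annotation table.

    Dosage is the count of ALT alleles per sample; missing genotypes become
    NaN. Multi-allelic records and indels are read, not dropped, and flagged
    ``is_biallelic_snp=False`` in the annotation so downstream filters can
    act on them.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    available = list(vcf.samples)
    if samples is not None:
        missing = [s for s in samples if s not in available]
        if missing:
            raise ValueError(f"sample ids not present in VCF: {missing}")
        vcf.set_samples(list(samples))
    sample_ids = list(vcf.samples)

    dosages = []
    ann_rows = []
    seen = set()
    for var in vcf:
        snp_id = var.ID or f"{var.CHROM}:{var.POS}:{var.REF}:{','.join(var.ALT)}"
        if snp_id in seen:
            raise ValueError(f"duplicate variant id {snp_id!r} in {path}")
        seen.add(snp_id)
        alt = ",".join(var.ALT)
        biallelic = (
            len(var.ALT) == 1
            and var.REF in _SINGLE_NT
            and var.ALT[0] in _SINGLE_NT
        )
        ann_rows.append(
            {
                "snp_id": snp_id,
                "chromosome": var.CHROM,
                "position": var.POS,
                "ref": var.REF,
                "alt": alt,
                "is_biallelic_snp": biallelic,
            }
        )
        # gts012: 0/1/2 = ALT count, 3 = missing
        gt = np.asarray(var.gt_types, dtype=float)
        gt[gt == 3] = np.nan
        dosages.append(gt)

    if not ann_rows:
        raise ValueError(f"no variant records found in {path}")
    annotation = pd.DataFrame(ann_rows).set_index("snp_id", drop=False)
    values = pd.DataFrame(
        np.vstack(dosages).T, index=pd.Index(sample_ids, name="sample_id"),
        columns=annotation.index,
    )
    return GenotypeMatrix(values), annotation


def write_genotypes_vcf(
    geno: GenotypeMatrix, annotation: pd.DataFrame, path, header_comments: Iterable[str] = ()
) -> None:
    """Write dosages back to a minimal VCF 4.2 (0->0/0, 1->0/1, 2->1/1, NaN->./.)."""
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in header_comments:
            fh.write(f"##{c}\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in annotation["chromosome"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.sample_ids)
            + "\n"
        )
        values = geno.values
        for snp_id in values.columns:
            row = annotation.loc[snp_id]
            calls = [
                gt_map.get(v, "./.") if not np.isnan(v) else "./."
                for v in values[snp_id].to_numpy(dtype=float)
            ]
            fh.write(
                f"{row['chromosome']}\t{int(row['position'])}\t{snp_id}\t"
                f"{row['ref']}\t{row['alt']}\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def read_genotypes_tsv(path) -> GenotypeMatrix:
    """Read a samples x SNPs dosage TSV (first column sample ids, NaN = missing)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index.name = "sample_id"
    return GenotypeMatrix(df.astype(float))


def write_genotypes_tsv(geno: GenotypeMatrix, path, header_comments: Iterable[str] = ()) -> None:
    _write_table(geno.values, path, header_comments, index_label="sample_id")


# ---------------------------------------------------------------------------
# expression


def read_expression_tsv(path, state: str = "tpm") -> ExpressionMatrix:
    """Read an expression TSV, auto-orienting to samples x features.

    Orientation is detected from the first header token: ``sample_id`` means
    samples are rows; ``gene_id`` / ``transcript_id`` mean features are rows
    (the matrix is transposed on read). Duplicate feature ids and non-numeric
    cells are errors.
    """
    _check_header_duplicates(path)
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate row ids in {path}: {dups[:10]}")
    label = (df.index.name or "").strip().lower()
    if label in _FEATURE_ROW_NAMES:
        df = df.T
        df.index.name = "sample_id"
        df.columns.name = None
    elif label in _SAMPLE_ROW_NAMES or label == "":
        df.index.name = "sample_id"
    else:
        logger.warning(
            "expression TSV index label %r not recognized; assuming samples x features", label
        )
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise ValueError(f"non-numeric expression value at row {row!r}, column {col!r}")
        df[col] = coerced
    return ExpressionMatrix(df.astype(float), state)


def write_expression_tsv(
    expr: ExpressionMatrix, path, header_comments: Iterable[str] = ()
) -> None:
    comments = list(header_comments) + [f"state={expr.state}"]
    _write_table(expr.values, path, comments, index_label="sample_id")


# ---------------------------------------------------------------------------
# metadata / annotations


def read_sample_metadata(path) -> pd.DataFrame:
    """Sample metadata TSV with columns sample_id, population, batch, gender."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"sample_id", "population", "batch", "gender"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample metadata missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in metadata")
    return df.set_index("sample_id", drop=False)


def read_gene_annotation(path) -> pd.DataFrame:
    """Gene annotation TSV with columns gene_id, chromosome, tss[, strand]."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str, "chromosome": str})
    required = {"gene_id", "chromosome", "tss"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene annotation missing columns: {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        raise ValueError("duplicate gene_id in annotation")
    df["tss"] = df["tss"].astype(int)
    if (df["tss"] < 1).any():
        raise ValueError("tss positions are 1-based and must be >= 1")
    return df.set_index("gene_id", drop=False)


def read_snp_annotation(path) -> pd.DataFrame:
    """SNP annotation TSV: snp_id, chromosome, position, ref, alt, is_biallelic_snp."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"snp_id": str, "chromosome": str})
    required = {"snp_id", "chromosome", "position"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"snp annotation missing columns: {sorted(missing)}")
    if df["snp_id"].duplicated().any():
        raise ValueError("duplicate snp_id in annotation")
    df["position"] = df["position"].astype(int)
    if "is_biallelic_snp" not in df.columns:
        df["is_biallelic_snp"] = True
    else:
        df["is_biallelic_snp"] = df["is_biallelic_snp"].astype(str).str.lower().isin(
            {"true", "1", "t", "yes"}
        )
    return df.set_index("snp_id", drop=False)


def read_tx2gene(path) -> pd.Series:
    """Two-column TSV mapping transcript_id -> gene_id."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("tx2gene map needs two columns: transcript_id, gene_id")
    tx, gene = df.columns[:2]
    if df[tx].duplicated().any():
        raise ValueError("duplicate transcript ids in tx2gene map")
    return pd.Series(df[gene].to_numpy(), index=df[tx].to_numpy(), name="gene_id")


# ---------------------------------------------------------------------------
# results


def write_results(table: pd.DataFrame, path, header_comments: Iterable[str] = ()) -> None:
    """Write a result table (gene scores, eQTL results, projections) as TSV.

    Column order is the table's own, floats carry >= 6 significant digits and
    the header rows record run provenance. An empty table is an error rather
    than an empty file.
    """
    if table.shape[0] == 0:
        raise ValueError("refusing to write an empty result table")
    _write_table(table, path, header_comments, index_label=table.index.name)


def read_results(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def _write_table(df: pd.DataFrame, path, header_comments: Iterable[str], index_label=None) -> None:
    with open(path, "w") as fh:
        for c in header_comments:
            fh.write(f"# {c}\n")
        df.to_csv(fh, sep="\t", float_format="%.10g", index_label=index_label)


def provenance_header(seed=None, **params) -> list[str]:
    from . import __version__

    items = [f"pcca version={__version__}"]
    if seed is not None:
        items.append(f"seed={seed}")
    items.extend(f"{k}={v}" for k, v in params.items())
    return items
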