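"""Readers and validators for the pipeline's file formats.

Formats are deliberately plain: GT-only VCF for genotypes, tab-separated
tables for counts/metadata/allele-specific reads, one-gene-per-line panel
lists. Variant ids are CHROM:POS:REF:ALT (1-based positions). Validation is
strict and names the offending rows, since silent coercion upstream of a
statistical pipeline is how cohorts go wrong.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from ._utils import LAYERS

__all__ = [
    "read_vcf_genotypes",
    "read_counts_tsv",
    "read_metadata_tsv",
    "read_allelic_counts_tsv",
    "read_gene_list",
]

# cyvcf2 gt_types codes: HOM_REF=0, HET=1, UNKNOWN=2, HOM_ALT=3
_GT_CODE = {0: 0, 1: 1, 2: -1, 3: 2}


def read_vcf_genotypes(path: str | Path) -> pd.DataFrame:
    """0/1/2 genotype table (variants x samples) from a GT-only VCF.

    Missing genotypes are coded -1. Multi-allelic records are skipped with a
    warning; a malformed file raises with the record number reached.
    """
    path = str(path)
    try:
        vcf = VCF(path)
        samples = list(vcf.samples)
        ids, rows = [], []
        for i, var in enumerate(vcf, start=1):
            if len(var.ALT) != 1:
                warnings.warn(
                    f"{path}: skipping multi-allelic record {i} ({var.CHROM}:{var.POS})",
                    stacklevel=2,
                )
                continue
            ids.append(f"{var.CHROM}:{var.POS}:{var.REF}:{var.ALT[0]}")
            rows.append([_GT_CODE[g] for g in var.gt_types])
    except Exception as err:  # noqa: BLE001 - htslib raises bare Exceptions
        raise ValueError(f"malformed VCF {path}: {err}") from err
    return pd.DataFrame(np.asarray(rows, dtype=np.int8), index=ids, columns=samples)


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Gene x sample integer count matrix (first column gene_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"{path}: duplicate gene ids {dupes}")
    if df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        frac, _ = np.modf(df.to_numpy(float))
        if np.nanmax(np.abs(frac)) > 0:
            bad = df.index[np.abs(frac).max(axis=1) > 0].tolist()[:5]
            raise ValueError(f"{path}: non-integer counts in rows {bad}")
        df = df.astype(np.int64)
    if (df.to_numpy() < 0).any():
        bad = df.index[(df < 0).any(axis=1)].tolist()[:5]
        raise ValueError(f"{path}: negative counts in rows {bad}")
    return df


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    """Sample metadata with layer/population/sex validation."""
    df = pd.read_csv(path, sep="\t", na_values=["."])
    required = {"sample_id", "pair_id", "population", "infant_sex", "layer"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()[:5]
        raise ValueError(f"{path}: duplicate sample ids {dupes}")
    bad_layers = set(df["layer"]) - set(LAYERS)
    if bad_layers:
        raise ValueError(f"{path}: unknown layer labels {sorted(bad_layers)}")
    for col in ("population", "infant_sex"):
        levels = df[col].dropna().unique()
        if len(levels) > 2:
            raise ValueError(f"{path}: {col} must be binary, got {sorted(levels)}")
    return df


def read_allelic_counts_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "variant_id", "a_count", "b_count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if (df[["a_count", "b_count"]].to_numpy() < 0).any():
        raise ValueError(f"{path}: negative read counts")
    return df


def read_gene_list(path: str | Path) -> list:
    """One gene id per line; blank lines and #-comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    if len(out) != len(set(out)):
        raise ValueError(f"{path}: duplicate gene ids in list")
    return out
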