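"""Readers and writers for the plain-text formats the tool consumes.

Formats (all TSV unless noted):
  z-scores   — header ``snp_id\tz``
  LD         — whitespace-delimited square numeric matrix, row order matching
               the z-score table
  genotypes  — samples x SNPs with a header row of SNP ids, or the PLINK
               ``.raw`` additive dialect (FID IID PAT MAT SEX PHENOTYPE then
               one column per SNP)
  phenotype  — two columns: sample_id, value
  gene map   — chrom, tss, gene_id (optionally a fourth strand column);
               coordinates are 1-based
  variants   — id, chrom, pos, z
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError, ParseError
from .locus import LocusData

_PLINK_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def read_zscores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"snp_id", "z"}.issubset(df.columns):
        raise ParseError(f"{path}: expected columns snp_id and z")
    df["z"] = pd.to_numeric(df["z"], errors="raise")
    return df[["snp_id", "z"]]


def write_zscores(df: pd.DataFrame, path: str | Path) -> None:
    df[["snp_id", "z"]].to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_ld(path: str | Path) -> np.ndarray:
    mat = np.loadtxt(path)
    if mat.ndim == 0:
        mat = mat.reshape(1, 1)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ParseError(f"{path}: LD matrix must be square, got {mat.shape}")
    return mat


def write_ld(ld: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(ld, dtype=float), fmt="%.17g")


def read_locus(zscore_path: str | Path, ld_path: str | Path) -> LocusData:
    z = read_zscores(zscore_path)
    ld = read_ld(ld_path)
    if ld.shape[0] != len(z):
        raise InvalidInputError(
            f"LD matrix is {ld.shape[0]}x{ld.shape[0]} but z table has {len(z)} SNPs"
        )
    return LocusData(snp_ids=z["snp_id"].tolist(), stats=z["z"].to_numpy(), ld=ld)


def read_genotypes(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a genotype TSV or PLINK .raw file; returns (raw dosages, snp ids)."""
    path = Path(path)
    df = pd.read_csv(path, sep=r"\s+" if path.suffix == ".raw" else "\t")
    if list(df.columns[: len(_PLINK_META)]) == _PLINK_META:
        snp_cols = list(df.columns[len(_PLINK_META):])
        values = df[snp_cols].to_numpy(dtype=float)
        # strip the _A allele suffix of the .raw dialect
        ids = [c.rsplit("_", 1)[0] if "_" in c else c for c in snp_cols]
        return values, ids
    return df.to_numpy(dtype=float), list(df.columns)


def read_phenotype(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: phenotype file needs sample_id and value columns")
    df = df.iloc[:, :2]
    df.columns = ["sample_id", "value"]
    df["value"] = pd.to_numeric(df["value"], errors="raise")
    return df


def read_gene_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "tss", "gene_id"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: gene map needs columns {sorted(required)}")
    df["tss"] = pd.to_numeric(df["tss"], errors="raise").astype(int)
    if (df["tss"] < 1).any():
        raise ParseError(f"{path}: tss positions must be 1-based (>= 1)")
    if df["gene_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate gene_id entries")
    return df


def read_variant_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"id", "chrom", "pos", "z"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: variant table needs columns {sorted(required)}")
    try:
        df["pos"] = pd.to_numeric(df["pos"], errors="raise").astype(int)
        df["z"] = pd.to_numeric(df["z"], errors="raise")
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{path}: malformed numeric column ({exc})") from exc
    if (df["pos"] < 1).any():
        bad = int(df.index[df["pos"] < 1][0]) + 2  # 1-based line, after header
        raise ParseError(f"{path}: non-positive position at line {bad}")
    return df
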