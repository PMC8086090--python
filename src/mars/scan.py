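"""Multi-locus scan driver with null-panel caching.

A scan walks a gene map, assembles the cis window of each gene (variants
within a symmetric window of the TSS), computes the locus LRT and its
empirical p against a null panel.  Panels are keyed by the LD checksum, so a
panel built for a locus in one trait or tissue is reused for the same variant
set in another — and refused, with regeneration, when the variants differ.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .locus import LocusData
from .model import ModelParams, lrt_statistic
from .sampling import (
    NullPanel,
    build_null_panel,
    ld_checksum,
    read_panel,
    significance_test,
    write_panel,
)

logger = logging.getLogger("mars.scan")


@dataclass
class GeneMapEntry:
    """One gene anchor: identifier, chromosome, 1-based TSS position."""

    gene_id: str
    chrom: str
    tss: int
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.tss < 1:
            raise InvalidInputError(f"{self.gene_id}: tss must be >= 1 (1-based)")


@dataclass
class ScanResult:
    """Per-locus rows plus run metadata."""

    table: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        import json

        path = Path(path)
        self.table.to_csv(path, sep="\t", index=False, float_format="%.17g")
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(self.meta, indent=2, default=str) + "\n"
        )

    @classmethod
    def read(cls, path: str | Path) -> "ScanResult":
        import json

        path = Path(path)
        table = pd.read_csv(path, sep="\t", float_precision="round_trip")
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(table=table, meta=meta)


def assemble_locus(gene: GeneMapEntry, variants: pd.DataFrame,
                   ld: np.ndarray | None = None,
                   window: int = 1_000_000,
                   min_snps: int = 50,
                   exclusive_min: bool = False):
    """Select the cis variants of a gene; optionally attach LD.

    Variants on ``gene.chrom`` with |pos - tss| <= window (closed interval,
    1-based coordinates) are kept.  Loci with fewer than ``min_snps`` SNPs
    (strictly fewer, or <= when ``exclusive_min`` demands more than min_snps)
    are skipped, returning None.  When ``ld`` is given it must be square over
    the full ``variants`` table, row order matching; the sub-matrix of the
    selected variants is attached and a LocusData returned.  Without ``ld``
    the selected sub-table is returned.
    """
    mask = (variants["chrom"].astype(str) == str(gene.chrom)) & (
        (variants["pos"] - gene.tss).abs() <= window
    )
    sub = variants.loc[mask]
    m = len(sub)
    too_small = m <= min_snps if exclusive_min else m < min_snps
    if too_small:
        logger.info(
            "skipping %s: %d cis SNPs (< required %d%s)",
            gene.gene_id, m, min_snps, " exclusive" if exclusive_min else "",
        )
        return None
    if ld is None:
        return sub.reset_index(drop=True)
    ld = np.asarray(ld, dtype=float)
    if ld.shape[0] != len(variants):
        raise InvalidInputError(
            "ld must cover the full variant table (row order matching)"
        )
    idx = np.flatnonzero(mask.to_numpy())
    return LocusData(
        snp_ids=sub["id"].astype(str).tolist(),
        stats=sub["z"].to_numpy(dtype=float),
        ld=ld[np.ix_(idx, idx)],
    )


class PanelCache:
    """In-memory + on-disk cache of null panels keyed by (gene, LD checksum)."""

    def __init__(self, directory: str | Path | None = None):
        self.directory = Path(directory) if directory is not None else None
        if self.directory is not None:
            self.directory.mkdir(parents=True, exist_ok=True)
        self._mem: dict[tuple[str, str], NullPanel] = {}

    def _path(self, gene_id: str) -> Path | None:
        if self.directory is None:
            return None
        return self.directory / f"{gene_id}.panel.tsv"

    def get(self, gene_id: str, checksum: str) -> NullPanel | None:
        panel = self._mem.get((gene_id, checksum))
        if panel is not None:
            return panel
        path = self._path(gene_id)
        if path is not None and path.exists():
            panel = read_panel(path)
            if panel.ld_checksum == checksum:
                self._mem[(gene_id, checksum)] = panel
                return panel
            logger.warning(
                "cached panel for %s was built on different variants; regenerating",
                gene_id,
            )
        return None

    def put(self, gene_id: str, panel: NullPanel) -> None:
        self._mem[(gene_id, panel.ld_checksum)] = panel
        path = self._path(gene_id)
        if path is not None:
            write_panel(panel, path)


def scan(gene_map: pd.DataFrame, variant_tables: dict[str, pd.DataFrame],
         ld_by_gene: dict[str, np.ndarray], params: ModelParams | None = None,
         K: int = 1000, seed: int = 0, alpha: float = 5e-8,
         window: int = 1_000_000, min_snps: int = 50,
         exclusive_min: bool = False, importance: bool = False,
         panel_dir: str | Path | None = None, bh_correct: bool = False,
         ) -> ScanResult:
    """Score every (trait/tissue, gene) pair, reusing null panels where valid.

    ``variant_tables`` maps a trait or tissue name to its variant table;
    ``ld_by_gene`` maps gene_id to the LD matrix over that gene's cis window
    (identical variant sets across traits are the panel-reuse precondition).
    ``bh_correct`` adds a Benjamini-Hochberg q-value column across all scanned
    loci (a deviation from empirical-FDR bordering, clearly optional).
    """
    params = params or ModelParams()
    cache = PanelCache(panel_dir)
    rng = np.random.default_rng(seed)
    rows = []
    for _, g in gene_map.iterrows():
        gene = GeneMapEntry(gene_id=str(g["gene_id"]), chrom=str(g["chrom"]),
                            tss=int(g["tss"]), strand=g.get("strand"))
        for trait, variants in variant_tables.items():
            sub = assemble_locus(gene, variants, window=window,
                                 min_snps=min_snps, exclusive_min=exclusive_min)
            if sub is None:
                continue
            gene_ld = ld_by_gene.get(gene.gene_id)
            if gene_ld is None:
                logger.warning("no LD matrix for %s; skipping", gene.gene_id)
                continue
            gene_ld = np.asarray(gene_ld, dtype=float)
            if gene_ld.shape[0] != len(sub):
                raise InvalidInputError(
                    f"{gene.gene_id}: LD matrix is {gene_ld.shape[0]}x"
                    f"{gene_ld.shape[0]} but the cis window holds {len(sub)} SNPs"
                )
            locus = LocusData(snp_ids=sub["id"].astype(str).tolist(),
                              stats=sub["z"].to_numpy(dtype=float), ld=gene_ld)
            checksum = ld_checksum(locus.ld)
            panel = cache.get(gene.gene_id, checksum)
            if panel is None:
                panel_seed = int(rng.integers(2**31 - 1))
                panel = build_null_panel(ld=locus.ld, K=K, seed=panel_seed,
                                         params=params, importance=importance)
                cache.put(gene.gene_id, panel)
            else:
                logger.info("panel cache hit for %s (%s)", gene.gene_id, trait)
            res = lrt_statistic(locus, params)
            sig = significance_test(res.lrt_stat, panel, alpha=alpha,
                                    expected_checksum=checksum)
            rows.append({
                "trait": trait,
                "gene_id": gene.gene_id,
                "m_total": locus.m,
                "m_used": len(res.selected_indices),
                "lrt_stat": res.lrt_stat,
                "p_value": sig.p_value,
                "significant": sig.significant,
            })
    table = pd.DataFrame(rows, columns=["trait", "gene_id", "m_total", "m_used",
                                        "lrt_stat", "p_value", "significant"])
    if bh_correct and len(table):
        from statsmodels.stats.multitest import multipletests

        table["q_value"] = multipletests(table["p_value"], method="fdr_bh")[1]
    meta = {
        "params": params.to_dict(),
        "seed": int(seed),
        "K": int(K),
        "alpha": float(alpha),
        "window": int(window),
        "min_snps": int(min_snps),
        "exclusive_min": bool(exclusive_min),
        "importance": bool(importance),
    }
    return ScanResult(table=table, meta=meta)
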