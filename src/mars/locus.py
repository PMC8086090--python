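"""Locus containers: per-SNP z-scores plus the LD (correlation) matrix.

The summary statistic of SNP i is marginally N(lambda_i, 1) and the vector of
statistics for a locus has covariance equal to the genotype correlation matrix
Sigma, so a locus is fully described by (snp_ids, z, Sigma).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError

_SYM_TOL = 1e-10
_DIAG_TOL = 1e-10
_CORR_TOL = 1e-10


@dataclass
class LocusData:
    """Summary statistics and LD for one locus.

    Parameters
    ----------
    snp_ids : list of str
        Unique variant identifiers, in locus order.
    stats : (m,) array
        Marginal association z-scores S = [s_1 .. s_m].
    ld : (m, m) array
        Pairwise genotype correlation matrix Sigma (unit diagonal, symmetric);
        this is also the covariance of ``stats`` under the model.
    """

    snp_ids: list[str]
    stats: np.ndarray
    ld: np.ndarray

    def __post_init__(self) -> None:
        self.stats = np.asarray(self.stats, dtype=float).reshape(-1)
        self.ld = np.asarray(self.ld, dtype=float)
        m = self.stats.shape[0]
        self.snp_ids = list(self.snp_ids)
        if len(self.snp_ids) != m:
            raise InvalidInputError(
                f"snp_ids has length {len(self.snp_ids)} but stats has length {m}"
            )
        if len(set(self.snp_ids)) != m:
            raise InvalidInputError("snp_ids must be unique")
        if self.ld.shape != (m, m):
            raise InvalidInputError(f"ld has shape {self.ld.shape}, expected {(m, m)}")
        if m == 0:
            raise InvalidInputError("empty locus")
        if not np.all(np.isfinite(self.stats)) or not np.all(np.isfinite(self.ld)):
            raise InvalidInputError("non-finite values in locus data")
        if np.max(np.abs(self.ld - self.ld.T)) > _SYM_TOL:
            raise InvalidInputError("ld matrix is not symmetric")
        if np.max(np.abs(np.diag(self.ld) - 1.0)) > _DIAG_TOL:
            raise InvalidInputError("ld matrix diagonal must be 1")
        if np.max(np.abs(self.ld)) > 1.0 + _CORR_TOL:
            raise InvalidInputError("ld entries must satisfy |r| <= 1")

    @property
    def m(self) -> int:
        """Number of SNPs in the locus."""
        return self.stats.shape[0]

    def subset(self, indices: np.ndarray) -> "LocusData":
        """Restrict the locus to ``indices`` (order preserved as given)."""
        idx = np.asarray(indices, dtype=int)
        return LocusData(
            snp_ids=[self.snp_ids[i] for i in idx],
            stats=self.stats[idx],
            ld=self.ld[np.ix_(idx, idx)],
        )


def top_k_indices(stats: np.ndarray, k: int, by_abs: bool = True) -> np.ndarray:
    """Indices of the k strongest statistics, returned in original locus order.

    Ranking is by |z| (default) or by signed z; ties broken by original index
    (lower index ranks first), which a stable sort guarantees.
    """
    if k < 1:
        raise InvalidInputError("k must be >= 1")
    stats = np.asarray(stats, dtype=float)
    m = stats.shape[0]
    if m <= k:
        return np.arange(m)
    key = -np.abs(stats) if by_abs else -stats
    order = np.argsort(key, kind="stable")[:k]
    return np.sort(order)


def select_top_k(data: LocusData, k: int, by_abs: bool = True) -> LocusData:
    """Restrict a locus to its k SNPs with the strongest statistics.

    Large loci are truncated to the SNPs with largest |z| before configuration
    enumeration; the causal variants are expected to be among them, so the
    truncated likelihood ratio closely approximates the full one.
    """
    if data.m <= k:
        return data
    return data.subset(top_k_indices(data.stats, k, by_abs=by_abs))
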