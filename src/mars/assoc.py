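"""Marginal association statistics from individual-level data.

For each SNP i with standardized genotypes X_i (mean 0, variance 1, population
denominator, so X_i'X_i = n) and phenotype Y, the single-SNP model
Y = mu 1 + X_i beta_i + e gives

    beta_hat_i = X_i'Y / X_i'X_i,
    z_i = (beta_hat_i / sigma_e_hat_i) sqrt(X_i'X_i),

with the residual scale sigma_e_hat estimated per SNP with an n-2 denominator.
The non-centrality of z_i is lambda_i = (beta_i / sigma_e) sqrt(n), and the
z-score vector of a locus has covariance equal to the genotype correlation
matrix X'X / n.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError


@dataclass
class GenotypeMatrix:
    """Standardized dosage matrix (samples x SNPs)."""

    values: np.ndarray
    snp_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidInputError("genotype matrix must be 2-D (samples x SNPs)")
        if len(self.snp_ids) != self.values.shape[1]:
            raise InvalidInputError("snp_ids length must match column count")
        mu = self.values.mean(axis=0)
        var = self.values.var(axis=0)
        if np.max(np.abs(mu)) > 1e-8 or np.max(np.abs(var - 1.0)) > 1e-6:
            raise InvalidInputError(
                "columns must be standardized to mean 0, variance 1"
            )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]


@dataclass
class OLSFit:
    """Per-SNP single-variant regression summary."""

    snp_id: str
    beta_hat: float
    mu_hat: float
    resid: np.ndarray
    sigma_e_hat: float
    z: float
    ncp: float | None = None


def standardize(raw: np.ndarray, snp_ids: list[str] | None = None,
                missing: str = "impute") -> GenotypeMatrix:
    """Standardize a raw dosage matrix to column mean 0, variance 1.

    The population (n) denominator is used for the variance so that
    X_i'X_i = n exactly.  Missing dosages (NaN) are mean-imputed per SNP by
    default (``missing="impute"``), or the offending samples dropped listwise
    (``missing="drop"``).
    """
    x = np.array(raw, dtype=float, copy=True)
    if x.ndim == 1:
        x = x[:, None]
    n, m = x.shape
    ids = list(snp_ids) if snp_ids is not None else [f"snp{i}" for i in range(m)]
    if np.isnan(x).any():
        if missing == "drop":
            keep = ~np.isnan(x).any(axis=1)
            x = x[keep]
            n = x.shape[0]
        elif missing == "impute":
            col_mean = np.nanmean(x, axis=0)
            nan_r, nan_c = np.nonzero(np.isnan(x))
            x[nan_r, nan_c] = col_mean[nan_c]
        else:
            raise InvalidInputError(f"unknown missing-data policy {missing!r}")
    mu = x.mean(axis=0)
    sd = x.std(axis=0)  # population denominator
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise InvalidInputError(
            f"monomorphic SNP(s) cannot be standardized: {[ids[i] for i in zero]}"
        )
    return GenotypeMatrix(values=(x - mu) / sd, snp_ids=ids)


def marginal_stats(x: GenotypeMatrix, y: np.ndarray,
                   true_beta: np.ndarray | None = None,
                   true_sigma_e: float | None = None) -> list[OLSFit]:
    """Single-SNP OLS fits for every SNP of a locus.

    When the generating ``true_beta`` and ``true_sigma_e`` are known (in
    simulations) the non-centrality lambda_i = (beta_i/sigma_e) sqrt(n) is
    recorded on each fit.
    """
    y = np.asarray(y, dtype=float).reshape(-1)
    if y.shape[0] != x.n:
        raise InvalidInputError("phenotype length must equal sample count")
    if np.allclose(y, y[0]):
        raise InvalidInputError("phenotype is constant")
    n = x.n
    xv = x.values
    xty = xv.T @ y  # X_i'Y per SNP; X_i'X_i = n for standardized columns
    beta = xty / n
    mu_hat = float(y.mean())  # OLS intercept: columns are centred
    fits: list[OLSFit] = []
    for j, sid in enumerate(x.snp_ids):
        resid = y - mu_hat - beta[j] * xv[:, j]
        sigma_e = float(np.sqrt(resid @ resid / (n - 2)))
        z = float(beta[j] / sigma_e * np.sqrt(n))
        ncp = None
        if true_beta is not None and true_sigma_e is not None:
            ncp = float(np.asarray(true_beta)[j] / true_sigma_e * np.sqrt(n))
        fits.append(
            OLSFit(snp_id=sid, beta_hat=float(beta[j]), mu_hat=mu_hat,
                   resid=resid, sigma_e_hat=sigma_e, z=z, ncp=ncp)
        )
    return fits


def zscores(x: GenotypeMatrix, y: np.ndarray) -> np.ndarray:
    """z-score vector of a locus (vectorised fast path of marginal_stats)."""
    y = np.asarray(y, dtype=float).reshape(-1)
    if y.shape[0] != x.n:
        raise InvalidInputError("phenotype length must equal sample count")
    n = x.n
    beta = x.values.T @ y / n
    yc = y - y.mean()
    yty = yc @ yc
    # ||resid||^2 = ||y - ybar||^2 - n beta^2 for standardized, centred X
    rss = yty - n * beta**2
    sigma_e = np.sqrt(rss / (n - 2))
    return beta / sigma_e * np.sqrt(n)


def ld_from_genotypes(x: GenotypeMatrix) -> np.ndarray:
    """LD matrix Sigma = X'X / n of standardized genotypes."""
    sigma = x.values.T @ x.values / x.n
    sigma = 0.5 * (sigma + sigma.T)
    np.fill_diagonal(sigma, 1.0)
    return sigma


def univariate_test(stats: np.ndarray, null_max_stats: np.ndarray) -> float:
    """Empirical p of the locus max-|z| statistic against null maxima.

    Zero exceedances are floored at 1/K (the panel's resolution).
    """
    obs = float(np.max(np.abs(np.asarray(stats, dtype=float))))
    null_max = np.asarray(null_max_stats, dtype=float)
    k = null_max.shape[0]
    count = int(np.sum(null_max > obs))
    return max(count, 1) / k if count == 0 else count / k
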