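"""Synthetic loci and the type-I-error / power experiments.

Simulations operate on the summary-statistic scale wherever the model allows:
alternative draws are S ~ N(Sigma Lambda, Sigma) with Lambda carrying the
per-causal non-centrality lambda, exactly the generative model of the test.
Genotype-level generation (latent MVN thresholded at Hardy-Weinberg quantiles)
is provided for end-to-end checks that the summary route and the
individual-level route agree.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import CalibrationError, InvalidParameterError
from .model import ModelParams, lrt_panel
from .sampling import _ld_cholesky, sample_null_direct, univariate_pvalues


@dataclass
class AltSpec:
    """Non-centrality vector implanting causal effects.

    ``ncp`` is zero except at ``causal_indices`` where it equals ``lam``.
    """

    m: int
    causal_indices: np.ndarray
    lam: float

    def __post_init__(self) -> None:
        self.causal_indices = np.asarray(self.causal_indices, dtype=int).reshape(-1)
        if np.any(self.causal_indices < 0) or np.any(self.causal_indices >= self.m):
            raise InvalidParameterError("causal indices out of range")
        if len(set(self.causal_indices.tolist())) != self.causal_indices.size:
            raise InvalidParameterError("causal indices must be distinct")

    @property
    def ncp(self) -> np.ndarray:
        v = np.zeros(self.m)
        v[self.causal_indices] = self.lam
        return v


@dataclass
class PowerReport:
    """Power of the set test and the univariate baseline under one design."""

    power_mars: float
    power_uni: float
    improvement_pct: float
    lrt_threshold: float
    q: int
    n_reps: int
    alpha: float

    def to_dict(self) -> dict:
        return {
            "power_mars": self.power_mars,
            "power_uni": self.power_uni,
            "improvement_pct": self.improvement_pct,
            "lrt_threshold": self.lrt_threshold,
            "q": self.q,
            "n_reps": self.n_reps,
            "alpha": self.alpha,
        }


def gen_ld(m: int, structure: str = "ar1", rho: float = 0.5,
           block_size: int | None = None) -> np.ndarray:
    """Parametric LD matrix: AR(1) decay or equicorrelated blocks."""
    if not abs(rho) < 1.0:
        raise InvalidParameterError("|rho| must be < 1")
    if structure == "ar1":
        idx = np.arange(m)
        return rho ** np.abs(idx[:, None] - idx[None, :])
    if structure == "block":
        bs = block_size or m
        sigma = np.eye(m)
        for start in range(0, m, bs):
            stop = min(start + bs, m)
            sigma[start:stop, start:stop] = rho
        np.fill_diagonal(sigma, 1.0)
        return sigma
    raise InvalidParameterError(f"unknown LD structure {structure!r}")


def gen_genotypes(m: int, n: int, ld: np.ndarray,
                  maf_range: tuple[float, float] = (0.05, 0.5),
                  seed: int | np.random.Generator = 0) -> np.ndarray:
    """Raw dosage matrix with target LD, via thresholded latent Gaussians.

    Each sample's latent vector is MVN(0, ld); per SNP, a minor-allele
    frequency p is drawn uniformly from ``maf_range`` and the latent value cut
    at the Hardy-Weinberg genotype-frequency quantiles ((1-p)^2, then
    (1-p)^2 + 2p(1-p)) into dosages {0, 1, 2}.
    """
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise InvalidParameterError("maf_range must satisfy 0 < lo <= hi <= 0.5")
    rng = np.random.default_rng(seed)
    low = _ld_cholesky(np.asarray(ld, dtype=float))
    latent = rng.standard_normal((n, m)) @ low.T
    maf = rng.uniform(lo, hi, size=m)
    q0 = norm.ppf((1.0 - maf) ** 2)
    q1 = norm.ppf((1.0 - maf) ** 2 + 2.0 * maf * (1.0 - maf))
    return (latent > q0[None, :]).astype(float) + (latent > q1[None, :])


def genotypes_from_ld(ld: np.ndarray, n: int,
                      seed: int | np.random.Generator = 0) -> np.ndarray:
    """Synthetic standardized genotype matrix with X'X/n exactly equal to ld.

    Construction: an orthonormal basis of the complement of the ones vector is
    rotated onto the Cholesky factor of ld, so column means are 0, X'X/n = ld
    to machine precision.  This is a synthetic stand-in for real genotypes,
    useful for exercising the genotype-trick sampler at a prescribed LD.
    """
    ld = np.asarray(ld, dtype=float)
    m = ld.shape[0]
    if n < m + 1:
        raise InvalidParameterError("need n >= m + 1 samples")
    rng = np.random.default_rng(seed)
    g = rng.standard_normal((n, m))
    g -= g.mean(axis=0)  # orthogonal to the ones vector
    q, _ = np.linalg.qr(g)
    low = _ld_cholesky(ld)
    return np.sqrt(n) * q @ low.T


def sample_alt_stats(ld: np.ndarray, alt: AltSpec, K: int,
                     seed: int | np.random.Generator = 0) -> np.ndarray:
    """K draws from the alternative S ~ N(Sigma Lambda, Sigma)."""
    ld = np.asarray(ld, dtype=float)
    mean = ld @ alt.ncp
    return sample_null_direct(ld, K, seed) + mean[None, :]


def sample_alt_stats_random_causals(ld: np.ndarray, n_causal: int, lam: float,
                                    K: int, seed: int | np.random.Generator = 0,
                                    ) -> np.ndarray:
    """Alternative draws with the causal index set re-drawn per replicate."""
    ld = np.asarray(ld, dtype=float)
    m = ld.shape[0]
    rng = np.random.default_rng(seed)
    noise = sample_null_direct(ld, K, rng)
    # means[k] = lam * sum of ld columns at that replicate's causal set
    idx = np.argsort(rng.random((K, m)), axis=1)[:, :n_causal]
    means = lam * ld[idx].sum(axis=1)
    return noise + means


def calibrate_threshold(null_stats: np.ndarray, params: ModelParams,
                        alpha: float, ld: np.ndarray | None = None,
                        null_lrt: np.ndarray | None = None) -> tuple[float, int]:
    """Transfer the per-test level alpha onto the LRT scale via the null panel.

    q = number of null draws whose locus-level univariate p is below alpha;
    the threshold is the q-th largest null LRT, so exactly q null LRTs are at
    or above it — the two tests then reject the same number of null draws.
    """
    null_stats = np.atleast_2d(np.asarray(null_stats, dtype=float))
    uni_p = univariate_pvalues(null_stats)
    q = int(np.sum(uni_p < alpha))
    if q == 0:
        raise CalibrationError(
            f"no null draw has univariate p < {alpha:g}; increase the panel "
            f"size K or the level alpha"
        )
    if null_lrt is None:
        if ld is None:
            raise InvalidParameterError("provide ld or precomputed null_lrt")
        null_lrt = lrt_panel(null_stats, ld, params)
    threshold = float(np.partition(null_lrt, -q)[-q])
    return threshold, q


def estimate_power(alt_stats: np.ndarray, ld: np.ndarray, lrt_threshold: float,
                   params: ModelParams,
                   alt_lrt: np.ndarray | None = None) -> float:
    """Percentage of alternative draws whose LRT exceeds the threshold."""
    if alt_lrt is None:
        alt_lrt = lrt_panel(np.atleast_2d(alt_stats), ld, params)
    return float(np.mean(alt_lrt > lrt_threshold) * 100.0)


def estimate_power_uni(alt_stats: np.ndarray, alpha: float) -> float:
    """Percentage of alternative draws whose univariate locus p is below alpha."""
    uni_p = univariate_pvalues(np.atleast_2d(alt_stats))
    return float(np.mean(uni_p < alpha) * 100.0)


def power_experiment(ld: np.ndarray, params: ModelParams, n_causal: int,
                     lam: float, n_reps: int, alpha: float,
                     seed: int = 0) -> PowerReport:
    """Full power comparison at one design point.

    Null and alternative panels of ``n_reps`` draws each; the LRT threshold is
    calibrated from the null panel by the univariate-quantile transfer, causal
    index sets are re-drawn per alternative replicate.
    """
    rng = np.random.default_rng(seed)
    null_seed, alt_seed = rng.integers(2**31 - 1, size=2)
    null_stats = sample_null_direct(ld, n_reps, int(null_seed))
    null_lrt = lrt_panel(null_stats, ld, params)
    threshold, q = calibrate_threshold(null_stats, params, alpha,
                                       null_lrt=null_lrt)
    alt_stats = sample_alt_stats_random_causals(ld, n_causal, lam, n_reps,
                                                int(alt_seed))
    power_mars = estimate_power(alt_stats, ld, threshold, params)
    power_uni = estimate_power_uni(alt_stats, alpha)
    improvement = (
        (power_mars - power_uni) / power_uni * 100.0 if power_uni > 0 else float("nan")
    )
    return PowerReport(
        power_mars=power_mars,
        power_uni=power_uni,
        improvement_pct=improvement,
        lrt_threshold=threshold,
        q=q,
        n_reps=n_reps,
        alpha=alpha,
    )


def type1_experiment(ld: np.ndarray, params: ModelParams, n_reps: int,
                     alphas: list[float] | np.ndarray,
                     seed: int = 0) -> pd.DataFrame:
    """Split-half false-positive-rate estimation.

    ``n_reps`` null statistic vectors are drawn and split in half.  For each
    alpha, the LRT threshold is the upper-alpha order statistic of the first
    half's LRTs; the empirical FPR is the fraction of second-half LRTs above
    it.  A calibrated test returns FPR close to alpha.
    """
    null_stats = sample_null_direct(ld, n_reps, seed)
    lrt = lrt_panel(null_stats, ld, params)
    half = n_reps // 2
    first, second = lrt[:half], lrt[half:]
    rows = []
    for alpha in alphas:
        k = max(1, int(round(alpha * half)))
        threshold = float(np.partition(first, -k)[-k])
        fpr = float(np.mean(second > threshold))
        rows.append({"alpha": float(alpha), "empirical_fpr": fpr,
                     "lrt_threshold": threshold})
    return pd.DataFrame(rows)
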