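"""The MARS likelihood-ratio statistic.

Model. Given a causal-status vector C (c_i = 1 iff SNP i is causal), true
effects are Lambda | C ~ N(0, Delta) with Delta diagonal, Delta_ii = sigma2
for causal SNPs and epsilon otherwise, and the statistic vector satisfies
S | Lambda ~ N(Sigma Lambda, Sigma).  Marginalising Lambda,

    S | C ~ N(0, Sigma + Sigma Delta Sigma).

With an independent Bernoulli(gamma) prior on each causal indicator, the locus
test statistic is the ratio of the prior-weighted sum of likelihoods over all
non-null statuses (at most ``max_causal`` causal SNPs) to the null likelihood:

    LRT = sum_{C != C0} p(S|C) p(C)  /  [ p(S|C0) p(C0) ].

Computation. Each configuration covariance is a rank-n_causal update of the
base covariance: Sigma + Sigma E D E^T Sigma with E the causal-column selector.
Since Sigma^-1 (Sigma E) = E, Woodbury and the matrix-determinant lemma reduce
every configuration to linear algebra of size n_causal:

    S^T (Sigma + sigma2 Sigma_c Sigma_c^T)^-1 S
        = S^T Sigma^-1 S - S_c^T (I/sigma2 + Sigma_cc)^-1 S_c
    |Sigma + ...| = |Sigma| |I + sigma2 Sigma_cc|

where the subscript c restricts to the causal index set.  epsilon > 0 is
folded into a base covariance Sigma_eps = Sigma + eps Sigma Sigma factored
once per locus; the same identities hold with Sigma_cc replaced by the causal
submatrix of Sigma (I + eps Sigma)^-1 and sigma2 by sigma2 - eps.  All
accumulation is in log space.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from math import comb, log, pi

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import logsumexp

from .errors import InvalidParameterError, NumericalError
from .locus import LocusData, select_top_k

_LOG_2PI = log(2.0 * pi)


@dataclass
class ModelParams:
    """Hyper-parameters of the causal-status model.

    gamma : per-SNP prior causal probability (scalar or length-m vector).
    sigma2 : variance of the causal effect-size distribution (the causal
        diagonal of Delta); on the z-score scale this is the squared typical
        non-centrality of a causal SNP.
    epsilon : non-causal diagonal of Delta (0 gives an exact point-mass null).
    max_causal : maximum number of simultaneously causal SNPs enumerated.
    top_k : number of SNPs (largest |z|) retained before enumeration.
    ridge : diagonal loading added to Sigma when it is numerically singular.
    """

    gamma: float | np.ndarray = 0.01
    sigma2: float = 27.04
    epsilon: float = 0.0
    max_causal: int = 3
    top_k: int = 50
    ridge: float = 1e-6

    def __post_init__(self) -> None:
        g = np.asarray(self.gamma, dtype=float)
        if np.any(g <= 0.0) or np.any(g >= 1.0):
            raise InvalidParameterError("gamma must lie strictly in (0, 1)")
        if self.sigma2 <= 0.0:
            raise InvalidParameterError("sigma2 must be > 0")
        if self.epsilon < 0.0:
            raise InvalidParameterError("epsilon must be >= 0")
        if self.epsilon >= self.sigma2:
            raise InvalidParameterError("epsilon must be < sigma2")
        if not 1 <= self.max_causal <= self.top_k:
            raise InvalidParameterError("need 1 <= max_causal <= top_k")

    def gamma_vector(self, m: int) -> np.ndarray:
        g = np.asarray(self.gamma, dtype=float)
        if g.ndim == 0:
            return np.full(m, float(g))
        if g.shape != (m,):
            raise InvalidParameterError(f"gamma vector has length {g.shape}, expected {m}")
        return g

    def to_dict(self) -> dict:
        g = np.asarray(self.gamma, dtype=float)
        return {
            "gamma": g.tolist() if g.ndim else float(g),
            "sigma2": float(self.sigma2),
            "epsilon": float(self.epsilon),
            "max_causal": int(self.max_causal),
            "top_k": int(self.top_k),
        }


@dataclass
class CausalConfig:
    """A binary causal-status vector."""

    status: np.ndarray
    n_causal: int = field(init=False)

    def __post_init__(self) -> None:
        self.status = np.asarray(self.status, dtype=int).reshape(-1)
        if not np.all((self.status == 0) | (self.status == 1)):
            raise InvalidParameterError("causal status entries must be 0 or 1")
        self.n_causal = int(self.status.sum())

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.status)


@dataclass
class LRTResult:
    """Likelihood-ratio statistic of a locus and its log-space parts."""

    lrt_stat: float
    log_l0: float
    log_l1: float
    n_configs: int
    selected_indices: np.ndarray


def causal_prior(config: CausalConfig | np.ndarray, gamma: float | np.ndarray,
                 log_space: bool = False) -> float:
    """Independent-Bernoulli prior p(C) = prod gamma_i^{c_i} (1-gamma_i)^{1-c_i}."""
    status = config.status if isinstance(config, CausalConfig) else np.asarray(config, int)
    g = np.asarray(gamma, dtype=float)
    if np.any(g <= 0.0) or np.any(g >= 1.0):
        raise InvalidParameterError("gamma must lie strictly in (0, 1)")
    if g.ndim == 0:
        g = np.full(status.shape[0], float(g))
    lp = float(np.sum(np.where(status == 1, np.log(g), np.log1p(-g))))
    return lp if log_space else float(np.exp(lp))


def enumerate_configs(m: int, max_causal: int):
    """Yield every causal status with 1..max_causal causal SNPs.

    Order is deterministic: by n_causal, then lexicographic in the causal
    index set.  Total count is sum_{i=1..max_causal} C(m, i).
    """
    if not 1 <= max_causal <= m:
        raise InvalidParameterError("need 1 <= max_causal <= m")
    for c in range(1, max_causal + 1):
        for idx in itertools.combinations(range(m), c):
            status = np.zeros(m, dtype=int)
            status[list(idx)] = 1
            yield CausalConfig(status=status)


def n_configs(m: int, max_causal: int) -> int:
    """Number of non-null configurations with at most max_causal causal SNPs."""
    return sum(comb(m, c) for c in range(1, min(max_causal, m) + 1))


def config_covariance(ld: np.ndarray, config: CausalConfig,
                      params: ModelParams) -> np.ndarray:
    """Dense configuration covariance Sigma + Sigma Delta Sigma."""
    ld = np.asarray(ld, dtype=float)
    delta = np.where(np.asarray(config.status, bool), params.sigma2, params.epsilon)
    cov = ld + (ld * delta) @ ld
    return 0.5 * (cov + cov.T)


class LocusFactorization:
    """Per-locus factorizations shared by every configuration.

    Factors the base covariance once (Sigma, plus the epsilon fold-in when
    epsilon > 0) so each configuration costs O(n_causal^3) plus gathers.
    """

    def __init__(self, ld: np.ndarray, params: ModelParams):
        sigma = np.asarray(ld, dtype=float)
        m = sigma.shape[0]
        eigmin = float(np.linalg.eigvalsh(sigma).min())
        if eigmin < 1e-8:
            warnings.warn(
                f"LD matrix nearly singular (min eigenvalue {eigmin:.2e}); "
                f"adding ridge {params.ridge:g} to the diagonal",
                RuntimeWarning,
                stacklevel=2,
            )
            sigma = sigma + params.ridge * np.eye(m)
        self.m = m
        self.params = params
        self.sigma = sigma
        self.chol = cho_factor(sigma, lower=True)
        self.logdet_sigma = 2.0 * float(np.sum(np.log(np.diag(self.chol[0]))))
        eps = params.epsilon
        if eps > 0.0:
            # Sigma_eps = Sigma (I + eps Sigma); A = (I+eps Sigma)^-1 commutes
            # with Sigma, B = Sigma A is the causal-submatrix kernel.
            a = np.linalg.inv(np.eye(m) + eps * sigma)
            self.A = 0.5 * (a + a.T)
            b = sigma @ self.A
            self.B = 0.5 * (b + b.T)
            sign, ld2 = np.linalg.slogdet(np.eye(m) + eps * sigma)
            if sign <= 0:
                raise NumericalError("I + epsilon*Sigma not positive definite")
            self.logdet_base = self.logdet_sigma + float(ld2)
        else:
            self.A = None
            self.B = sigma
            self.logdet_base = self.logdet_sigma
        self.d = params.sigma2 - eps

    def base_quads(self, stats: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(q0, T): base quadratic forms s' Sigma_eps^-1 s and rows A s."""
        s = np.atleast_2d(np.asarray(stats, dtype=float))
        sol = cho_solve(self.chol, s.T).T  # rows Sigma^-1 s
        if self.A is not None:
            t = s @ self.A
        else:
            t = s
        q0 = np.einsum("km,km->k", t, sol)
        return q0, t

    def null_loglik(self, stats: np.ndarray) -> np.ndarray:
        """log p(S | C0) for each row of stats (no prior)."""
        q0, _ = self.base_quads(stats)
        return -0.5 * (self.m * _LOG_2PI + self.logdet_base + q0)


def _config_chunks(m: int, n_causal: int, chunk: int):
    """Yield (p, n_causal) index arrays covering all combinations."""
    it = itertools.combinations(range(m), n_causal)
    while True:
        block = list(itertools.islice(it, chunk))
        if not block:
            return
        yield np.asarray(block, dtype=int)


def lrt_batch(stats: np.ndarray, ld: np.ndarray, params: ModelParams,
              return_parts: bool = False):
    """Likelihood-ratio statistics for K statistic rows sharing one LD matrix.

    ``stats`` is (K, m) (or (m,)); truncation to top_k is the caller's job —
    this routine enumerates configurations over all m columns given.

    Returns the (K,) vector of LRT values, or (lrt, log_l0, log_l1) when
    ``return_parts``; log_l0 and log_l1 include the configuration priors.
    """
    s = np.atleast_2d(np.asarray(stats, dtype=float))
    k_rows, m = s.shape
    max_c = min(params.max_causal, m)
    gamma = params.gamma_vector(m)
    log_g = np.log(gamma)
    log_1mg = np.log1p(-gamma)
    lp0 = float(log_1mg.sum())

    fac = LocusFactorization(ld, params)
    q0, t = fac.base_quads(s)
    const = m * _LOG_2PI + fac.logdet_base
    log_l0 = -0.5 * (const + q0) + lp0

    d = fac.d
    chunk = max(1, int(4_000_000 / max(k_rows, 1)))
    pieces: list[np.ndarray] = []
    for c in range(1, max_c + 1):
        eye_c = np.eye(c)
        for cfg in _config_chunks(m, c, max(1, chunk // c)):
            bcc = fac.B[cfg[:, :, None], cfg[:, None, :]]  # (p, c, c)
            g_mat = eye_c + d * bcc
            sign, ldet = np.linalg.slogdet(g_mat)
            if np.any(sign <= 0):
                bad = cfg[int(np.argmax(sign <= 0))]
                raise NumericalError(
                    f"configuration covariance not positive definite for causal "
                    f"index set {tuple(int(i) for i in bad)}"
                )
            g_inv = np.linalg.inv(g_mat)
            w = t[:, cfg]  # (K, p, c)
            quad = d * np.einsum("kpc,pcd,kpd->kp", w, g_inv, w)
            ll = -0.5 * (const + ldet[None, :] + q0[:, None] - quad)
            lp = lp0 + (log_g - log_1mg)[cfg].sum(axis=1)
            pieces.append(logsumexp(ll + lp[None, :], axis=1))
    log_l1 = logsumexp(np.stack(pieces, axis=0), axis=0)
    if not (np.all(np.isfinite(log_l0)) and np.all(np.isfinite(log_l1))):
        raise NumericalError("non-finite log-likelihood in LRT computation")
    # exp may saturate to +inf for overwhelming signals; the log parts stay exact
    with np.errstate(over="ignore"):
        lrt = np.exp(log_l1 - log_l0)
    if return_parts:
        return lrt, log_l0, log_l1
    return lrt


def config_loglik(stats: np.ndarray, ld: np.ndarray, config: CausalConfig,
                  params: ModelParams) -> float:
    """log p(S | C) via the low-rank update (no prior term)."""
    s = np.asarray(stats, dtype=float).reshape(1, -1)
    fac = LocusFactorization(ld, params)
    if config.n_causal == 0:
        return float(fac.null_loglik(s)[0])
    cfg = config.indices.reshape(1, -1)
    c = cfg.shape[1]
    bcc = fac.B[cfg[:, :, None], cfg[:, None, :]]
    g_mat = np.eye(c) + fac.d * bcc
    sign, ldet = np.linalg.slogdet(g_mat)
    if np.any(sign <= 0):
        raise NumericalError(
            f"configuration covariance not positive definite for causal "
            f"index set {tuple(int(i) for i in config.indices)}"
        )
    q0, t = fac.base_quads(s)
    w = t[:, cfg]
    quad = fac.d * np.einsum("kpc,pcd,kpd->kp", w, np.linalg.inv(g_mat), w)
    const = fac.m * _LOG_2PI + fac.logdet_base
    return float(-0.5 * (const + ldet[0] + q0[0] - quad[0, 0]))


def lrt_statistic(data: LocusData, params: ModelParams,
                  by_abs: bool = True) -> LRTResult:
    """The MARS statistic of one locus: truncate to top_k, enumerate, aggregate."""
    if data.m > params.top_k:
        from .locus import top_k_indices

        sel = top_k_indices(data.stats, params.top_k, by_abs=by_abs)
        sub = data.subset(sel)
    else:
        sel = np.arange(data.m)
        sub = data
    gamma = params.gamma
    g = np.asarray(gamma, dtype=float)
    if g.ndim == 1 and g.shape[0] == data.m and sub.m != data.m:
        params = ModelParams(gamma=g[sel], sigma2=params.sigma2,
                             epsilon=params.epsilon, max_causal=params.max_causal,
                             top_k=params.top_k, ridge=params.ridge)
    lrt, log_l0, log_l1 = lrt_batch(sub.stats, sub.ld, params, return_parts=True)
    return LRTResult(
        lrt_stat=float(lrt[0]),
        log_l0=float(log_l0[0]),
        log_l1=float(log_l1[0]),
        n_configs=n_configs(sub.m, params.max_causal),
        selected_indices=sel,
    )


def lrt_panel(stats: np.ndarray, ld: np.ndarray, params: ModelParams,
              by_abs: bool = True) -> np.ndarray:
    """LRT statistics for a (K, m) matrix of draws, honouring top_k per draw.

    When m <= top_k every draw shares one factorization (fast path); otherwise
    each draw selects its own top-k SNPs and is evaluated on that sub-locus.
    """
    s = np.atleast_2d(np.asarray(stats, dtype=float))
    m = s.shape[1]
    if m <= params.top_k:
        return lrt_batch(s, ld, params)
    from .locus import top_k_indices

    out = np.empty(s.shape[0])
    for i, row in enumerate(s):
        sel = top_k_indices(row, params.top_k, by_abs=by_abs)
        out[i] = lrt_batch(row[sel], ld[np.ix_(sel, sel)], params)[0]
    return out
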