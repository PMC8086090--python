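import itertools

import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import multivariate_normal

import mars


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def ar1_locus_20():
    """AR(1) rho=0.5, m=20 locus used by the calibration experiments."""
    return mars.gen_ld(20, "ar1", 0.5)


def random_correlation(m, rng, extra=3):
    """A well-conditioned random correlation matrix."""
    a = rng.standard_normal((m, m + extra))
    s = a @ a.T
    d = np.sqrt(np.diag(s))
    return s / np.outer(d, d)


def dense_lrt(stats, ld, params):
    """Brute-force likelihood ratio: dense MVN densities over all configs.

    Independent oracle for the low-rank implementation; O(2^m) work, use only
    for m <= ~8.
    """
    m = len(stats)
    gamma = params.gamma_vector(m)
    log_terms = []
    for c in range(1, min(params.max_causal, m) + 1):
        for idx in itertools.combinations(range(m), c):
            delta = np.full(m, params.epsilon)
            delta[list(idx)] = params.sigma2
            cov = ld + (ld * delta) @ ld
            ll = multivariate_normal.logpdf(stats, mean=np.zeros(m), cov=cov)
            lp = float(np.log(gamma[list(idx)]).sum()
                       + np.log1p(-gamma)[[i for i in range(m) if i not in idx]].sum())
            log_terms.append(ll + lp)
    cov0 = ld + (ld * np.full(m, params.epsilon)) @ ld
    l0 = multivariate_normal.logpdf(stats, mean=np.zeros(m), cov=cov0) + float(
        np.log1p(-gamma).sum()
    )
    return float(np.exp(logsumexp(log_terms) - l0))
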