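"""Beta-uniform mixture model of per-gene association p-values.

A gene's p-value is routed by a binary switch T: when T = 1 the p-value
follows the significant component Beta(alpha, 1) with density
``alpha * p**(alpha-1)`` (alpha < 1 concentrates mass near zero); when
T = 0 it is Uniform(0, 1).  The functions here are the scalar/array
primitives used throughout fitting: branch densities, the mixture density,
inverse-CDF sampling, and the posterior of the switch given the latent
association score F.

Likelihood ratios are computed in log space: ``alpha * p**(alpha-1)``
overflows double precision for very small p (p can be clipped at 1e-300).
"""

from __future__ import annotations

import numpy as np

__all__ = ["beta1_logpdf", "mixture_logpdf", "sample_p", "posterior_T"]


def _validate_p(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p must lie in (0, 1]; clip before calling")
    return p


def beta1_logpdf(p, alpha):
    """Log-density of Beta(alpha, 1) at p: log(alpha) + (alpha - 1) * log(p).

    This is the significant (T = 1) branch of the mixture.  ``alpha`` must
    lie in (0, 1] — the value 1 is the uniform boundary where the density
    is identically 1.
    """
    p = _validate_p(p)
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0) or np.any(alpha > 1):
        raise ValueError("alpha must lie in (0, 1]")
    return np.log(alpha) + (alpha - 1.0) * np.log(p)


def mixture_logpdf(p, alpha, w):
    """Log-density of the two-component mixture w*Beta(alpha,1) + (1-w)*U(0,1).

    ``w`` is the marginal probability of the significant branch.  Evaluated
    with logaddexp so the beta branch cannot overflow for tiny p.
    """
    w = np.asarray(w, dtype=float)
    if np.any(w < 0) or np.any(w > 1):
        raise ValueError("mixture weight w must lie in [0, 1]")
    log_beta = beta1_logpdf(p, alpha)
    with np.errstate(divide="ignore"):
        lw = np.log(w)
        l1w = np.log1p(-w)
    # uniform branch has log-density 0
    return np.logaddexp(lw + log_beta, l1w)


def sample_p(T, alpha, rng: np.random.Generator):
    """Draw p-values given switch states T (0/1 array) and shape alpha.

    T = 0 genes draw Uniform(0,1); T = 1 genes draw Beta(alpha, 1) by the
    inverse CDF ``u**(1/alpha)``.  One uniform is consumed per gene, so the
    draw sequence is reproducible under a fixed seed regardless of the mix.
    """
    T = np.asarray(T)
    u = rng.uniform(size=T.shape)
    p = np.where(T == 1, u ** (1.0 / alpha), u)
    # guard against an exact 0 from u == 0
    return np.clip(p, np.finfo(float).tiny, 1.0)


def posterior_T(p, alpha, F, f_eps: float = 1e-6):
    """Posterior probability of the switch T = 1 given p, alpha and score F.

    Bayes inversion of T ~ Bernoulli(F) against the two branch densities:

        P(T=1 | p) = F * alpha * p**(alpha-1) / (F * alpha * p**(alpha-1) + 1 - F)

    computed in log space with a max-subtraction so the beta branch density
    (which can exceed 1e270 for clipped p) never overflows.  F is clipped
    into [f_eps, 1 - f_eps] first.
    """
    F = np.clip(np.asarray(F, dtype=float), f_eps, 1.0 - f_eps)
    log_num = np.log(F) + beta1_logpdf(p, alpha)
    log_den_other = np.log1p(-F)  # uniform branch: log((1-F) * 1)
    m = np.maximum(log_num, log_den_other)
    num = np.exp(log_num - m)
    return num / (num + np.exp(log_den_other - m))
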