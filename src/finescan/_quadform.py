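"""Tail probability of a positively weighted sum of 1-df chi-square variables.

This is the null distribution of variance-component score statistics such as
SKAT: ``Q ~ sum_l lambda_l * chi2_1``. The primary route numerically inverts
the characteristic function (Imhof's formula); when the inversion is
unreliable the moment-matched noncentral chi-square approximation of
Liu, Tang & Zhang is used instead.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import integrate, stats

#: relative eigenvalue truncation threshold
EIG_TRUNC = 1e-10


def _imhof_integrand(u: np.ndarray, q: float, lam: np.ndarray) -> np.ndarray:
    lu = lam[:, None] * u[None, :]
    theta = 0.5 * np.sum(np.arctan(lu), axis=0) - 0.5 * q * u
    rho = np.exp(0.25 * np.sum(np.log1p(lu**2), axis=0))
    return np.sin(theta) / (u * rho)


def imhof_pvalue(q: float, lam: np.ndarray) -> float:
    """P(sum lambda_l chi2_1 > q) by adaptive quadrature of Imhof's integral."""
    lam = np.asarray(lam, dtype=float)
    # scale invariance: divide by max eigenvalue for a well-conditioned grid
    s = lam.max()
    lam = lam / s
    q = q / s

    def f(u):
        return _imhof_integrand(np.atleast_1d(u), q, lam)[0]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, err = integrate.quad(f, 0.0, np.inf, limit=400, epsabs=1e-12, epsrel=1e-9)
    p = 0.5 + val / np.pi
    if not np.isfinite(p) or err > 1e-4:
        raise ArithmeticError("Imhof quadrature unreliable")
    return float(min(max(p, 1e-16), 1.0))


def liu_pvalue(q: float, lam: np.ndarray) -> float:
    """Liu-Tang-Zhang moment-matched noncentral chi-square approximation."""
    lam = np.asarray(lam, dtype=float)
    c1 = lam.sum()
    c2 = np.sum(lam**2)
    c3 = np.sum(lam**3)
    c4 = np.sum(lam**4)
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        ell = a**2 - 2.0 * delta
    else:
        delta = 0.0
        ell = 1.0 / s2
    mu_x = ell + delta
    sigma_x = np.sqrt(2.0) * np.sqrt(ell + 2.0 * delta)
    t = (q - c1) / np.sqrt(2.0 * c2)
    x = t * sigma_x + mu_x
    p = stats.ncx2.sf(x, df=ell, nc=delta) if delta > 0 else stats.chi2.sf(x, df=ell)
    return float(min(max(p, 1e-16), 1.0))


def weighted_chisq_sf(q: float, lam: np.ndarray) -> tuple[float, str]:
    """Survival function of ``sum lambda_l chi2_1`` at ``q``.

    Returns ``(p, method)`` with ``method`` one of ``"imhof"``/``"liu"``.
    Eigenvalues below ``EIG_TRUNC * max(lam)`` are discarded.
    """
    lam = np.asarray(lam, dtype=float)
    lam = lam[lam > 0]
    if lam.size == 0:
        raise ValueError("no positive eigenvalues")
    lam = lam[lam > EIG_TRUNC * lam.max()]
    if q <= 0:
        return 1.0, "exact"
    try:
        return imhof_pvalue(q, lam), "imhof"
    except Exception:
        return liu_pvalue(q, lam), "liu"
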