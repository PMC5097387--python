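"""Per-SNV case-control association, meta-analysis, and multiplicity.

Single-SNV tests are additive-dosage logistic regressions (IRLS fit to a
relative log-likelihood tolerance of 1e-10) reporting Wald statistics plus
the maximized and covariates-only log-likelihoods; the latter pair feeds the
approximate-Bayesian credible-set stage. Cross-population combination uses
inverse-variance fixed-effect meta-analysis. The multiple-testing threshold
divides alpha by a region-specific effective number of tests derived from
correlation-matrix eigenvalues (simpleM-style, 99.5% variance explained).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .core import GenotypeMatrix

log = logging.getLogger(__name__)

IRLS_TOL = 1e-10
IRLS_MAX_ITER = 50
#: |beta| beyond which a logistic fit is treated as (quasi-)separated
#: (a per-allele log-OR of 15 is an odds ratio above 3e6)
SEPARATION_BETA = 15.0


@dataclass
class AssocResult:
    variant_id: str
    population: str
    beta: float = np.nan
    se: float = np.nan
    z: float = np.nan
    p: float = np.nan
    loglik: float = np.nan
    null_loglik: float = np.nan
    n: int = 0
    maf: float = np.nan
    evaluable: bool = False
    note: str = ""

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci95(self) -> tuple[float, float]:
        return (float(np.exp(self.beta - 1.959963984540054 * self.se)),
                float(np.exp(self.beta + 1.959963984540054 * self.se)))


@dataclass
class MetaResult:
    variant_id: str
    beta: float
    se: float
    z: float
    p: float
    populations: list[str]
    per_population: dict = field(default_factory=dict)


@dataclass
class MultiplicityResult:
    meff_by_region: dict
    total_meff: int
    alpha: float
    threshold: float


# ----------------------------------------------------------------------
# logistic regression (IRLS)
# ----------------------------------------------------------------------
def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _irls(X: np.ndarray, y: np.ndarray, beta0: np.ndarray | None = None):
    """Newton/IRLS with step halving. Returns (beta, cov, loglik, ok)."""
    n, p = X.shape
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    ll = _loglik(y, X @ beta)
    converged = False
    H = None
    for _ in range(IRLS_MAX_ITER):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        XtW = X.T * w
        H = XtW @ X
        grad = X.T @ (y - mu)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return beta, None, ll, False
        # step halving keeps the likelihood non-decreasing
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new = _loglik(y, X @ cand)
            if ll_new >= ll - 1e-14:
                break
            scale *= 0.5
        else:
            return beta, None, ll, False
        delta = ll_new - ll
        beta, ll = cand, ll_new
        if abs(delta) < IRLS_TOL * (abs(ll) + 1.0):
            converged = True
            break
    if not converged or np.max(np.abs(beta)) > SEPARATION_BETA:
        return beta, None, ll, False
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return beta, None, ll, False
    if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) <= 0):
        return beta, None, ll, False
    return beta, cov, ll, True


def fit_logistic(
    dosage: np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    variant_id: str = "",
    population: str = "",
) -> AssocResult:
    """Additive logistic regression of a binary phenotype on one dosage.

    Samples with a missing dosage (NaN) are dropped for this variant; both
    the maximized and the covariates-only log-likelihoods are computed on
    the identical sample subset. Monomorphic dosages, quasi-complete
    separation and non-convergence yield a not-evaluable result.
    """
    dosage = np.asarray(dosage, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    use = np.isfinite(dosage)
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != dosage.shape[0]:
            covariates = covariates.T
        use &= np.all(np.isfinite(covariates), axis=1)
    d, yy = dosage[use], y[use]
    n = int(use.sum())
    res = AssocResult(variant_id=variant_id, population=population, n=n)
    if n == 0:
        res.note = "no called genotypes"
        return res
    res.maf = float(min(d.mean() / 2.0, 1.0 - d.mean() / 2.0))
    if yy.min() == yy.max():
        res.note = "single phenotype class"
        return res
    if d.min() == d.max():
        res.note = "monomorphic dosage"
        return res
    Xn = np.column_stack([np.ones(n)] + ([covariates[use]] if covariates is not None else []))
    b_null, _, ll_null, ok_null = _irls(Xn, yy)
    X = np.column_stack([Xn, d])
    beta0 = np.append(b_null, 0.0)
    b, cov, ll, ok = _irls(X, yy, beta0=beta0 if ok_null else None)
    res.null_loglik = ll_null
    if not (ok and ok_null):
        res.note = "separation or non-convergence"
        return res
    res.beta = float(b[-1])
    res.se = float(np.sqrt(cov[-1, -1]))
    res.z = res.beta / res.se
    res.p = float(max(2.0 * stats.norm.sf(abs(res.z)), 1e-300))
    res.loglik = ll
    res.evaluable = True
    return res


# ----------------------------------------------------------------------
# phenotype selection
# ----------------------------------------------------------------------
def phenotype_selection(sheet: pd.DataFrame, phenotype: str = "overall"):
    """Return (sample mask, 0/1 phenotype over masked samples).

    ``er_neg``/``er_pos`` compare ER-negative (resp. positive) cases against
    controls; cases of the other or unknown ER status are excluded rather
    than recoded.
    """
    status = sheet["status"].to_numpy()
    if phenotype == "overall":
        mask = np.ones(len(sheet), dtype=bool)
    elif phenotype in ("er_neg", "er_pos"):
        er = sheet["er_status"].to_numpy()
        want = "negative" if phenotype == "er_neg" else "positive"
        mask = (status == "control") | ((status == "case") & (er == want))
    else:
        raise ValueError(f"unknown phenotype {phenotype!r}")
    y = (status[mask] == "case").astype(float)
    return mask, y


# ----------------------------------------------------------------------
# region scan
# ----------------------------------------------------------------------
def _mean_impute(col: np.ndarray) -> np.ndarray:
    out = col.copy()
    bad = ~np.isfinite(out)
    if bad.any():
        out[bad] = np.nanmean(out) if np.isfinite(out).any() else 0.0
    return out


def scan_region(
    gm: GenotypeMatrix,
    sheet: pd.DataFrame,
    covariates: np.ndarray | None = None,
    condition_on=(),
    maf_min: float = 0.005,
    phenotype: str = "overall",
    population: str = "",
) -> list[AssocResult]:
    """Fit every variant with MAF > ``maf_min`` (on the analysis samples),
    optionally adding the dosages of ``condition_on`` variant ids as
    covariates. Conditioned variants, and variants at or below the MAF
    floor, are reported not-evaluable. Returns one result per variant of
    ``gm`` in variant order.
    """
    if list(sheet["sample_id"]) != list(gm.samples):
        raise ValueError("sample sheet must be aligned with the genotype matrix sample order")
    mask, y = phenotype_selection(sheet, phenotype)
    sub = gm.take_samples(mask)
    covs = None if covariates is None else np.atleast_2d(np.asarray(covariates, dtype=float))
    if covs is not None:
        if covs.shape[0] != gm.n_samples:
            covs = covs.T
        covs = covs[mask]

    condition_on = list(condition_on)
    vid_index = {v: j for j, v in enumerate(gm.variant_ids)}
    if condition_on:
        base = np.column_stack([np.ones(sub.n_samples)] + ([covs] if covs is not None else []))
        cond_cols = []
        for vid in condition_on:
            if vid not in vid_index:
                raise KeyError(f"condition_on variant {vid!r} not in matrix")
            col = _mean_impute(sub.dosage[:, vid_index[vid]])
            trial = np.column_stack([base] + cond_cols + [col])
            if np.linalg.matrix_rank(trial) < trial.shape[1]:
                raise ValueError(f"condition_on variant {vid!r} is collinear with the covariates")
            cond_cols.append(col)
        covs = np.column_stack(([covs] if covs is not None else []) + cond_cols)

    with np.errstate(invalid="ignore"):
        f = np.nansum(sub.dosage, axis=0) / (2.0 * np.sum(np.isfinite(sub.dosage), axis=0))
    maf = np.minimum(f, 1.0 - f)

    results: list[AssocResult] = []
    conditioned = set(condition_on)
    for j, vid in enumerate(gm.variant_ids):
        if vid in conditioned:
            results.append(AssocResult(variant_id=vid, population=population, n=sub.n_samples,
                                       maf=float(maf[j]), note="conditioned on"))
        elif not np.isfinite(maf[j]) or maf[j] <= maf_min:
            results.append(AssocResult(variant_id=vid, population=population, n=sub.n_samples,
                                       maf=float(maf[j]) if np.isfinite(maf[j]) else np.nan,
                                       note=f"maf <= {maf_min}"))
        else:
            results.append(fit_logistic(sub.dosage[:, j], y, covariates=covs,
                                        variant_id=vid, population=population))
    return results


def results_frame(results: list[AssocResult], region_by_variant: dict | None = None) -> pd.DataFrame:
    region_by_variant = region_by_variant or {}
    return pd.DataFrame(
        [
            dict(variant_id=r.variant_id, region_id=region_by_variant.get(r.variant_id, ""),
                 population=r.population, beta=r.beta, se=r.se,
                 z=r.z, p=r.p, loglik=r.loglik, null_loglik=r.null_loglik, n=r.n,
                 maf=r.maf, evaluable=r.evaluable, note=r.note)
            for r in results
        ]
    )


# ----------------------------------------------------------------------
# fixed-effect meta-analysis
# ----------------------------------------------------------------------
def meta_fixed(results: list[AssocResult]) -> MetaResult:
    """Inverse-variance fixed-effect combination of per-population results
    for one variant; not-evaluable populations are skipped."""
    usable = [r for r in results if r.evaluable]
    if not usable:
        raise ValueError("no evaluable population results to meta-analyze")
    vids = {r.variant_id for r in usable}
    if len(vids) > 1:
        raise ValueError(f"meta_fixed mixes variants {sorted(vids)}")
    w = np.array([1.0 / r.se**2 for r in usable])
    betas = np.array([r.beta for r in usable])
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    z = beta / se
    return MetaResult(
        variant_id=usable[0].variant_id,
        beta=beta,
        se=se,
        z=z,
        p=float(max(2.0 * stats.norm.sf(abs(z)), 1e-300)),
        populations=[r.population for r in usable],
        per_population={r.population: (r.beta, r.se) for r in usable},
    )


# ----------------------------------------------------------------------
# effective number of tests
# ----------------------------------------------------------------------
def region_correlation(gm: GenotypeMatrix, sample_mask=None, maf_min: float = 0.005) -> np.ndarray:
    """Correlation matrix of the common (MAF > maf_min), polymorphic
    dosages; missing genotypes are mean-imputed."""
    dos = gm.dosage if sample_mask is None else gm.dosage[np.asarray(sample_mask)]
    with np.errstate(invalid="ignore"):
        f = np.nansum(dos, axis=0) / (2.0 * np.sum(np.isfinite(dos), axis=0))
    maf = np.minimum(f, 1.0 - f)
    keep = np.isfinite(maf) & (maf > maf_min)
    cols = np.flatnonzero(keep)
    Z = np.column_stack([_mean_impute(dos[:, j]) for j in cols]) if cols.size else np.empty((dos.shape[0], 0))
    sd = Z.std(axis=0)
    Z = Z[:, sd > 0]
    if Z.shape[1] == 0:
        return np.empty((0, 0))
    return np.corrcoef(Z, rowvar=False).reshape(Z.shape[1], Z.shape[1])


def effective_tests(corr_by_region: dict, alpha: float = 0.05, variance_fraction: float = 0.995) -> MultiplicityResult:
    """simpleM-style effective number of tests: per region, the smallest k
    whose top-k correlation eigenvalues explain >= ``variance_fraction`` of
    the total; the significance threshold is alpha / sum(Meff)."""
    meff = {}
    for region, R in corr_by_region.items():
        R = np.asarray(R, dtype=float)
        if R.size == 0:
            raise ValueError(f"region {region!r} has no evaluable variants")
        lam = np.clip(np.linalg.eigvalsh(R)[::-1], 0.0, None)
        target = variance_fraction * lam.sum()
        meff[region] = int(np.searchsorted(np.cumsum(lam), target - 1e-12) + 1)
    total = int(sum(meff.values()))
    return MultiplicityResult(meff_by_region=meff, total_meff=total, alpha=alpha, threshold=alpha / total)


# ----------------------------------------------------------------------
# principal components
# ----------------------------------------------------------------------
def compute_pcs(gm: GenotypeMatrix, k: int = 3, maf_min: float = 0.05) -> np.ndarray:
    """Top-k principal-component scores for stratification adjustment.

    Dosages are restricted to MAF > ``maf_min`` (within the supplied
    samples, typically one population), centered at 2f and scaled by
    sqrt(2f(1-f)) with missing entries imputed to the mean, then projected
    on the leading eigenvectors of the variant-space sample covariance.
    The sign of each component is fixed so its largest-magnitude variant
    loading is positive.
    """
    n = gm.n_samples
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} samples for {k} PCs")
    with np.errstate(invalid="ignore"):
        f = np.nansum(gm.dosage, axis=0) / (2.0 * np.sum(np.isfinite(gm.dosage), axis=0))
    maf = np.minimum(f, 1.0 - f)
    keep = np.isfinite(maf) & (maf > maf_min)
    cols = np.flatnonzero(keep)
    if cols.size == 0:
        raise ValueError("no variants above the PCA MAF floor")
    Z = gm.dosage[:, cols] - 2.0 * f[cols]
    Z = np.where(np.isfinite(Z), Z, 0.0) / np.sqrt(2.0 * f[cols] * (1.0 - f[cols]))
    _, s, Vt = np.linalg.svd(Z, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-9))
    if k > rank:
        raise ValueError(f"k={k} exceeds the rank {rank} of the genotype matrix")
    V = Vt[:k].T
    for c in range(k):
        lead = np.argmax(np.abs(V[:, c]))
        if V[lead, c] < 0:
            V[:, c] = -V[:, c]
    return Z @ V
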