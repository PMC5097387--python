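"""Gene-based rare-variant association: burden and SKAT, with
cross-population meta-analysis.

A gene's test set is its rare (pooled MAF < 0.005, strict), nonsynonymous
variants, optionally restricted to those flagged damaging. The burden test
regresses case status on the per-subject minor-allele count across the set
(logistic, giving a per-gene OR with Wald CI); SKAT is the variance-component
score test with Beta(1,25) MAF weights whose null distribution is a weighted
sum of 1-df chi-squares (Imhof-type inversion, Liu fallback). Across
populations, burden results combine by inverse-variance fixed effects and
SKAT by summing per-population score vectors and projected information
matrices under a homogeneous-effect assumption (Hom-Meta-SKAT).

Missing dosages inside a rare-variant set are imputed to the reference
genotype: at MAF < 0.005 the reference call is overwhelmingly the truth, at
the cost of a slight dilution of carrier counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._quadform import weighted_chisq_sf
from .assoc import fit_logistic, _irls
from .core import GenotypeMatrix

log = logging.getLogger(__name__)

DEFAULT_WEIGHT_PARAMS = (1.0, 25.0)


@dataclass
class VariantSet:
    gene: str
    rule: str  # "nonsyn_rare" or "nonsyn_rare_damaging"
    variant_ids: list[str]
    columns: np.ndarray  # column indices into the genotype matrix

    def __len__(self) -> int:
        return len(self.variant_ids)


@dataclass
class GeneTestResult:
    gene: str
    scope: str  # population label or "meta"
    rule: str = ""
    n_variants: int = 0
    carrier_proportion: float = np.nan
    burden_beta: float = np.nan
    burden_se: float = np.nan
    burden_p: float = np.nan
    skat_q: float = np.nan
    skat_p: float = np.nan
    evaluable: bool = False
    note: str = ""

    @property
    def burden_or(self) -> float:
        return float(np.exp(self.burden_beta))

    @property
    def burden_ci95(self) -> tuple[float, float]:
        lo = np.exp(self.burden_beta - 1.959963984540054 * self.burden_se)
        hi = np.exp(self.burden_beta + 1.959963984540054 * self.burden_se)
        return float(lo), float(hi)


@dataclass
class SkatComponents:
    """Per-population SKAT ingredients aligned to a shared variant key list:
    unweighted score vector S = G'(y - mu) and projected information
    B = G' P G, plus allele counts for pooled-MAF weights."""

    variant_ids: list[str]
    score: np.ndarray  # (m,)
    info: np.ndarray  # (m, m)
    alt_alleles: np.ndarray  # (m,) minor-allele dosage sums
    n_chromosomes: np.ndarray  # (m,) 2 * called samples


# ----------------------------------------------------------------------
# set selection & carriers
# ----------------------------------------------------------------------
def select_variant_set(
    gm: GenotypeMatrix,
    gene: str,
    maf_max: float = 0.005,
    damaging_only: bool = False,
) -> VariantSet:
    """Rare nonsynonymous variant set for one gene.

    Membership requires gene match, impact class ``moderate``
    (nonsynonymous), pooled-sample MAF strictly below ``maf_max``, and —
    for the damaging rule — the damaging flag. Empty sets are returned, not
    raised; downstream tests skip them with a logged reason.
    """
    ann = gm.variants
    for col in ("gene", "impact"):
        if col not in ann.columns:
            raise ValueError("variant annotations (gene/impact) are required")
    if gene not in set(ann["gene"].dropna()):
        raise KeyError(f"unknown gene {gene!r}")
    with np.errstate(invalid="ignore"):
        f = np.nansum(gm.dosage, axis=0) / (2.0 * np.sum(np.isfinite(gm.dosage), axis=0))
    maf = np.minimum(f, 1.0 - f)
    keep = (
        (ann["gene"] == gene).to_numpy()
        & (ann["impact"] == "moderate").to_numpy()
        & np.isfinite(maf)
        & (maf < maf_max)
    )
    rule = "nonsyn_rare"
    if damaging_only:
        if "damaging" not in ann.columns:
            raise ValueError("damaging_only requires a damaging annotation column")
        keep &= ann["damaging"].to_numpy().astype(bool)
        rule = "nonsyn_rare_damaging"
    cols = np.flatnonzero(keep)
    return VariantSet(gene=gene, rule=rule, variant_ids=[ann["variant_id"].iloc[j] for j in cols], columns=cols)


def carrier_proportion(gm: GenotypeMatrix, vset: VariantSet) -> float:
    """Fraction of samples carrying >= 1 (non-missing) minor allele across
    the set; samples missing at every member drop out of the denominator."""
    if len(vset) == 0:
        raise ValueError(f"gene {vset.gene!r}: empty variant set")
    dos = gm.dosage[:, vset.columns]
    any_called = np.isfinite(dos).any(axis=1)
    carriers = np.nansum(dos, axis=1) >= 1
    return float(np.mean(carriers[any_called]))


# ----------------------------------------------------------------------
# burden
# ----------------------------------------------------------------------
def burden_test(
    gm: GenotypeMatrix,
    vset: VariantSet,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    scope: str = "",
    carrier_indicator: bool = False,
) -> GeneTestResult:
    """Logistic regression of case status on the per-subject minor-allele
    count over the set (missing dosage -> 0). ``carrier_indicator`` switches
    to a 0/1 any-carrier burden."""
    res = GeneTestResult(gene=vset.gene, scope=scope, rule=vset.rule, n_variants=len(vset))
    if len(vset) == 0:
        res.note = "empty variant set"
        log.info("burden_test: %s", res.note)
        return res
    res.carrier_proportion = carrier_proportion(gm, vset)
    burden = np.nansum(gm.dosage[:, vset.columns], axis=1)
    if carrier_indicator:
        burden = (burden >= 1).astype(float)
    if burden.min() == burden.max():
        res.note = "zero-variance burden score"
        return res
    fit = fit_logistic(burden, phenotype, covariates=covariates)
    res.burden_beta, res.burden_se, res.burden_p = fit.beta, fit.se, fit.p
    res.evaluable = fit.evaluable
    res.note = fit.note
    return res


# ----------------------------------------------------------------------
# SKAT
# ----------------------------------------------------------------------
def _beta_weights(maf: np.ndarray, weight_params=DEFAULT_WEIGHT_PARAMS) -> np.ndarray:
    a, b = weight_params
    return stats.beta.pdf(np.clip(maf, 1e-12, 1.0 - 1e-12), a, b)


def skat_components(
    gm: GenotypeMatrix,
    vset: VariantSet,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
) -> SkatComponents:
    """Score vector and projected information of one cohort (weights are
    applied later, from the pooled MAF across cohorts)."""
    y = np.asarray(phenotype, dtype=float)
    G = gm.dosage[:, vset.columns]
    called = np.isfinite(G)
    alt = np.nansum(G, axis=0)
    n_chrom = 2.0 * called.sum(axis=0)
    G = np.where(called, G, 0.0)
    n = G.shape[0]
    X = np.column_stack([np.ones(n)] + ([np.atleast_2d(covariates).reshape(n, -1)] if covariates is not None else []))
    b, _, _, ok = _irls(X, y)
    if not ok:
        raise ArithmeticError("null model fit failed")
    mu = 1.0 / (1.0 + np.exp(-(X @ b)))
    v = mu * (1.0 - mu)
    S = G.T @ (y - mu)
    VX = X * v[:, None]
    XtVX_inv = np.linalg.inv(X.T @ VX)
    GtVX = G.T @ VX
    B = (G.T * v) @ G - GtVX @ XtVX_inv @ GtVX.T
    return SkatComponents(variant_ids=list(vset.variant_ids), score=S, info=B, alt_alleles=alt, n_chromosomes=n_chrom)


def _skat_from_components(comp: SkatComponents, weights: np.ndarray) -> tuple[float, float, str]:
    q = float(np.sum(weights**2 * comp.score**2))
    W = np.diag(weights)
    A = W @ comp.info @ W
    lam = np.clip(np.linalg.eigvalsh(0.5 * (A + A.T)), 0.0, None)
    if lam.max() <= 0:
        raise ArithmeticError("degenerate SKAT kernel")
    p, method = weighted_chisq_sf(q, lam)
    return q, p, method


def skat_test(
    gm: GenotypeMatrix,
    vset: VariantSet,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    weight_params=DEFAULT_WEIGHT_PARAMS,
    scope: str = "",
) -> GeneTestResult:
    """Sequence kernel association test with Beta-density MAF weights."""
    res = GeneTestResult(gene=vset.gene, scope=scope, rule=vset.rule, n_variants=len(vset))
    if len(vset) == 0:
        res.note = "empty variant set"
        log.info("skat_test: %s", res.note)
        return res
    res.carrier_proportion = carrier_proportion(gm, vset)
    y = np.asarray(phenotype, dtype=float)
    if y.min() == y.max():
        res.note = "single phenotype class"
        return res
    try:
        comp = skat_components(gm, vset, y, covariates)
        maf = comp.alt_alleles / np.maximum(comp.n_chromosomes, 1.0)
        maf = np.minimum(maf, 1.0 - maf)
        w = _beta_weights(maf, weight_params)
        q, p, method = _skat_from_components(comp, w)
    except ArithmeticError as exc:
        res.note = str(exc)
        return res
    res.skat_q, res.skat_p = q, p
    res.evaluable = True
    res.note = method
    return res


# ----------------------------------------------------------------------
# cross-population meta
# ----------------------------------------------------------------------
def meta_burden(results: list[GeneTestResult]) -> GeneTestResult:
    """Inverse-variance fixed-effect combination of per-population burden
    log-ORs (exactly the single-SNV meta arithmetic)."""
    usable = [r for r in results if r.evaluable and np.isfinite(r.burden_se)]
    if not usable:
        raise ValueError("no evaluable population burden results")
    w = np.array([1.0 / r.burden_se**2 for r in usable])
    betas = np.array([r.burden_beta for r in usable])
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    z = beta / se
    out = GeneTestResult(
        gene=usable[0].gene,
        scope="meta",
        rule=usable[0].rule,
        n_variants=max(r.n_variants for r in usable),
        burden_beta=beta,
        burden_se=se,
        burden_p=float(max(2.0 * stats.norm.sf(abs(z)), 1e-300)),
        evaluable=True,
        note=",".join(r.scope for r in usable),
    )
    return out


def meta_skat_hom(
    components: list[SkatComponents],
    weight_params=DEFAULT_WEIGHT_PARAMS,
    gene: str = "",
    rule: str = "",
) -> GeneTestResult:
    """Hom-Meta-SKAT: per-variant scores and projected information matrices
    are summed across populations (variants absent from a population
    contribute zero of each), weights come from the pooled MAF, and the
    statistic/null distribution are formed exactly as in ``skat_test``."""
    if not components:
        raise ValueError("no population components supplied")
    keys: list[str] = []
    for comp in components:
        for vid in comp.variant_ids:
            if vid not in keys:
                keys.append(vid)
    m = len(keys)
    pos = {v: i for i, v in enumerate(keys)}
    S = np.zeros(m)
    B = np.zeros((m, m))
    alt = np.zeros(m)
    n_chrom = np.zeros(m)
    for comp in components:
        idx = np.array([pos[v] for v in comp.variant_ids])
        S[idx] += comp.score
        B[np.ix_(idx, idx)] += comp.info
        alt[idx] += comp.alt_alleles
        n_chrom[idx] += comp.n_chromosomes
    maf = alt / np.maximum(n_chrom, 1.0)
    maf = np.minimum(maf, 1.0 - maf)
    merged = SkatComponents(variant_ids=keys, score=S, info=B, alt_alleles=alt, n_chromosomes=n_chrom)
    res = GeneTestResult(gene=gene, scope="meta", rule=rule, n_variants=m)
    try:
        q, p, method = _skat_from_components(merged, _beta_weights(maf, weight_params))
    except ArithmeticError as exc:
        res.note = str(exc)
        return res
    res.skat_q, res.skat_p = q, p
    res.evaluable = True
    res.note = method
    return res


def bonferroni_threshold(n_tests_performed: int, alpha: float = 0.05) -> float:
    """Gene-level significance threshold: alpha over the number of gene x
    selection-rule tests actually performed."""
    if n_tests_performed < 1:
        raise ValueError("no tests performed")
    return alpha / n_tests_performed


def gene_results_frame(results: list[GeneTestResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        lo, hi = r.burden_ci95 if np.isfinite(r.burden_se) else (np.nan, np.nan)
        rows.append(
            dict(gene=r.gene, scope=r.scope, rule=r.rule, n_variants=r.n_variants,
                 carrier_proportion=r.carrier_proportion, burden_beta=r.burden_beta,
                 burden_se=r.burden_se, burden_or=np.exp(r.burden_beta),
                 burden_ci_low=lo, burden_ci_high=hi, burden_p=r.burden_p,
                 skat_q=r.skat_q, skat_p=r.skat_p, evaluable=r.evaluable, note=r.note)
        )
    return pd.DataFrame(rows)
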