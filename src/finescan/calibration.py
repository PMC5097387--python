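"""Simulation studies that validate the pipeline's statistical calibration.

These harnesses are the package's own operating characteristics: frequentist
coverage of the credible set under a single-causal generative model, type-I
error of the association and rare-variant tests, effect-size recovery, and
signal absorption by conditional scans. They are consumed by the test suite
and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.random import SeedSequence, default_rng
from scipy.special import expit

from .assoc import fit_logistic, scan_region
from .core import GenotypeMatrix
from .finemap import credible_set, posteriors_from_logliks
from .rare import VariantSet, burden_test, meta_skat_hom, skat_components, skat_test
from .simulate import (
    DiseaseModel,
    PopulationSpec,
    RegionSpec,
    simulate_cohort,
    simulate_panel,
    simulate_single_causal_region,
)


@dataclass
class CoverageResult:
    n_regions: int
    n_covered: int
    mean_pps_size: float

    @property
    def coverage_pct(self) -> float:
        return 100.0 * self.n_covered / self.n_regions


def pps_coverage(
    seed,
    n_regions: int = 500,
    mass: float = 0.90,
    n_variants: int = 200,
    founder_haplotypes: int = 30,
    switch_prob: float = 0.01,
    divergence_F: float = 0.01,
    n_cases: int = 2000,
    n_controls: int = 2000,
    target_maf: float = 0.2,
    odds_ratio: float = 1.5,
) -> CoverageResult:
    """Frequentist coverage of the credible set over single-causal regions.

    Each replicate simulates a founder-mosaic region with one causal common
    SNV, runs the single-SNV logistic scan, forms likelihood-ratio
    posteriors, builds the credible set at ``mass``, and records whether the
    causal SNV is a member. A well-calibrated construction covers the causal
    variant in about ``mass`` of regions.
    """
    ss = SeedSequence(seed)
    covered = 0
    sizes = []
    for region_seed in ss.spawn(n_regions):
        gm, sheet, causal = simulate_single_causal_region(
            seed=region_seed,
            n_variants=n_variants,
            founder_haplotypes=founder_haplotypes,
            switch_prob=switch_prob,
            divergence_F=divergence_F,
            n_cases=n_cases,
            n_controls=n_controls,
            target_maf=target_maf,
            odds_ratio=odds_ratio,
        )
        results = scan_region(gm, sheet)
        logliks = np.array([r.loglik if r.evaluable else np.nan for r in results])
        pi = posteriors_from_logliks(logliks)
        ps = credible_set(pi, mass=mass, variant_ids=gm.variant_ids)
        covered += bool(ps.member[causal])
        sizes.append(ps.size)
    return CoverageResult(n_regions=n_regions, n_covered=covered, mean_pps_size=float(np.mean(sizes)))


# ----------------------------------------------------------------------
def single_snv_type1(seed, n_tests: int = 2000, n_cases: int = 500, n_controls: int = 500) -> float:
    """Fraction of null single-SNV Wald tests with p < 0.05."""
    ss = SeedSequence(seed)
    s_panel, s_cohort = ss.spawn(2)
    region = RegionSpec("null", int(n_tests * 1.05) + 20, founder_haplotypes=200,
                        switch_prob=0.5, common_fraction=1.0)
    pop = PopulationSpec("P", n_cases, n_controls, divergence_F=0.05)
    panel = simulate_panel(region, [pop], s_panel)
    gm, sheet = simulate_cohort(panel, DiseaseModel(), [pop], s_cohort, read_stats=None)
    ps = np.array([r.p for r in scan_region(gm, sheet) if r.evaluable])
    if ps.size < n_tests:
        raise RuntimeError(f"only {ps.size} evaluable null tests")
    return float(np.mean(ps[:n_tests] < 0.05))


def _null_gene(rng, n, m):
    maf = rng.uniform(0.002, 0.008, m)
    dosage = rng.binomial(2, maf, (n, m)).astype(float)
    import pandas as pd

    variants = pd.DataFrame(
        {"variant_id": [f"g:{j}" for j in range(m)], "chrom": "g", "pos": range(m),
         "ref": "A", "alt": "G", "region_id": "g"}
    )
    gm = GenotypeMatrix(dosage=dosage, samples=[f"s{i}" for i in range(n)], variants=variants)
    vset = VariantSet("g", "nonsyn_rare", list(variants["variant_id"]), np.arange(m))
    return gm, vset


def rare_test_type1(seed, n_genes: int = 2000, n_cases: int = 500, n_controls: int = 500,
                    m_variants: int = 10) -> dict:
    """Empirical p<0.05 rates of burden, SKAT, and two-population
    Hom-Meta-SKAT over null genes (independent rare genotypes, label
    phenotype)."""
    rng = default_rng(SeedSequence(seed))
    n = n_cases + n_controls
    y = np.array([1.0] * n_cases + [0.0] * n_controls)
    hits = {"burden": [], "skat": [], "hom_meta_skat": []}
    for _ in range(n_genes):
        gm, vset = _null_gene(rng, n, m_variants)
        yy = rng.permutation(y)
        bt = burden_test(gm, vset, yy)
        if bt.evaluable:
            hits["burden"].append(bt.burden_p < 0.05)
        sk = skat_test(gm, vset, yy)
        if sk.evaluable:
            hits["skat"].append(sk.skat_p < 0.05)
        half = np.arange(n) % 2 == 0
        try:
            comps = [skat_components(gm.take_samples(mask), vset, yy[mask]) for mask in (half, ~half)]
            meta = meta_skat_hom(comps)
            if meta.evaluable:
                hits["hom_meta_skat"].append(meta.skat_p < 0.05)
        except ArithmeticError:
            pass
    return {k: float(np.mean(v)) for k, v in hits.items()}


# ----------------------------------------------------------------------
def odds_ratio_recovery(seed, n_seeds: int = 50, odds_ratio: float = 1.5,
                        n_cases: int = 2000, n_controls: int = 2000) -> float:
    """Mean fitted odds ratio at the causal SNV across replicates."""
    ors = []
    for s in SeedSequence(seed).spawn(n_seeds):
        gm, sheet, causal = simulate_single_causal_region(
            seed=s, n_cases=n_cases, n_controls=n_controls, odds_ratio=odds_ratio)
        y = (sheet["status"] == "case").to_numpy(dtype=float)
        res = fit_logistic(gm.dosage[:, causal], y)
        if res.evaluable:
            ors.append(res.odds_ratio)
    return float(np.mean(ors))


def conditional_suppression(seed, n_seeds: int = 20, r2_min: float = 0.8,
                            n_cases: int = 2000, n_controls: int = 2000) -> dict:
    """Mean |z| at strong LD proxies (r^2 > r2_min) of the causal SNV,
    before and after conditioning on it. Regions use a small founder pool
    and low switch probability so such proxies exist."""
    plain_z, cond_z = [], []
    for s in SeedSequence(seed).spawn(n_seeds):
        gm, sheet, causal = simulate_single_causal_region(
            seed=s, n_cases=n_cases, n_controls=n_controls,
            founder_haplotypes=6, switch_prob=0.001)
        d = gm.dosage
        cc = d[:, causal]
        proxies = []
        for j in range(gm.n_variants):
            if j == causal or d[:, j].std() == 0:
                continue
            if np.corrcoef(d[:, j], cc)[0, 1] ** 2 > r2_min:
                proxies.append(j)
        if not proxies:
            continue
        vid = gm.variant_ids[causal]
        plain = scan_region(gm, sheet)
        cond = scan_region(gm, sheet, condition_on=[vid])
        for j in proxies:
            if plain[j].evaluable:
                plain_z.append(abs(plain[j].z))
            if cond[j].evaluable:
                cond_z.append(abs(cond[j].z))
    return {
        "n_proxies": len(cond_z),
        "mean_abs_z_unconditioned": float(np.mean(plain_z)) if plain_z else np.nan,
        "mean_abs_z_conditioned": float(np.mean(cond_z)) if cond_z else np.nan,
    }
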