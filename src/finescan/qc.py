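"""Genotype-, variant- and sample-level quality control.

The cascade mirrors common deep-targeted-sequencing practice: individual
genotypes with too few reads (<5) or low quality (<10) are set to missing;
variants are dropped when too many samples have no reads (>10%), the total
read count is low (<20,000), missingness is high (>10%), or Hardy-Weinberg
equilibrium is violated (exact p < 1e-6) in any ancestry group; samples are
dropped for low call rate (<90%), low concordance with external genotypes
(<90%), or as one of an unexpected duplicate pair. All "<"/">" thresholds
are exclusive, so a genotype with exactly 5 reads passes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .core import NO_READS, GenotypeMatrix

log = logging.getLogger(__name__)

VARIANT_RULES = ("no_reads", "total_depth", "missingness", "hwe")
SAMPLE_RULES = ("call_rate", "concordance", "duplicate")


@dataclass
class QcThresholds:
    min_depth: int = 5
    min_gq: int = 10
    max_missing: float = 0.10
    min_total_reads: int = 20_000
    max_nodata_samples: float = 0.10
    hwe_p_min: float = 1e-6
    min_call_rate: float = 0.90
    min_concordance: float = 0.90
    duplicate_concordance: float = 0.99
    hwe_controls_only: bool = False

    def __post_init__(self) -> None:
        for name in ("max_missing", "max_nodata_samples", "min_call_rate", "min_concordance", "duplicate_concordance"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a proportion in [0, 1]")


@dataclass
class QcReport:
    """Per-rule removal counts plus in/out dimensions."""

    n_samples_in: int = 0
    n_variants_in: int = 0
    n_samples_out: int = 0
    n_variants_out: int = 0
    genotypes_masked: int = 0
    variant_removals: dict = field(default_factory=lambda: {r: 0 for r in VARIANT_RULES})
    sample_removals: dict = field(default_factory=lambda: {r: 0 for r in SAMPLE_RULES})

    def check_consistent(self) -> bool:
        return (
            self.n_variants_in - sum(self.variant_removals.values()) == self.n_variants_out
            and self.n_samples_in - sum(self.sample_removals.values()) == self.n_samples_out
        )


# ----------------------------------------------------------------------
def mask_low_quality_genotypes(gm: GenotypeMatrix, thresholds: QcThresholds = QcThresholds()) -> tuple[GenotypeMatrix, int]:
    """Set genotypes with DP < min_depth or GQ < min_gq to missing.

    Returns the masked matrix and the number of newly masked genotypes.
    A matrix without DP/GQ side channels is returned unchanged (warning).
    """
    if gm.depth is None and gm.qual is None:
        log.warning("mask_low_quality_genotypes: no DP/GQ side channels; no-op")
        return gm.copy(), 0
    out = gm.copy()
    bad = np.zeros(out.dosage.shape, dtype=bool)
    if out.depth is not None:
        bad |= (out.depth != NO_READS) & (out.depth < thresholds.min_depth)
        bad |= out.depth == NO_READS  # no read information at all
    if out.qual is not None:
        bad |= (out.qual != NO_READS) & (out.qual < thresholds.min_gq)
    newly = int(np.sum(bad & np.isfinite(out.dosage)))
    out.dosage[bad] = np.nan
    return out, newly


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    Given the observed allele counts, sums the probabilities of all
    heterozygote counts whose conditional probability does not exceed the
    observed one (two-sided, by probability ordering).
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_alt = n_het + 2 * n_hom_alt
    n_minor = min(n_alt, 2 * n - n_alt)
    if n_minor == 0:
        return 1.0
    # heterozygote counts share the parity of the minor-allele count
    h = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_min = (n_minor - h) // 2
    hom_maj = n - h - hom_min
    # log P(h | allele counts) up to a shared constant
    logp = -(gammaln(hom_min + 1) + gammaln(h + 1) + gammaln(hom_maj + 1)) + h * np.log(2.0)
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs = int(n_het)
    p_obs = prob[np.flatnonzero(h == obs)[0]]
    return float(min(1.0, prob[prob <= p_obs * (1.0 + 1e-12)].sum()))


def hwe_pvalues(gm: GenotypeMatrix, sample_mask=None) -> np.ndarray:
    """Exact HWE p per variant over the selected samples (NaN when no calls)."""
    dos = gm.dosage if sample_mask is None else gm.dosage[np.asarray(sample_mask)]
    out = np.full(gm.n_variants, np.nan)
    for j in range(gm.n_variants):
        col = dos[:, j]
        col = col[np.isfinite(col)]
        if col.size == 0:
            continue
        out[j] = hwe_exact_test(int(np.sum(col == 0)), int(np.sum(col == 1)), int(np.sum(col == 2)))
    return out


def filter_variants(
    gm: GenotypeMatrix,
    thresholds: QcThresholds,
    populations,
    status=None,
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop variants failing the no-reads / total-depth / missingness / HWE
    rules (attributed to the first rule tripped, in that order).

    ``populations`` gives one ancestry label per sample; HWE is evaluated in
    every group and a variant fails if any group's exact p < hwe_p_min.
    With ``thresholds.hwe_controls_only`` a ``status`` vector restricts the
    HWE computation to controls.
    """
    populations = np.asarray(populations)
    if populations.shape[0] != gm.n_samples:
        raise ValueError("one population label per sample required")
    report = QcReport(n_samples_in=gm.n_samples, n_variants_in=gm.n_variants, n_samples_out=gm.n_samples)

    fail_rule = np.full(gm.n_variants, "", dtype=object)

    if gm.depth is not None:
        depth = np.where(gm.depth == NO_READS, 0, gm.depth)
        nodata = np.mean(depth == 0, axis=0)
        fail_rule[(fail_rule == "") & (nodata > thresholds.max_nodata_samples)] = "no_reads"
        total = depth.sum(axis=0)
        fail_rule[(fail_rule == "") & (total < thresholds.min_total_reads)] = "total_depth"
    else:
        log.warning("filter_variants: no depth side channel; read-based rules skipped")

    missing = np.mean(~np.isfinite(gm.dosage), axis=0)
    fail_rule[(fail_rule == "") & (missing > thresholds.max_missing)] = "missingness"

    hwe_samples = np.ones(gm.n_samples, dtype=bool)
    if thresholds.hwe_controls_only:
        if status is None:
            raise ValueError("hwe_controls_only requires a status vector")
        hwe_samples = np.asarray(status) == "control"
    labels = set(populations)
    undecided = fail_rule == ""
    for label in sorted(labels):
        in_pop = (populations == label) & hwe_samples
        if not in_pop.any():
            continue
        sub = gm.dosage[in_pop][:, undecided]
        cols = np.flatnonzero(undecided)
        for k, j in enumerate(cols):
            col = sub[:, k]
            col = col[np.isfinite(col)]
            if col.size == 0:
                continue
            p = hwe_exact_test(int(np.sum(col == 0)), int(np.sum(col == 1)), int(np.sum(col == 2)))
            if p < thresholds.hwe_p_min:
                fail_rule[j] = "hwe"
        undecided = fail_rule == ""

    for rule in VARIANT_RULES:
        report.variant_removals[rule] = int(np.sum(fail_rule == rule))
    keep = fail_rule == ""
    out = gm.take_variants(keep)
    report.n_variants_out = out.n_variants
    return out, report


def _pairwise_concordance(a: np.ndarray, b: np.ndarray) -> float:
    both = np.isfinite(a) & np.isfinite(b)
    if not both.any():
        return np.nan
    return float(np.mean(a[both] == b[both]))


def filter_samples(
    gm: GenotypeMatrix,
    thresholds: QcThresholds,
    external: GenotypeMatrix | None = None,
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop samples with low call rate, low concordance with an external
    genotype table (at overlapping variants), and unexpected duplicates
    (pairwise concordance > duplicate_concordance; the lexicographically
    larger id of each pair is dropped)."""
    report = QcReport(n_samples_in=gm.n_samples, n_variants_in=gm.n_variants, n_variants_out=gm.n_variants)
    drop_rule: dict[str, str] = {}

    call_rate = np.mean(np.isfinite(gm.dosage), axis=1) if gm.n_variants else np.ones(gm.n_samples)
    for i, s in enumerate(gm.samples):
        if call_rate[i] < thresholds.min_call_rate:
            drop_rule[s] = "call_rate"

    if external is not None:
        shared_vars = [v for v in gm.variant_ids if v in set(external.variant_ids)]
        shared_samples = [s for s in gm.samples if s in set(external.samples)]
        if not shared_vars:
            log.warning("filter_samples: no overlapping variants with external table; concordance not evaluable")
        else:
            gi = {v: k for k, v in enumerate(gm.variant_ids)}
            ei = {v: k for k, v in enumerate(external.variant_ids)}
            gcols = [gi[v] for v in shared_vars]
            ecols = [ei[v] for v in shared_vars]
            ext_row = {s: k for k, s in enumerate(external.samples)}
            for i, s in enumerate(gm.samples):
                if s in drop_rule or s not in ext_row:
                    continue
                c = _pairwise_concordance(gm.dosage[i, gcols], external.dosage[ext_row[s], ecols])
                if np.isfinite(c) and c < thresholds.min_concordance:
                    drop_rule[s] = "concordance"

    # duplicate detection among samples still standing, via one-hot matmuls
    standing = [i for i, s in enumerate(gm.samples) if s not in drop_rule]
    if len(standing) > 1 and gm.n_variants > 0:
        D = gm.dosage[standing]
        finite = np.isfinite(D)
        eq = np.zeros((len(standing), len(standing)))
        for val in (0.0, 1.0, 2.0):
            ind = (D == val).astype(float)
            eq += ind @ ind.T
        both = finite.astype(float) @ finite.astype(float).T
        with np.errstate(invalid="ignore", divide="ignore"):
            conc = eq / both
        for a in range(len(standing)):
            for b in range(a + 1, len(standing)):
                if np.isfinite(conc[a, b]) and conc[a, b] > thresholds.duplicate_concordance:
                    sa, sb = gm.samples[standing[a]], gm.samples[standing[b]]
                    victim = max(sa, sb)
                    if victim not in drop_rule:
                        drop_rule[victim] = "duplicate"

    keep = np.array([s not in drop_rule for s in gm.samples])
    for rule in SAMPLE_RULES:
        report.sample_removals[rule] = sum(1 for r in drop_rule.values() if r == rule)
    out = gm.take_samples(keep)
    report.n_samples_out = out.n_samples
    return out, report


def allele_frequency(gm: GenotypeMatrix, populations=None, population: str | None = None) -> np.ndarray:
    """Per-variant minor allele frequency, pooled or within one population;
    missing genotypes drop out of the denominator (all-missing -> NaN)."""
    mask = None
    if population is not None:
        if populations is None:
            raise ValueError("population selection requires the label vector")
        mask = np.asarray(populations) == population
        if not mask.any():
            raise ValueError(f"unknown population {population!r}")
    dos = gm.dosage if mask is None else gm.dosage[mask]
    called = np.sum(np.isfinite(dos), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.nansum(dos, axis=0) / (2.0 * called)
    return np.minimum(f, 1.0 - f)
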