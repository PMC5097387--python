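"""Synthetic multiethnic case-control sequencing cohorts with ground truth.

The generator emulates a targeted-sequencing fine-mapping study: a handful of
GWAS regions sequenced in several ancestry groups, with an abundance of rare
and population-private variation, block linkage disequilibrium, and a known
logistic disease model. Every downstream stage (QC, association, credible
sets, rare-variant tests) can therefore be validated against known truth.

Model
-----
* Ancestral allele frequencies are drawn from a mixture: with probability
  ``common_fraction`` uniform on the common range [0.005, 0.5], otherwise
  from a neutral-shaped density proportional to 1/x on
  [1/(4*founder_haplotypes), 0.005].
* Population frequencies follow the Balding-Nichols model,
  ``p_k ~ Beta(p(1-F)/F, (1-p)(1-F)/F)`` with per-population divergence F.
* Each population carries a founder haplotype pool drawn site-wise at p_k;
  sample haplotypes are founder mosaics with a per-adjacent-site switch
  probability, producing tunable block LD without a coalescent simulator.
* Disease status is Bernoulli(logistic(alpha + sum beta_j g_j)) with the
  intercept calibrated by bisection so the population prevalence of a
  50,000-individual calibration pool matches ``baseline_prevalence``.
  Cases/controls are rejection-sampled to exact per-population targets.
* Per-genotype read depth (Poisson) and genotype quality (clipped normal)
  side channels feed the QC stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.random import SeedSequence, default_rng
from scipy.special import expit, logit

from .core import GenotypeMatrix, variant_key

log = logging.getLogger(__name__)

IMPACT_CLASSES = ("high", "moderate", "low", "modifier")

#: impact-class mix of a deep targeted-sequencing SNV catalogue
#: (disruptive / nonsynonymous / synonymous / noncoding)
DEFAULT_IMPACT_PROPORTIONS = np.array([81, 1983, 1374, 134092], dtype=float) / 137530.0


# ----------------------------------------------------------------------
# specs
# ----------------------------------------------------------------------
@dataclass
class RegionSpec:
    """One sequenced region.

    ``founder_haplotypes`` controls both LD (mosaics copy from a finite
    pool) and the lower bound 1/(4*founder_haplotypes) of the rare-frequency
    spectrum; ``switch_prob`` is the per-adjacent-variant mosaic
    recombination probability.
    """

    region_id: str
    n_variants: int
    founder_haplotypes: int = 1000
    switch_prob: float = 0.01
    common_fraction: float = 0.128
    chrom: str | None = None
    start: int = 1_000_000
    spacing: int = 150

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if self.founder_haplotypes < 2:
            raise ValueError("founder_haplotypes must be >= 2")
        if not 0.0 <= self.switch_prob <= 1.0:
            raise ValueError("switch_prob must be in [0, 1]")
        if not 0.0 <= self.common_fraction <= 1.0:
            raise ValueError("common_fraction must be in [0, 1]")

    @property
    def positions(self) -> np.ndarray:
        return self.start + self.spacing * np.arange(self.n_variants)

    @property
    def end(self) -> int:
        return int(self.positions[-1])


@dataclass
class PopulationSpec:
    label: str
    n_cases: int
    n_controls: int
    divergence_F: float
    private_rare_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_cases + self.n_controls < 2:
            raise ValueError("need at least 2 individuals")
        if not 0.0 < self.divergence_F < 1.0:
            raise ValueError("divergence_F must be in (0, 1)")
        if self.private_rare_rate < 0:
            raise ValueError("private_rare_rate must be >= 0")


@dataclass
class DiseaseModel:
    """Logistic disease model: keys of ``causal_effects`` are
    ``(region_id, variant_index)`` pairs (or ``"region:index"`` strings),
    values are per-allele log odds ratios."""

    baseline_prevalence: float = 0.10
    causal_effects: dict = field(default_factory=dict)
    er_neg_fraction: float = 393.0 / 2288.0

    def __post_init__(self) -> None:
        if not 0.0 < self.baseline_prevalence < 1.0:
            raise ValueError("baseline_prevalence must be in (0, 1)")
        if not 0.0 <= self.er_neg_fraction <= 1.0:
            raise ValueError("er_neg_fraction must be in [0, 1]")
        effects = {}
        for key, beta in self.causal_effects.items():
            if isinstance(key, str):
                rid, idx = key.rsplit(":", 1)
                key = (rid, int(idx))
            if not np.isfinite(beta):
                raise ValueError(f"non-finite effect for {key}")
            effects[(str(key[0]), int(key[1]))] = float(beta)
        self.causal_effects = effects


@dataclass
class ReadStatsModel:
    """Per-genotype DP ~ Poisson(mean_depth), GQ ~ round(N(gq_mean, gq_sd))
    clipped to [0, 99]; genotypes with zero reads get GQ 0."""

    mean_depth: float = 50.0
    gq_mean: float = 60.0
    gq_sd: float = 15.0


@dataclass
class HaplotypePanel:
    """Per-population founder haplotype pools for one region."""

    region: RegionSpec
    founders: dict  # label -> (H, L) uint8
    p: np.ndarray  # ancestral frequencies
    p_k: dict  # label -> (L,) population frequencies
    private_owner: np.ndarray | None = None  # label or "" per variant

    def founder_frequency(self, label: str) -> np.ndarray:
        return self.founders[label].mean(axis=0)


def default_populations() -> list[PopulationSpec]:
    """The study conditions: four ancestry groups totalling 2288 cases and
    2323 controls (AA 937, JA 1256, HI 907, EU 1511)."""
    return [
        PopulationSpec("AA", 468, 469, divergence_F=0.12, private_rare_rate=25.0),
        PopulationSpec("JA", 622, 634, divergence_F=0.10, private_rare_rate=25.0),
        PopulationSpec("HI", 452, 455, divergence_F=0.06, private_rare_rate=25.0),
        PopulationSpec("EU", 746, 765, divergence_F=0.08, private_rare_rate=25.0),
    ]


# ----------------------------------------------------------------------
# founder panel
# ----------------------------------------------------------------------
def simulate_panel(region: RegionSpec, pops: list[PopulationSpec], seed) -> HaplotypePanel:
    """Draw ancestral/population frequencies and founder haplotype pools."""
    rng = default_rng(seed)
    L, H = region.n_variants, region.founder_haplotypes

    is_common = rng.random(L) < region.common_fraction
    p = np.empty(L)
    p[is_common] = rng.uniform(0.005, 0.5, is_common.sum())
    n_rare = int((~is_common).sum())
    if n_rare:
        a, b = 1.0 / (4.0 * H), 0.005
        if a >= b:
            raise ValueError(
                f"founder pool of {H} haplotypes cannot host the rare spectrum "
                f"(1/(4H)={a:.4g} >= 0.005); enlarge founder_haplotypes or set "
                "common_fraction=1"
            )
        # inverse-CDF sampling from density ∝ 1/x on [a, b]
        p[~is_common] = a * (b / a) ** rng.random(n_rare)

    founders, p_k = {}, {}
    for pop in pops:
        F = pop.divergence_F
        pk = rng.beta(p * (1.0 - F) / F, (1.0 - p) * (1.0 - F) / F)
        founders[pop.label] = (rng.random((H, L)) < pk).astype(np.uint8)
        p_k[pop.label] = pk

    # population-private rare variants
    owner = np.full(L, "", dtype=object)
    rare_idx = np.flatnonzero(~is_common)
    for pop in pops:
        if pop.private_rare_rate <= 0:
            continue
        n_priv = rng.poisson(pop.private_rare_rate)
        eligible = rare_idx[owner[rare_idx] == ""]
        n_priv = min(n_priv, eligible.size)
        if n_priv == 0:
            continue
        chosen = rng.choice(eligible, size=n_priv, replace=False)
        owner[chosen] = pop.label
        for other in pops:
            if other.label != pop.label:
                founders[other.label][:, chosen] = 0
                p_k[other.label][chosen] = 0.0
        # guarantee the owner actually segregates the variant
        col = founders[pop.label][:, chosen]
        empty = np.flatnonzero(col.sum(axis=0) == 0)
        if empty.size:
            rows = rng.integers(0, H, empty.size)
            founders[pop.label][rows, chosen[empty]] = 1

    return HaplotypePanel(region=region, founders=founders, p=p, p_k=p_k, private_owner=owner)


# ----------------------------------------------------------------------
# mosaic haplotype sampling
# ----------------------------------------------------------------------
def _mosaic_haplotypes(founders: np.ndarray, n_hap: int, switch_prob: float, rng) -> np.ndarray:
    """Sample ``n_hap`` founder-mosaic haplotypes over all sites."""
    H, L = founders.shape
    if switch_prob <= 0.0:
        idx = rng.integers(0, H, n_hap)
        return founders[idx]
    switch = rng.random((n_hap, L), dtype=np.float32) < switch_prob
    switch[:, 0] = True
    new_idx = rng.integers(0, H, (n_hap, L), dtype=np.int32)
    cols = np.arange(L, dtype=np.int32)
    # index of the most recent switch, then gather the founder chosen there
    last = np.maximum.accumulate(cols * switch, axis=1)
    founder_idx = np.take_along_axis(new_idx, last, axis=1)
    return founders[founder_idx, cols]


def _mosaic_at_columns(founders: np.ndarray, n_hap: int, switch_prob: float, cols: np.ndarray, rng) -> np.ndarray:
    """Exact marginal of the mosaic process restricted to ``cols``.

    The founder-index process refreshes to uniform with probability
    ``switch_prob`` per step, so across a gap of d steps it is redrawn with
    probability 1-(1-switch_prob)^d and kept otherwise.
    """
    H = founders.shape[0]
    cols = np.sort(np.asarray(cols))
    out = np.empty((n_hap, cols.size), dtype=founders.dtype)
    idx = rng.integers(0, H, n_hap)
    out[:, 0] = founders[idx, cols[0]]
    for j in range(1, cols.size):
        d = cols[j] - cols[j - 1]
        refresh = rng.random(n_hap) >= (1.0 - switch_prob) ** d
        idx = np.where(refresh, rng.integers(0, H, n_hap), idx)
        out[:, j] = founders[idx, cols[j]]
    return out


# ----------------------------------------------------------------------
# cohort sampling
# ----------------------------------------------------------------------
def _causal_layout(panels: list[HaplotypePanel], model: DiseaseModel):
    """Map causal effects to (panel_index, column) with global betas."""
    by_region = {pan.region.region_id: i for i, pan in enumerate(panels)}
    entries = []
    for (rid, idx), beta in sorted(model.causal_effects.items()):
        if rid not in by_region:
            raise ValueError(f"causal variant region {rid!r} not in panels")
        pan = panels[by_region[rid]]
        if not 0 <= idx < pan.region.n_variants:
            raise ValueError(f"causal variant index {idx} outside region {rid!r}")
        entries.append((by_region[rid], idx, beta))
    return entries


def _calibrate_intercept(panels, entries, model, pops, rng, pool_size=50_000) -> float:
    """Bisection of the logistic intercept so the calibration-pool prevalence
    matches ``baseline_prevalence`` (within Monte-Carlo error of the pool)."""
    if not entries:
        return float(logit(model.baseline_prevalence))
    total = sum(p.n_cases + p.n_controls for p in pops)
    score = np.zeros(pool_size)
    start = 0
    for pop in pops:
        n_pop = max(2, round(pool_size * (pop.n_cases + pop.n_controls) / total))
        n_pop = min(n_pop, pool_size - start)
        if n_pop <= 0:
            break
        for pi in sorted({e[0] for e in entries}):
            pan = panels[pi]
            cols = np.array([idx for p, idx, _ in entries if p == pi])
            betas = np.array([b for p, _, b in entries if p == pi])
            h1 = _mosaic_at_columns(pan.founders[pop.label], n_pop, pan.region.switch_prob, cols, rng)
            h2 = _mosaic_at_columns(pan.founders[pop.label], n_pop, pan.region.switch_prob, cols, rng)
            order = np.argsort(cols)
            score[start : start + n_pop] += ((h1 + h2).astype(float) @ betas[order])
        start += n_pop
    score = score[:start]
    target = model.baseline_prevalence

    def gap(alpha):
        return expit(alpha + score).mean() - target

    lo, hi = -40.0, 40.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if gap(mid) < 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-10:
            break
    alpha = 0.5 * (lo + hi)
    if abs(gap(alpha)) > 0.002:
        raise RuntimeError("intercept calibration failed to reach target prevalence")
    return float(alpha)


def simulate_cohort(
    panels,
    model: DiseaseModel,
    pops: list[PopulationSpec],
    seed,
    read_stats: ReadStatsModel | None = ReadStatsModel(),
    er_model: DiseaseModel | None = None,
    calibration_pool: int = 50_000,
    max_pool: int | None = None,
):
    """Sample a case-control cohort from founder panels under ``model``.

    Individuals are formed from two mosaic haplotypes per region; disease
    probability is logistic in the causal genotypes; cases and controls are
    rejection-sampled to the exact per-population targets. Returns
    ``(GenotypeMatrix, sample_sheet)`` where the sample sheet has columns
    ``sample_id, population, status, er_status``.

    ``er_model``, when given, makes ER-negative status among cases depend on
    genotype through a second logistic model (its intercept is calibrated so
    the overall ER- fraction among cases matches ``model.er_neg_fraction``);
    by default ER status is assigned independently of genotype.
    """
    if isinstance(panels, HaplotypePanel):
        panels = [panels]
    entries = _causal_layout(panels, model)
    ss = SeedSequence(seed) if not isinstance(seed, SeedSequence) else seed
    calib_seed, sample_seed, side_seed = ss.spawn(3)
    alpha = _calibrate_intercept(panels, entries, model, pops, default_rng(calib_seed), calibration_pool)

    offsets = np.cumsum([0] + [pan.region.n_variants for pan in panels])
    L_tot = offsets[-1]
    causal_cols = np.array([offsets[pi] + idx for pi, idx, _ in entries], dtype=int)
    causal_beta = np.array([b for _, _, b in entries])

    pop_rngs = {pop.label: default_rng(s) for pop, s in zip(pops, sample_seed.spawn(len(pops)))}
    genos, rows = [], []
    prev = model.baseline_prevalence
    for pop in pops:
        rng = pop_rngs[pop.label]
        need_cases, need_controls = pop.n_cases, pop.n_controls
        kept_cases, kept_controls = [], []
        generated = 0
        cap = max_pool if max_pool is not None else int(
            64 + 60.0 * (need_cases / max(prev, 1e-6) + need_controls / max(1 - prev, 1e-6))
        )
        while len(kept_cases) < need_cases or len(kept_controls) < need_controls:
            if generated >= cap:
                raise RuntimeError(
                    f"population {pop.label}: generated {generated} individuals (pool cap {cap}) "
                    f"without reaching {need_cases} cases / {need_controls} controls "
                    f"(realized prevalence {len(kept_cases) / max(generated, 1):.4f}); "
                    "the case target is unattainable at this baseline_prevalence"
                )
            batch = int(
                1.25 * max(
                    (need_cases - len(kept_cases)) / max(prev, 1e-6),
                    (need_controls - len(kept_controls)) / max(1 - prev, 1e-6),
                )
            ) + 32
            batch = min(batch, cap - generated)
            G = np.empty((batch, L_tot), dtype=np.uint8)
            for pi, pan in enumerate(panels):
                hap = _mosaic_haplotypes(pan.founders[pop.label], 2 * batch, pan.region.switch_prob, rng)
                G[:, offsets[pi] : offsets[pi + 1]] = hap[:batch] + hap[batch:]
            eta = alpha + (G[:, causal_cols].astype(float) @ causal_beta if entries else 0.0)
            case = rng.random(batch) < expit(eta)
            generated += batch
            for i in np.flatnonzero(case):
                if len(kept_cases) < need_cases:
                    kept_cases.append(G[i])
            for i in np.flatnonzero(~case):
                if len(kept_controls) < need_controls:
                    kept_controls.append(G[i])
        pop_G = np.vstack(kept_cases + kept_controls)
        genos.append(pop_G)
        serial = np.arange(len(pop_G))
        for j in serial:
            rows.append(
                (
                    f"{pop.label}-{j:05d}",
                    pop.label,
                    "case" if j < need_cases else "control",
                )
            )
    G_all = np.vstack(genos).astype(float)
    sheet = pd.DataFrame(rows, columns=["sample_id", "population", "status"])

    # ER status among cases
    side_rng = default_rng(side_seed)
    er = np.full(len(sheet), "unknown", dtype=object)
    case_mask = (sheet["status"] == "case").to_numpy()
    if er_model is not None:
        er_entries = _causal_layout(panels, er_model)
        er_cols = np.array([offsets[pi] + idx for pi, idx, _ in er_entries], dtype=int)
        er_beta = np.array([b for _, _, b in er_entries])
        sc = G_all[np.ix_(case_mask, er_cols)] @ er_beta if er_entries else np.zeros(case_mask.sum())
        lo, hi = -40.0, 40.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if expit(mid + sc).mean() < model.er_neg_fraction:
                lo = mid
            else:
                hi = mid
        p_neg = expit(0.5 * (lo + hi) + sc)
    else:
        p_neg = np.full(int(case_mask.sum()), model.er_neg_fraction)
    neg = side_rng.random(case_mask.sum()) < p_neg
    er[np.flatnonzero(case_mask)] = np.where(neg, "negative", "positive")
    sheet["er_status"] = er

    # variant table
    var_rows = []
    for i, pan in enumerate(panels):
        reg = pan.region
        chrom = reg.chrom or f"chr{i + 1}"
        for pos in reg.positions:
            var_rows.append((variant_key(chrom, int(pos), "A", "G"), chrom, int(pos), "A", "G", reg.region_id))
    variants = pd.DataFrame(var_rows, columns=["variant_id", "chrom", "pos", "ref", "alt", "region_id"])

    depth = qual = None
    if read_stats is not None:
        depth = side_rng.poisson(read_stats.mean_depth, G_all.shape).astype(np.int32)
        qual = np.clip(np.rint(side_rng.normal(read_stats.gq_mean, read_stats.gq_sd, G_all.shape)), 0, 99).astype(np.int32)
        qual[depth == 0] = 0

    gm = GenotypeMatrix(
        dosage=G_all,
        samples=sheet["sample_id"].tolist(),
        variants=variants,
        depth=depth,
        qual=qual,
    )
    return gm, sheet


# ----------------------------------------------------------------------
# annotation
# ----------------------------------------------------------------------
def make_gene_intervals(regions: pd.DataFrame, genes_per_region: int = 6, gene_fraction: float = 0.6, seed=0) -> pd.DataFrame:
    """Evenly spaced synthetic gene intervals covering ``gene_fraction`` of
    each region span (columns: gene, chrom, start, end, region_id; 1-based
    closed)."""
    rows = []
    for _, reg in regions.iterrows():
        span = reg["end"] - reg["start"] + 1
        glen = max(1, int(span * gene_fraction / genes_per_region))
        gap = max(0, (span - genes_per_region * glen) // max(1, genes_per_region))
        cursor = int(reg["start"])
        for j in range(genes_per_region):
            rows.append((f"{reg['region_id']}_g{j + 1}", reg["chrom"], cursor, min(cursor + glen - 1, int(reg["end"])), reg["region_id"]))
            cursor += glen + gap
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end", "region_id"])


def assign_annotations(
    variants: pd.DataFrame,
    proportions,
    seed,
    gene_intervals: pd.DataFrame,
    damaging_prob: float = 0.4,
) -> pd.DataFrame:
    """Assign impact class (multinomial), gene (interval containment) and,
    for nonsynonymous variants, a damaging flag (Bernoulli)."""
    proportions = np.asarray(proportions, dtype=float)
    if proportions.shape != (4,):
        raise ValueError("proportions must cover (high, moderate, low, modifier)")
    if abs(proportions.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions sum to {proportions.sum()!r}, not 1")
    rng = default_rng(seed)
    out = variants.copy()
    out["impact"] = rng.choice(IMPACT_CLASSES, size=len(out), p=proportions)

    gene = np.full(len(out), None, dtype=object)
    for _, gi in gene_intervals.iterrows():
        hit = (
            (out["chrom"] == gi["chrom"])
            & (out["pos"] >= gi["start"])
            & (out["pos"] <= gi["end"])
            & pd.isna(gene)
        ).to_numpy()
        gene[hit] = gi["gene"]
    out["gene"] = gene

    damaging = np.zeros(len(out), dtype=bool)
    mod = (out["impact"] == "moderate").to_numpy()
    damaging[mod] = rng.random(mod.sum()) < damaging_prob
    out["damaging"] = damaging
    return out


def regions_frame(panels) -> pd.DataFrame:
    """Region table (region_id, chrom, start, end; 1-based closed)."""
    if isinstance(panels, HaplotypePanel):
        panels = [panels]
    rows = []
    for i, pan in enumerate(panels):
        reg = pan.region
        chrom = reg.chrom or f"chr{i + 1}"
        rows.append((reg.region_id, chrom, reg.start, reg.end))
    return pd.DataFrame(rows, columns=["region_id", "chrom", "start", "end"])


# ----------------------------------------------------------------------
# convenience: one region, one causal variant
# ----------------------------------------------------------------------
def simulate_single_causal_region(
    seed,
    n_variants: int = 200,
    founder_haplotypes: int = 30,
    switch_prob: float = 0.01,
    divergence_F: float = 0.01,
    n_cases: int = 2000,
    n_controls: int = 2000,
    target_maf: float = 0.2,
    odds_ratio: float = 1.5,
    read_stats: ReadStatsModel | None = None,
):
    """Single-population region with one causal SNV at (approximately) the
    target MAF; returns ``(gm, sheet, causal_index)``. Used by the
    credible-set calibration and parameter-recovery studies."""
    ss = SeedSequence(seed) if not isinstance(seed, SeedSequence) else seed
    panel_seed, cohort_seed = ss.spawn(2)
    region = RegionSpec("r1", n_variants, founder_haplotypes, switch_prob, common_fraction=1.0)
    pop = PopulationSpec("P1", n_cases, n_controls, divergence_F=divergence_F)
    panel = simulate_panel(region, [pop], panel_seed)
    freq = panel.founder_frequency("P1")
    maf = np.minimum(freq, 1 - freq)
    causal = int(np.argmin(np.abs(maf - target_maf)))
    model = DiseaseModel(causal_effects={("r1", causal): float(np.log(odds_ratio))})
    gm, sheet = simulate_cohort(panel, model, [pop], cohort_seed, read_stats=read_stats)
    return gm, sheet, causal
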