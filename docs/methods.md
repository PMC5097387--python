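# Methods

`finescan` implements the statistical core of a multiethnic targeted-sequencing
fine-mapping study: genotype/variant/sample QC, per-SNV logistic association
with cross-population fixed-effect meta-analysis, an effective-number-of-tests
multiplicity correction, conditional scans, approximate-Bayesian credible sets,
and gene-based rare-variant tests (burden, SKAT, Hom-Meta-SKAT). A synthetic
cohort generator with a known logistic disease model provides ground truth for
every stage.

## Synthetic cohorts

**Allele-frequency spectrum.** Each variant draws an ancestral frequency from a
two-component mixture: with probability `common_fraction` uniform on the common
range [0.005, 0.5], otherwise from a neutral-spectrum-shaped density
proportional to 1/x on [1/(4H), 0.005], where H is the founder-pool size. The
1/x shape is the standard neutral-equilibrium approximation; only the rare
*fraction* (not the spectrum shape) is typically known for a given study, so
the shape is a fixed modelling choice. The default `common_fraction = 0.128`
reproduces a catalogue in which 87% of SNVs are rare (MAF < 0.005).

**Population divergence.** Population frequencies follow the Balding-Nichols
model, `p_k ~ Beta(p(1-F)/F, (1-p)(1-F)/F)`. Default divergence values (AA
0.12, JA 0.10, EU 0.08, HI 0.06) are in the range of continental human F_ST
estimates, with the admixed group lowest. An additional per-population
`private_rare_rate` (Poisson count of variants forced private to one group)
supplements the privacy that divergence and rare-variant sampling already
create, emulating catalogues in which most variants are seen in one ancestry
group only.

**Linkage disequilibrium.** Each population carries a founder haplotype pool
drawn site-wise independently at `p_k`; sample haplotypes copy founders as
mosaics with a per-adjacent-site switch probability `s`. Two properties follow
directly:

* the sample correlation between sites j and k equals the founder-pool
  empirical correlation damped by `(1-s)^|j-k|`, so LD blocks arise from
  *founder-pattern collisions* — two sites carried by the same subset of
  founders are perfect proxies before recombination damping;
* the expected squared correlation of unrelated sites is approximately `1/H`,
  so large pools (H in the hundreds to thousands, the default 1000) give
  realistically weak background LD, while small pools (H around 6-10) make
  strong proxies (r² > 0.8) common. The LD-absorption studies use small pools
  for exactly this reason.

This is deliberately simpler than coalescent simulation: one knob (`s`, plus
H) controls block structure, and no external simulator is needed. It does not
reproduce fine-scale human LD decay, recombination hotspots, or
mutation-age/frequency coupling; conclusions from passing tests are about the
statistical machinery, not about any specific human region.

**Disease model and sampling.** Disease probability is
`logistic(alpha + sum_j beta_j g_j)` over configurable causal dosages. The
intercept is calibrated by bisection so that the prevalence of a
50,000-individual calibration pool matches `baseline_prevalence` (default
0.10, roughly a lifetime breast-cancer risk; under case-control sampling the
odds ratios are invariant to this choice). The calibration pool draws
genotypes only at the causal columns using the exact Markov "refresh"
representation of the mosaic process (across a gap of d sites the founder
index is redrawn uniformly with probability `1-(1-s)^d`), which is
distributionally identical to materializing full haplotypes and much cheaper.
Cases and controls are then rejection-sampled from full-genotype batches to
exact per-population targets; an explicit error reports an unattainable case
target. ER (estrogen-receptor) status is assigned to cases independently of
genotype with probability `er_neg_fraction` (default 393/2288 ≈ 0.172); an
optional second logistic model makes ER-negative status genotype-dependent.

Default population sizes are AA 468/469, JA 622/634, HI 452/455, EU 746/765
(cases/controls), which reproduce the published study marginals (2288 cases,
2323 controls; group totals 937/1256/907/1511) exactly; the within-group
splits beyond AA are interpolated, as they are not individually published.

Per-genotype read depth is Poisson (mean 50, deep targeted sequencing) and
genotype quality a clipped normal (mean 60, sd 15); genotypes without reads
get GQ 0. These feed the QC stage only.

All randomness flows from one master seed through `numpy` `SeedSequence`
spawning (per region, per population, calibration, side channels), making
every simulation bit-reproducible.

## Quality control

Thresholds follow deep-targeted-sequencing practice, with all comparisons
exclusive ("fewer than 5 reads" masks DP ≤ 4; DP = 5 passes): genotypes with
DP < 5 or GQ < 10 are set missing; variants are removed when > 10% of samples
have no reads, the total read count is < 20,000, missingness is > 10%, or the
exact Hardy-Weinberg test gives p < 1e-6 in any ancestry group; samples are
removed for call rate < 90%, concordance < 90% with an external genotype
table, or as the lexicographically larger member of a duplicate pair
(pairwise concordance > 0.99 — a chosen operational definition, since
"unexpected duplicates" has no published criterion). Variant-removal
attribution follows a fixed order (no-reads → total-depth → missingness →
HWE) so reports are reproducible; a variant violating several rules counts
under the first.

The HWE test is the exact conditional test (probability-ordered two-sided
sum over heterozygote counts given the allele counts), not the chi-square
approximation, because rare variants dominate sequencing catalogues and
chi-square is invalid at low counts. It is computed per ancestry group over
all samples by default; whether the original analysis used all samples or
controls only is not documented, so a controls-only switch is provided
(`QcThresholds.hwe_controls_only`).

## Single-SNV association and meta-analysis

Each variant is tested by additive-dosage logistic regression (IRLS/Newton
with step halving; convergence when the relative log-likelihood change is
below 1e-10, at most 50 iterations). Wald statistics are reported because the
per-allele odds ratios with 95% CIs in the result tables are Wald-form; the
maximized and covariates-only log-likelihoods are recorded on the identical
sample subset for the credible-set stage. Monomorphic dosages, non-convergence
and (quasi-)separation (|log-OR| > 15) are flagged not-evaluable and excluded
from meta-analysis and posterior sums. Missing dosages drop the sample for
that variant only.

Population stratification is adjusted with the top three within-population
principal components, computed from common variants (MAF > 0.05) standardized
by `sqrt(2f(1-f))`, missing entries mean-imputed, scores being projections on
the leading eigenvectors of the variant-space covariance (signs fixed by the
largest-magnitude loading).

Cross-population combination is inverse-variance fixed-effect meta-analysis
over the evaluable populations. Conditional scans add the (mean-imputed)
dosages of index/top SNVs as covariates; conditioned variants are reported
not-evaluable, and collinear conditioning fails loudly naming the variant.

The multiplicity correction is simpleM-style: per region, the effective test
count is the smallest k whose top-k correlation-matrix eigenvalues reach
99.5% of the total (the method's published default constant); the genome-wide
threshold is alpha divided by the summed effective counts.

## Credible sets

Under a single-causal-variant assumption with a uniform prior and one model
per SNV (intercept + covariates + that SNV, all of equal dimension), the
posterior for SNV i is `exp(l_i) / sum_j exp(l_j)` over evaluable SNVs, with
the maximized log-likelihoods used directly and no complexity penalty — the
models share one dimension, so any per-model constant penalty (BIC included)
cancels; `posteriors_from_logliks` still exposes a `penalty` argument for
unequal-dimension extensions. The computation is log-sum-exp stabilized. Not-evaluable SNVs get zero posterior rather than prior mass —
the sum runs over tested SNVs only. The posterior probability set (PPS) is
the smallest descending-posterior prefix whose cumulative mass *strictly
exceeds* the target (default 0.90), with a 1e-12 guard against float
equality at the boundary and ties broken by variant id.

For cross-population sets, per-population log-likelihoods are summed; where a
variant is not evaluable in a population, that population contributes its
covariates-only log-likelihood, keeping all variants on a common stratified
scale. A pooled single-model alternative is available through the scan API,
but the summed-stratified convention is the default.

**Coverage behaviour.** The calibration study (`finescan.calibration.
pps_coverage`) measures the frequentist coverage of the 90% PPS over
simulated single-causal regions. Because the set is the smallest prefix
*exceeding* 90%, its realized posterior mass — and hence its expected
coverage under a well-specified model — is at least the nominal mass, and
the overshoot grows as posteriors concentrate: with 200 near-independent
common SNVs, n = 2000/2000 and a causal OR of 1.5 at MAF 0.2 (Wald z ≈ 7),
the posterior is essentially a point mass on the causal SNV, the PPS has
size ~1, and coverage saturates near 100%. In diffuse or high-LD regimes
(weaker effects, or small founder pools producing strong proxies) the study
measures coverage of 95-98% at mass 0.90. The construction therefore behaves
conservatively everywhere — it over-covers, never under-covers — which is
the operationally safe direction for a set meant to shortlist candidate
causal variants.

## Rare-variant tests

A gene's test set is its nonsynonymous (impact class "moderate") variants
with pooled-sample MAF strictly below 0.005, optionally restricted to those
flagged damaging. Missing dosages inside a set are imputed to homozygous
reference: at MAF < 0.005 the reference call is overwhelmingly likely, at the
cost of slightly diluting carrier counts (a conservative bias). The carrier
proportion is the fraction of subjects with at least one observed minor
allele, excluding subjects missing at every member.

The burden statistic is the per-subject minor-allele count regressed in the
same logistic machinery (yielding per-gene ORs with Wald CIs); a
carrier-indicator burden is available as an option. SKAT uses Beta(1, 25)
density weights on the pooled MAF (the method's published default), score
vector `S = G'(y - mu_hat)` from the covariates-only null fit, statistic
`Q = sum_j w_j^2 S_j^2`, and the null distribution `sum_l lambda_l chi2_1`
with eigenvalues of `W^{1/2} G' P G W^{1/2}`,
`P = V - V X (X'VX)^{-1} X'V`. Tail probabilities come from Imhof-type
numerical inversion of the characteristic function (adaptive quadrature,
eigenvalues truncated below 1e-10 of the maximum) with the Liu-Tang-Zhang
moment-matched fallback when the inversion is unreliable. The inversion was
verified against a 200,000-draw Monte Carlo of the weighted-chi-square null
to four decimals; note that for very rare variants at small n the *exact
permutation* null can differ visibly from this asymptotic reference — a
property of score-test asymptotics, not of the inversion.

Meta-analysis: burden results combine by inverse variance exactly as the
single-SNV meta; Hom-Meta-SKAT sums per-population score vectors and
projected information matrices over variants aligned by key (absent variants
contribute zero score and zero information), takes weights from the pooled
MAF, and evaluates Q against the summed-information eigenvalues — the
homogeneous-effect assumption. Gene-level significance uses alpha divided by
the number of gene x selection-rule tests actually performed.

## Study harness problem sizes

The packaged operating-characteristic studies run at: 500 regions x 200 SNVs
x 4000 subjects for credible-set coverage; 2000 null tests/genes for each
type-I-error family (n = 1000 subjects; the Hom-Meta variant splits the
cohort in two); 50 replicates for odds-ratio recovery and 20 for conditional
LD absorption (6-founder pools, switch probability 0.001, so that r² > 0.8
proxies exist). These sizes put Monte-Carlo error comfortably inside the
asserted bands while keeping the full suite fast.

## Known limitations

* The generator's LD is block-collision LD, not coalescent LD; it has no
  hotspot structure and no frequency-age correlation.
* ER status is genotype-independent by default, so ER-stratified analyses are
  null by construction unless an ER-specific model is supplied.
* The credible set over-covers by construction (see above); it should be read
  as "at least 90%", which is also how the shortlist is used in practice.
* Wald p-values are mildly anti-conservative for very rare variants; the
  single-SNV scan guards this with its MAF floor (default 0.005), and the
  rare-variant machinery uses score/permutation-comparable statistics instead.
* Sample-level duplicate detection is O(n² m) on the concordance matrix;
  adequate for cohort sizes in the thousands, not for biobanks.
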