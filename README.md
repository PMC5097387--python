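# finescan

Fine-mapping of GWAS susceptibility regions from multiethnic targeted
sequencing: quality control of sequencing genotypes, per-SNV case-control
association with cross-population meta-analysis, conditional scans, a
multiplicity correction based on the effective number of tests,
approximate-Bayesian credible sets, and gene-based rare-variant tests —
plus a synthetic-cohort generator with a known disease model so every stage
can be validated against ground truth.

It is aimed at statistical geneticists who have deep targeted-sequencing
genotypes (a VCF with per-genotype DP/GQ), a sample sheet with ancestry and
case/control labels, region definitions (BED), and a variant annotation
table, and who want the full post-calling analysis of a multiethnic
fine-mapping study as a tested, scriptable library.

## The statistics at the core

**Association.** Within each ancestry group, each SNV with MAF > 0.005 is
tested by additive logistic regression adjusted for the top three
within-group principal components; groups are combined by inverse-variance
fixed-effect meta-analysis (β = Σwₖβₖ/Σwₖ, w = 1/se², se = (Σw)^(-1/2)).
Independent signals are probed by re-scanning conditional on the top or
index SNV. Multiplicity uses a region-specific effective number of tests
M_eff (smallest k with the top-k correlation eigenvalues reaching 99.5% of
the total), with threshold α/ΣM_eff.

**Credible sets.** Assuming one causal SNV per region, the posterior for
SNV i is the ratio of its maximized logistic likelihood to the region sum,
πᵢ = exp(ℓᵢ)/Σⱼexp(ℓⱼ); the posterior probability set (PPS) is the smallest
set of SNVs whose summed posterior strictly exceeds 90%. Cross-population
sets sum per-population log-likelihoods (monomorphic populations contribute
their covariates-only log-likelihood).

**Rare variation.** Per gene, the rare (pooled MAF < 0.005) nonsynonymous
variants — optionally only those predicted damaging — are tested by a
minor-allele-count burden logistic regression (per-gene OR with 95% CI) and
by SKAT (Q = Σⱼwⱼ²Sⱼ², Beta(1,25) MAF weights, weighted-chi-square null via
Imhof inversion with a Liu fallback). Across ancestries, burden results
combine by inverse variance and SKAT by summing score vectors and
information matrices under a homogeneous-effect assumption (Hom-Meta-SKAT).

See `docs/methods.md` for the full model, defaults, and design choices.

## Worked example

Simulate one high-LD region with a known causal SNV (per-allele OR 1.5 at
MAF 0.2) in 2000 cases / 2000 controls, scan it, and build the 90% credible
set:

```python
import numpy as np
from finescan import (simulate_single_causal_region, scan_region,
                      posteriors_from_logliks, credible_set)

gm, sheet, causal = simulate_single_causal_region(
    seed=7, n_variants=200, founder_haplotypes=6, switch_prob=0.001,
    n_cases=2000, n_controls=2000, odds_ratio=1.5)
results = scan_region(gm, sheet)
top = max((r for r in results if r.evaluable), key=lambda r: abs(r.z))
print(f"causal SNV: {gm.variant_ids[causal]} (simulated per-allele OR 1.5)")
print(f"top SNV:    {top.variant_id}  OR={top.odds_ratio:.3f} "
      f"(95% CI {top.ci95[0]:.3f}-{top.ci95[1]:.3f})  p={top.p:.2e}")
ll = np.array([r.loglik if r.evaluable else np.nan for r in results])
pps = credible_set(posteriors_from_logliks(ll), mass=0.90,
                   variant_ids=gm.variant_ids)
print(f"90% PPS: {pps.size} of {gm.n_variants} SNVs "
      f"(cumulative posterior {pps.cum_mass:.3f}); "
      f"contains causal: {pps.contains(gm.variant_ids[causal])}")
```

prints

```
causal SNV: chr1:1000900:A:G (simulated per-allele OR 1.5)
top SNV:    chr1:1000900:A:G  OR=1.484 (95% CI 1.327-1.659)  p=4.53e-12
90% PPS: 2 of 200 SNVs (cumulative posterior 0.971); contains causal: True
```

The scan recovers the simulated effect (fitted OR 1.48 vs true 1.5) and the
credible set shrinks the 200 candidate SNVs to 2 — the causal variant and
its one near-perfect LD proxy.

The same pipeline is available from the shell as `finescan` with
`simulate`, `qc`, `assoc`, `meta`, `finemap` and `rare` subcommands over
VCF/BED/TSV files; `finescan simulate --config cfg.yaml --out data/ --seed 1`
writes a complete synthetic study (VCF + sample sheet + regions BED +
annotations) for the downstream commands.

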