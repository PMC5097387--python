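"""Approximate-Bayesian single-causal posteriors and credible sets.

Under the assumption of exactly one causal SNV per region and a uniform
prior over candidates, each variant's posterior probability is its maximized
logistic-regression likelihood divided by the region sum (every per-variant
model has identical dimension, so maximized likelihood ratios are used
directly; a BIC-penalized variant is available but non-default). The
posterior probability set (PPS) is the smallest set of variants whose
summed posterior strictly exceeds the target mass (default 0.90).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assoc import AssocResult

#: float guard for strict-inequality comparison at the mass boundary
MASS_EPS = 1e-12


@dataclass
class PosteriorSet:
    region_id: str
    variant_ids: np.ndarray  # input order
    posterior: np.ndarray  # input order, sums to 1 over evaluable variants
    order: np.ndarray  # indices sorted by descending posterior (ties: id)
    member: np.ndarray  # bool, input order
    mass: float
    cum_mass: float  # cumulative posterior of the members

    @property
    def size(self) -> int:
        return int(self.member.sum())

    @property
    def proportion(self) -> float:
        return self.size / len(self.variant_ids)

    def contains(self, variant_id: str) -> bool:
        return bool(self.member[np.flatnonzero(self.variant_ids == variant_id)].any())


def posteriors_from_logliks(logliks, penalty: float = 0.0) -> np.ndarray:
    """Softmax of per-variant maximized log-likelihoods (log-sum-exp
    stabilized). NaN entries mark not-evaluable variants and receive zero
    posterior. ``penalty`` subtracts a constant per-model complexity term,
    which cancels here but is kept for the BIC-penalized variant."""
    ll = np.asarray(logliks, dtype=float) - penalty
    ok = np.isfinite(ll)
    if ll.size == 0 or not ok.any():
        raise ValueError("no evaluable variants in region")
    out = np.zeros(ll.size)
    m = ll[ok].max()
    w = np.exp(ll[ok] - m)
    out[ok] = w / w.sum()
    return out


def credible_set(posterior, mass: float = 0.90, variant_ids=None, region_id: str = "") -> PosteriorSet:
    """Smallest descending-order prefix whose cumulative posterior strictly
    exceeds ``mass`` (ties broken by variant id for determinism)."""
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    pi = np.asarray(posterior, dtype=float)
    if variant_ids is None:
        variant_ids = np.array([f"v{i}" for i in range(pi.size)])
    else:
        variant_ids = np.asarray(variant_ids, dtype=object)
    order = np.lexsort((variant_ids, -pi))
    csum = np.cumsum(pi[order])
    # strict ">" with a tolerance guard against float equality at the edge
    k = int(np.searchsorted(csum, mass + MASS_EPS, side="right") + 1)
    k = min(k, pi.size)
    member = np.zeros(pi.size, dtype=bool)
    member[order[:k]] = True
    return PosteriorSet(
        region_id=region_id,
        variant_ids=variant_ids,
        posterior=pi,
        order=order,
        member=member,
        mass=mass,
        cum_mass=float(csum[k - 1]),
    )


def cross_population_logliks(per_population: dict[str, list[AssocResult]]) -> tuple[np.ndarray, np.ndarray]:
    """Combine per-population scans into one log-likelihood per variant.

    Populations contribute their maximized log-likelihood where the variant
    is evaluable and their covariates-only log-likelihood otherwise, keeping
    all variants on a common stratified-likelihood scale even when
    monomorphic in some groups. Returns ``(variant_ids, combined_loglik)``
    with NaN for variants evaluable in no population.
    """
    if not per_population:
        raise ValueError("no population scans supplied")
    keys = None
    for pop, results in per_population.items():
        ids = [r.variant_id for r in results]
        if keys is None:
            keys = ids
        elif ids != keys:
            raise ValueError(f"population {pop!r} scan has mismatched variant keys")
    combined = np.zeros(len(keys))
    any_eval = np.zeros(len(keys), dtype=bool)
    for pop, results in per_population.items():
        null_ll = next((r.null_loglik for r in results if np.isfinite(r.null_loglik)), np.nan)
        for i, r in enumerate(results):
            if r.evaluable:
                combined[i] += r.loglik
                any_eval[i] = True
            else:
                fallback = r.null_loglik if np.isfinite(r.null_loglik) else null_ll
                combined[i] += fallback
    combined[~any_eval] = np.nan
    return np.asarray(keys, dtype=object), combined
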