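"""Core in-memory containers shared by every pipeline stage.

The central object is :class:`GenotypeMatrix`, a samples x variants dosage
matrix (0/1/2 with NaN for missing calls) carrying optional per-genotype
read-depth (DP) and genotype-quality (GQ) side channels plus a variant
annotation frame. Variants are identified by ``chrom:pos:ref:alt`` keys.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: sentinel for absent DP/GQ entries
NO_READS = -1

VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "ref", "alt", "region_id"]


def variant_key(chrom: str, pos: int, ref: str, alt: str) -> str:
    return f"{chrom}:{pos}:{ref}:{alt}"


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with depth/quality side channels.

    Parameters
    ----------
    dosage
        ``(n_samples, n_variants)`` float array of alt-allele counts; NaN
        marks a missing genotype.
    samples
        Sample identifiers, one per row.
    variants
        One row per column; must contain at least ``variant_id``, ``chrom``,
        ``pos``, ``ref``, ``alt`` (``region_id``/``gene``/``impact``/
        ``damaging`` are added by later stages).
    depth, qual
        Optional integer matrices of per-genotype DP and GQ; ``NO_READS``
        marks entries with no information.
    """

    dosage: np.ndarray
    samples: list[str]
    variants: pd.DataFrame
    depth: np.ndarray | None = None
    qual: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (samples x variants)")
        n, m = self.dosage.shape
        if len(self.samples) != n:
            raise ValueError(f"{len(self.samples)} sample ids for {n} rows")
        if len(self.variants) != m:
            raise ValueError(f"{len(self.variants)} variant rows for {m} columns")
        if len(set(self.samples)) != n:
            raise ValueError("sample ids must be unique")
        for side in (self.depth, self.qual):
            if side is not None and side.shape != (n, m):
                raise ValueError("side-channel shape mismatch")
        self.variants = self.variants.reset_index(drop=True)

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    @property
    def variant_ids(self) -> np.ndarray:
        return self.variants["variant_id"].to_numpy()

    def sample_index(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"unknown sample id {exc.args[0]!r}") from None

    def take_samples(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            dosage=self.dosage[index],
            samples=[self.samples[i] for i in index],
            variants=self.variants.copy(),
            depth=None if self.depth is None else self.depth[index],
            qual=None if self.qual is None else self.qual[index],
        )

    def take_variants(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            dosage=self.dosage[:, index],
            samples=list(self.samples),
            variants=self.variants.iloc[index].reset_index(drop=True),
            depth=None if self.depth is None else self.depth[:, index],
            qual=None if self.qual is None else self.qual[:, index],
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosage=self.dosage.copy(),
            samples=list(self.samples),
            variants=self.variants.copy(),
            depth=None if self.depth is None else self.depth.copy(),
            qual=None if self.qual is None else self.qual.copy(),
        )


def alt_allele_frequency(gm: GenotypeMatrix, sample_mask=None) -> np.ndarray:
    """Per-variant alt-allele frequency; missing genotypes drop out of the
    denominator. All-missing variants yield NaN."""
    dos = gm.dosage if sample_mask is None else gm.dosage[np.asarray(sample_mask)]
    called = np.sum(~np.isnan(dos), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.nansum(dos, axis=0) / (2.0 * called)


def minor_allele_frequency(gm: GenotypeMatrix, sample_mask=None) -> np.ndarray:
    f = alt_allele_frequency(gm, sample_mask)
    return np.minimum(f, 1.0 - f)
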