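import numpy as np
import pandas as pd
import pytest

from finescan.core import GenotypeMatrix


def make_gm(dosage, depth=None, qual=None, samples=None, chrom="chr1", start=100, extra=None):
    """Small GenotypeMatrix factory for crafted fixtures."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    samples = samples or [f"s{i:03d}" for i in range(n)]
    variants = pd.DataFrame(
        {
            "variant_id": [f"{chrom}:{start + j}:A:G" for j in range(m)],
            "chrom": chrom,
            "pos": [start + j for j in range(m)],
            "ref": "A",
            "alt": "G",
            "region_id": "r1",
        }
    )
    if extra:
        for k, v in extra.items():
            variants[k] = v
    return GenotypeMatrix(
        dosage=dosage,
        samples=samples,
        variants=variants,
        depth=None if depth is None else np.asarray(depth, dtype=np.int32),
        qual=None if qual is None else np.asarray(qual, dtype=np.int32),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """One-region, one-population cohort with a known causal variant."""
    from finescan import ReadStatsModel, simulate_single_causal_region

    gm, sheet, causal = simulate_single_causal_region(
        seed=20160923 % (2**31), n_cases=300, n_controls=300, n_variants=80,
        read_stats=ReadStatsModel(),
    )
    return gm, sheet, causal
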