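import numpy as np
import pandas as pd
import pytest

import paleoscore as ps
from paleoscore.genotype import MISSING, GenotypeMatrix, SNPRecord


def make_matrix(calls, ploidy=1, chrom="1", start=1000):
    """Small GenotypeMatrix from a samples x snps array of call codes."""
    calls = np.asarray(calls, dtype=np.int8)
    n, L = calls.shape
    snps = [
        SNPRecord(id=f"s{j}", chrom=chrom, pos=start + j * 10_000,
                  ref_allele="A", alt_allele="G")
        for j in range(L)
    ]
    return GenotypeMatrix(
        samples=[f"ind{i}" for i in range(n)], snps=snps, calls=calls, ploidy=ploidy
    )


def make_meta(n, dates=None, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "sample_id": [f"ind{i}" for i in range(n)],
            "date_bp": dates if dates is not None else rng.uniform(0, 12000, n),
            "lat": rng.uniform(36, 60, n),
            "lon": rng.uniform(-5, 40, n),
            "coverage": rng.lognormal(0, 0.5, n),
        }
    )


@pytest.fixture(scope="session")
def small_neutral():
    """One modest neutral dataset reused across read-only tests."""
    cfg = ps.make_preset(
        "neutral", n_snps_null=2000, n_snps_trait=40, n_individuals=150
    )
    return ps.simulate_dataset(cfg, seed=11)


@pytest.fixture(scope="session")
def small_neutral_pcs(small_neutral):
    model = ps.fit_reference_pca(small_neutral.matrix, k=10)
    return ps.project_samples(model, small_neutral.matrix)
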