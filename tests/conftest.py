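import numpy as np
import pandas as pd
import pytest

from tce.io_tables import (
    ExpressionMatrix,
    FeatureAnnotation,
    GenotypeMatrix,
    SampleTable,
)
from tce.sim import SimConfig, simulate_population


@pytest.fixture(scope="session")
def sim_small():
    """One small simulated population with a planted triple (single QTL)."""
    cfg = SimConfig(n_samples=200, n_genes=300, n_snps=300, n_qtl=1, seed=11)
    return simulate_population(cfg)


@pytest.fixture()
def tiny_genotypes():
    dosages = pd.DataFrame(
        [[0.0, 1.0, 2.0], [1.0, np.nan, 0.0]],
        index=pd.Index(["snp1", "snp2"], name="snp_id"),
        columns=["s1", "s2", "s3"],
    )
    snps = pd.DataFrame(
        {"chrom": ["1", "2"], "pos": [100, 5000], "ref": ["A", "C"],
         "alt": ["G", "T"]},
        index=dosages.index,
    )
    return GenotypeMatrix(dosages, snps)


@pytest.fixture()
def tiny_samples():
    rng = np.random.default_rng(5)
    n = 40
    data = pd.DataFrame(
        {
            "sex": rng.choice(["F", "M"], n),
            "batch": rng.choice(["B1", "B2"], n),
            "boar": rng.choice(["D1", "D2", "D3"], n),
            "age": rng.integers(204, 217, n).astype(float),
            "phenotype": rng.normal(3.3, 1.1, n),
        },
        index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"),
    )
    return SampleTable(data)


@pytest.fixture()
def tiny_annotation():
    genes = pd.DataFrame(
        {
            "chrom": ["1", "1", "2"],
            "start": [1_000_000, 5_000_000, 1_000_000],
            "end": [1_005_000, 5_004_000, 1_010_000],
        },
        index=pd.Index(["gA", "gB", "gC"], name="gene_id"),
    )
    return FeatureAnnotation(genes)
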