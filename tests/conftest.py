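import numpy as np
import pandas as pd
import pytest

import gwaspath as gp


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def small_stats():
    """Five SNPs on two chromosomes with QC fields."""
    df = pd.DataFrame({
        "snp_id": ["rs1", "rs2", "rs3", "rs4", "rs5"],
        "chrom": ["1", "1", "2", "6", "6"],
        "pos": [100_000, 160_000, 50_000, 24_999_999, 30_000_000],
        "p_value": [0.01, 0.5, 0.2, 0.05, 0.9],
        "maf": [0.25, 0.005, 0.4, 0.1, 0.3],
        "call_rate": [1.0, 0.99, 0.92, 1.0, 1.0],
    })
    return gp.SummaryStats(df)


@pytest.fixture
def stats_file(tmp_path):
    path = tmp_path / "stats.tsv"
    pd.DataFrame({
        "snp": ["rs1", "rs2", "rs3"],
        "chrom": ["1", "1", "2"],
        "pos": [100, 200, 300],
        "p": [0.1, 0.2, 0.3],
    }).to_csv(path, sep="\t", index=False)
    return path


@pytest.fixture
def tiny_panel(rng):
    """60-sample panel over 4 SNPs: two correlated, one independent, one copy."""
    n = 60
    a = rng.integers(0, 3, n).astype(float)
    b = a.copy()
    b[:5] = rng.integers(0, 3, 5)
    c = rng.integers(0, 3, n).astype(float)
    return gp.GenotypePanel(
        samples=[f"s{i}" for i in range(n)],
        snp_ids=["rs1", "rs2", "rs3", "rs4"],
        dosages=np.column_stack([a, b, c, a]),  # rs4 duplicates rs1
    )


@pytest.fixture
def null_gene_results(rng):
    """200 genes with iid uniform adjusted P-values (simulation flavour)."""
    K = 200
    return pd.DataFrame({
        "gene_id": [f"g{i:04d}" for i in range(K)],
        "n_snps": rng.integers(1, 10, K),
        "stat_min_p": rng.uniform(size=K),
        "stat_fisher": rng.chisquare(4, K),
        "adj_p_min": rng.uniform(size=K),
        "adj_p_fisher": rng.uniform(size=K),
        "method": "simulation",
        "n_null": 1000,
    })
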