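import logging

import numpy as np
import pandas as pd
import pytest

from cudelim.containers import DistMatrix, SnpTable
from cudelim.simdata import SimConfig, simulate_dataset

logging.getLogger("cudelim").setLevel(logging.ERROR)


def make_snp_table(freq: np.ndarray, n: np.ndarray | int = 100,
                   pops: list[str] | None = None,
                   chrom: str = "chr1") -> SnpTable:
    """Build a SnpTable from a raw (SNPs x pops) frequency array."""
    freq = np.asarray(freq, dtype=float)
    n_snps, n_pops = freq.shape
    pops = pops or [f"P{j + 1}" for j in range(n_pops)]
    if np.isscalar(n):
        n = np.full_like(freq, n, dtype=int)
    idx = pd.Index([f"s{i + 1}" for i in range(n_snps)], name="snp_id")
    meta = pd.DataFrame({"chrom": chrom, "pos": np.arange(1, n_snps + 1) * 10}, index=idx)
    return SnpTable(meta, pd.DataFrame(freq, index=idx, columns=pops),
                    pd.DataFrame(np.asarray(n, dtype=int), index=idx, columns=pops))


def random_distmatrix(rng: np.random.Generator, n: int, kind: str = "marine") -> DistMatrix:
    a = rng.random((n, n))
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 0.0)
    labels = [f"P{i + 1:02d}" for i in range(n)]
    return DistMatrix(pd.DataFrame(a, index=labels, columns=labels), kind)


@pytest.fixture(scope="session")
def small_dataset():
    """A small but structured simulated dataset shared across tests."""
    cfg = SimConfig(n_pops=14, n_snps=3000, n_genes=150, n_adaptive_genes=6,
                    n_ind_per_pop=15, seed=42)
    snp, gt, truth = simulate_dataset(cfg, genotypes=True)
    return cfg, snp, gt, truth
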