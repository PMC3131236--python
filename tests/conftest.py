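import numpy as np
import pytest

from bivalency.io import norm_chrom
from bivalency.simulate import SimulationConfig, simulate_genes, simulate_reads


def brute_force_counts(reads, windows, rule="any"):
    """Independent per-read linear scan used as the counting oracle."""
    counts = []
    for wc, ws, we in windows:
        c = 0
        for rc, rs, re in reads.reads:
            if norm_chrom(rc) != norm_chrom(wc):
                continue
            if rule == "any":
                hit = rs < we and re > ws
            elif rule == "midpoint":
                hit = ws <= (rs + re) // 2 < we
            elif rule == "five_prime":
                hit = ws <= rs < we
            else:
                raise ValueError(rule)
            c += hit
        counts.append(c)
    return np.array(counts)


@pytest.fixture(scope="session")
def small_dataset():
    """A 300-gene simulated dataset shared across read-level tests."""
    cfg = SimulationConfig(n_genes=300, chrom_length=10_000_000, seed=42)
    genes, expr, truth = simulate_genes(cfg)
    k4 = simulate_reads(genes, truth, cfg, "H3K4me3")
    k27 = simulate_reads(genes, truth, cfg, "H3K27me3")
    return cfg, genes, expr, truth, k4, k27
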