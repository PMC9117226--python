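import numpy as np
import pandas as pd
import pytest

from intergenic import GeneUniverse, SyntheticConfig, generate_bundle


def random_universe(rng, n_genes=200, n_chrom=3, gap_scale=5000,
                    gene_scale=2000) -> GeneUniverse:
    """Random non-overlapping gene layout for oracle comparisons."""
    rows = []
    per = n_genes // n_chrom
    for c in range(n_chrom):
        pos = 0
        for i in range(per):
            pos += int(rng.integers(1, gap_scale))
            length = int(rng.integers(500, gene_scale))
            rows.append((f"c{c}g{i}", f"chr{c}", pos, pos + length,
                         "+" if rng.random() < 0.5 else "-"))
            pos += length
    return GeneUniverse(pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand"]))


@pytest.fixture(scope="session")
def small_bundle():
    """A quick planted bundle for per-module recovery tests."""
    return generate_bundle(SyntheticConfig(
        seed=7, n_chromosomes=2, genes_per_chromosome=500))


@pytest.fixture(scope="session")
def default_bundle():
    """The full-size (20,000-gene) default bundle."""
    return generate_bundle(SyntheticConfig(seed=2))
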