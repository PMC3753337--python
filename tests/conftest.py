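import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from svjl import simgenome as sg

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_genome():
    return sg.simulate_genome(2, [120_000, 80_000], seed=11)


@pytest.fixture(scope="session")
def genome_with_genes():
    genome = sg.simulate_genome(2, [400_000, 300_000], seed=5)
    genes = sg.simulate_gene_models(genome, 10, seed=6)
    return genome, genes


def make_pairs(rows):
    """Read-pair table from (chrom1, pos1, s1, chrom2, pos2, s2) tuples."""
    import pandas as pd

    return pd.DataFrame([
        {"id": f"p{i}", "chrom1": c1, "pos1": p1, "strand1": s1,
         "chrom2": c2, "pos2": p2, "strand2": s2, "read_len": 50,
         "source": ""}
        for i, (c1, p1, s1, c2, p2, s2) in enumerate(rows)])


def concordant_background(chrom="chr1", n=300, mu=3000, sd=300, seed=0,
                          span=1_000_000):
    """Concordant outward pairs for insert-model fitting."""
    rng = np.random.default_rng(seed)
    pos1 = rng.integers(1, span, n)
    ins = np.rint(rng.normal(mu, sd, n)).astype(int)
    return make_pairs([(chrom, int(p), "-", chrom, int(p + i - 50), "+")
                       for p, i in zip(pos1, ins)])
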