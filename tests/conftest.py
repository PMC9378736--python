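import numpy as np
import pytest

import circscreen as cs
from circscreen.synthetic import SimulationTruth, simulate_reads

SAMPLES = ["T01", "T02", "T03", "N01", "N02", "N03"]


@pytest.fixture(scope="session")
def small_world():
    """A 20 kb genome with 8 genes and 2 planted circles (one per strand)."""
    genome = cs.make_genome(1, 20_000, 0.45, seed=7)
    genes = cs.make_genes(genome, 8, seed=1)
    plus = next(g for g in genes if g.strand == "+")
    minus = next(g for g in genes if g.strand == "-")
    circs = [
        cs.make_circ(genome, plus, 0, 1, {s: 1.0 for s in SAMPLES}, circ_id="c_plus"),
        cs.make_circ(genome, minus, 1, 2, {s: 0.8 for s in SAMPLES}, circ_id="c_minus"),
    ]
    lin = {g.gene_id: {s: 1.0 for s in SAMPLES} for g in genes}
    truth = SimulationTruth(7, SAMPLES, genes, circs, lin)
    return genome, genes, truth


@pytest.fixture(scope="session")
def small_reads(small_world):
    genome, genes, truth = small_world
    return simulate_reads(truth, genome, read_len=150, depth=3000, err=0.0, seed=3)


@pytest.fixture(scope="session")
def circ_profile():
    """A tumour-high circRNA abundance profile over 12 paired samples."""
    rng = np.random.default_rng(11)
    base = np.concatenate([4.0 * np.ones(6), np.ones(6)])
    return base * np.exp(rng.normal(0, 0.2, 12))
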