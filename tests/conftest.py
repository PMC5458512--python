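import numpy as np
import pytest

from srtail import align as al
from srtail import classify as cl
from srtail import simulate as sim


@pytest.fixture(scope="session")
def toy():
    """Default toy genome (2 x 50 kb) and its annotation."""
    genome, db = sim.build_toy_genome(sim.SimGenomeSpec(seed=11))
    return genome, db


@pytest.fixture(scope="session")
def index(toy):
    return al.build_index(toy[0], k=12)


@pytest.fixture(scope="session")
def wt_sample(toy):
    """Wild-type Argonaute-bound sample, default error rate, with truth."""
    genome, db = toy
    model = sim.preset_model("wt", "ago_bound", n_reads=8_000, seed=21)
    return sim.simulate_sample(genome, db, model)


@pytest.fixture(scope="session")
def wt_table(toy, index, wt_sample):
    reads, _ = wt_sample
    table = al.align_sample(reads, index, seed=5)
    return cl.classify_sample(table, toy[1])


@pytest.fixture(scope="session")
def errorfree_sample(toy):
    """Error-free wild-type sample for exact-recovery checks."""
    genome, db = toy
    base = sim.preset_model("wt", "ago_bound", n_reads=6_000, seed=31)
    model = sim.ReadModel(**{**base.__dict__, "seq_error_rate": 0.0})
    return sim.simulate_sample(genome, db, model)


@pytest.fixture(scope="session")
def errorfree_table(toy, index, errorfree_sample):
    reads, _ = errorfree_sample
    return al.align_sample(reads, index, seed=7)


@pytest.fixture(scope="session")
def tiny_genome():
    """2 kb single-chromosome genome for brute-force oracle comparisons."""
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list("ACGT"), size=2_000))
    return {"tiny": seq}


@pytest.fixture(scope="session")
def tiny_index(tiny_genome):
    return al.build_index(tiny_genome, k=12)
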