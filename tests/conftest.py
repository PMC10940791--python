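import numpy as np
import pytest

import svpopgen as sp


@pytest.fixture(scope="session")
def small_config():
    return sp.SimConfig(seed=7, n_snps=800, n_indels=100, n_svs=120,
                        chrom_lengths={"chr1": 2_000_000, "chr2": 2_000_000})


@pytest.fixture(scope="session")
def small_truth(small_config):
    return sp.simulate_frequencies(small_config)


@pytest.fixture(scope="session")
def small_sim(small_truth, small_config):
    return sp.simulate_genotypes(small_truth, small_config)


@pytest.fixture(scope="session")
def snp_matrix(small_sim):
    return small_sim.matrix("SNP")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_callset(rng, n, chrom="chr1", caller="c1", platform="SR",
                   pos_hi=100_000, len_hi=500):
    """Random SVCall list for property tests."""
    calls = []
    for _ in range(n):
        svtype = str(rng.choice(["DEL", "INS", "DUP", "INV"]))
        pos = int(rng.integers(1, pos_hi))
        length = int(rng.integers(50, len_hi))
        end = pos if svtype == "INS" else pos + length - 1
        calls.append(sp.SVCall(chrom, pos, end, svtype, length,
                               caller_id=caller, platform=platform))
    return calls
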