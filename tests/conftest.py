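import numpy as np
import pytest

import sfpkit as sk


@pytest.fixture(scope="session")
def small_pair():
    """20 kb genome pair at rice-like SNP density, no indels/duplications."""
    return sk.generate_genome_pair(
        20_000, sk.SimParams(indel_rate=0.0), seed=7
    )


@pytest.fixture(scope="session")
def small_probes(small_pair):
    return sk.design_probe_sets(small_pair, n_sets=20, probes_per_set=11, seed=8)


@pytest.fixture(scope="session")
def gdna_matrix(small_pair, small_probes):
    return sk.simulate_intensities(
        small_probes, small_pair, "gdna", 5, sk.SimParams(indel_rate=0.0), seed=9
    )


@pytest.fixture(scope="session")
def null_sim():
    """Zero-SFP simulation: genome+probes reused, clean null intensities."""
    params = sk.SimParams(snp_rate=0.0, indel_rate=0.0)
    pair = sk.generate_genome_pair(50_000, params, seed=11)
    probes = sk.design_probe_sets(pair, n_sets=100, probes_per_set=11, seed=12)
    matrix = sk.simulate_intensities(probes, pair, "gdna", 5, params, seed=13)
    return pair, probes, matrix


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
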