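import pytest

import genefam as gf


def small_sim_config(seed: int = 11) -> gf.SimConfig:
    """A reduced genome that keeps every planted structure but runs fast."""
    return gf.SimConfig(
        seed=seed,
        n_chromosomes=4,
        genes_per_chromosome=30,
        family_size_per_subgroup={"A1": 4, "A2": 3, "A3": 2, "A4": 5,
                                  "A5": 3, "A6": 5},
        n_tandem_arrays=3,
        n_segmental_blocks=2,
        block_anchor_count=5,
        target_ks_list=[0.1, 0.3],
        motif_specs=[(9, "WDDMSLWSY")],
        refs_per_subgroup=2,
    )


@pytest.fixture(scope="session")
def small_sim():
    return gf.simulate_genome(small_sim_config())


@pytest.fixture(scope="session")
def default_sim():
    """The full-scale default genome (12 chromosomes, 66-member family)."""
    return gf.simulate_genome(gf.SimConfig(seed=1))


@pytest.fixture(scope="session")
def packaged_profile():
    return gf.build_profile(gf.packaged_seed_alignment())
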