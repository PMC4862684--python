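import numpy as np
import pytest

from clonemut.simulate import SimulationConfig, emit_lineage, generate_reference


@pytest.fixture(scope="session")
def small_reference() -> str:
    return generate_reference(20_000, 0.45, seed=42)


@pytest.fixture(scope="session")
def medium_reference() -> str:
    """Large enough to sample thousands of context-specific events."""
    return generate_reference(150_000, 0.45, seed=43)


def small_config(**overrides) -> SimulationConfig:
    """Desk-size simulation config used across tests."""
    base = dict(
        seed=11,
        genome_length=60_000,
        n_case_clones=2,
        n_control_clones=2,
        a3b_snv_count=800,
        background_snv_count=300,
        indel_count=100,
        n_probes=800,
        strand_block_size=6_000,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def lineage(tmp_path_factory):
    """One shared small simulated lineage (ground truth + files on disk)."""
    outdir = tmp_path_factory.mktemp("lineage")
    return emit_lineage(small_config(), outdir)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
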