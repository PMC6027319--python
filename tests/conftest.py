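import numpy as np
import pytest

from bchrom import simulate as sim


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def tiny_config():
    """One amplified family + one null family on a small genome."""
    burst = sim.BurstSpec
    return sim.SimulationConfig(
        seed=0,
        background_length=60_000,
        families=(
            sim.TEFamilySpec(
                "GypsyT", "Gypsy", "LTR", 500,
                (burst(0.05, 0.01, 10),), b_copies=40,
            ),
            sim.TEFamilySpec(
                "L2T", "L2", "LINE", 400, (burst(0.10, 0.01, 8),)
            ),
        ),
        samples=(
            sim.SampleMeta("REF-0B", "M", 0, is_reference=True),
            sim.SampleMeta("S-1B", "M", 1),
            sim.SampleMeta("S-2B", "F", 2),
        ),
        mean_depth=20.0,
        read_length=100,
    )


@pytest.fixture
def tiny_truth(tiny_config, rng):
    truth, library = sim.build_reference_genome(tiny_config, rng)
    truth = sim.build_b_haplotype(truth, tiny_config, rng, library)
    return truth, library
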