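import numpy as np
import pytest

from pharmnet import (
    DescriptorSpec,
    InteractionDataset,
    ProfileMatrix,
    SimConfig,
    generate,
)


@pytest.fixture(scope="session")
def sim_small():
    """Small planted dataset shared by fast integration-style unit tests."""
    return generate(
        SimConfig(
            n_drugs=24,
            n_proteins=16,
            n_side_effects=10,
            n_domains=8,
            n_fp_bits=32,
            n_planted=3,
            n_lead_series=4,
            seed=7,
        )
    )


@pytest.fixture
def tiny_profiles():
    """2 drugs x 2 side effects and 2 proteins x 2 domains."""
    drugs = ProfileMatrix.from_dense(
        ["d1", "d2"], ["seA", "seB"], np.array([[1, 0], [0, 1]])
    )
    proteins = ProfileMatrix.from_dense(
        ["p1", "p2"], ["domA", "domB"], np.array([[1, 1], [0, 1]])
    )
    return drugs, proteins


@pytest.fixture
def tiny_dataset(tiny_profiles):
    drugs, proteins = tiny_profiles
    return InteractionDataset.build(
        drugs.entity_ids, proteins.entity_ids, [("d1", "p1"), ("d2", "p2"), ("d1", "p2")]
    )


@pytest.fixture
def tensor_spec_2x2():
    return DescriptorSpec("tensor", ("seA", "seB"), ("domA", "domB"))
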