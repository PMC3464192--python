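import numpy as np
import pytest

from disomut import (
    MutationRecord,
    PropensityPredictor,
    PropensityScale,
    ProteinRecord,
    SimConfig,
    gen_mutations,
    gen_proteins,
)


@pytest.fixture(scope="session")
def scale() -> PropensityScale:
    return PropensityScale.top_idp()


@pytest.fixture(scope="session")
def predictor(scale) -> PropensityPredictor:
    return PropensityPredictor(scale)


@pytest.fixture()
def toy_proteins() -> list[ProteinRecord]:
    return [
        ProteinRecord("p1", "MKT"),
        ProteinRecord("p2", "ACDEFGHIKLMNPQRSTVWY"),
    ]


@pytest.fixture()
def toy_mutation() -> MutationRecord:
    return MutationRecord("p1", 2, "K", "R", "DM")


@pytest.fixture(scope="session")
def small_sim():
    """A small synthetic study shared by tests that only need structure."""
    config = SimConfig(
        n_proteins=10,
        length_min=200,
        length_max=400,
        mutations_per_dataset={"DM": 300, "Poly": 300},
        p_do={"DM": 0.2, "Poly": 0.1},
        p_od={"DM": 0.05, "Poly": 0.05},
        seed=7,
    )
    synthetic = gen_proteins(config)
    mutations = gen_mutations(synthetic, config)
    return config, synthetic, mutations


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
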