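import numpy as np
import pytest

from senoscreen import (
    EnsembleConfig,
    FixtureSpec,
    MlpConfig,
    MockEmbedder,
    MockEmbedderSpec,
    SenolyticPredictor,
    generate_library,
)


@pytest.fixture(scope="session")
def mock_embedder():
    """Stochastic 128-d mock embedder used throughout the suite."""
    return MockEmbedder(MockEmbedderSpec(dim=128, tau=0.05, base_seed=0))


@pytest.fixture(scope="session")
def deterministic_embedder():
    return MockEmbedder(MockEmbedderSpec(dim=128, tau=0.0, base_seed=0))


@pytest.fixture(scope="session")
def default_library():
    """The benchmark fixture: 50 actives / 1000 inactives, 5% scaffold
    overlap, 2% label noise."""
    return generate_library(FixtureSpec(seed=5))


@pytest.fixture(scope="session")
def small_library():
    return generate_library(FixtureSpec(n_pos=25, n_neg=300, seed=11))


def _test_scale_configs():
    # small network / ensemble so fitted-pipeline tests stay fast;
    # statistical behaviour is unchanged
    return dict(
        mlp_config=MlpConfig(hidden_width=64, max_epochs=400, patience=100),
        ensemble_config=EnsembleConfig(n_sub=3),
    )


@pytest.fixture(scope="session")
def test_scale_configs():
    return _test_scale_configs()


@pytest.fixture(scope="session")
def fitted_results(small_library, mock_embedder):
    """A fitted dual predictor on the small fixture, shared across tests."""
    predictor = SenolyticPredictor.from_dataframe(
        small_library[["id", "smiles", "label"]],
        mock_embedder,
        oversample_k=5,
        seed=42,
        **_test_scale_configs(),
    )
    return predictor.fit(n_boot=20)
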