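"""Shared fixtures: small synthetic studies generated once per session."""

import numpy as np
import pytest

from cortexreg import synthio


def small_config(seed: int = 1, **overrides) -> synthio.SynthConfig:
    """A scaled-down study for unit tests: 400 genes, 150 samples,
    60-gene module, 5 drivers x 12-gene regulons."""
    defaults = dict(
        n_genes=400,
        n_samples=150,
        n_module_genes=60,
        regulon_size=12,
        n_ppi_nodes=400,
        n_peaks=100,
        seed=seed,
    )
    defaults.update(overrides)
    return synthio.SynthConfig(**defaults)


@pytest.fixture(scope="session")
def small_bundle():
    return synthio.generate_study(small_config(seed=7))


@pytest.fixture(scope="session")
def small_study(small_bundle):
    return small_bundle.study


@pytest.fixture(scope="session")
def small_truth(small_bundle):
    return small_bundle.truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
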