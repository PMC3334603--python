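import numpy as np
import pytest

from aluhsf import PipelineConfig, SyntheticConfig, generate_dataset, run_pipeline


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """A compact dataset: 15 genes per class, default planted structure."""
    return SyntheticConfig(
        seed=11,
        n_genes_per_class={c: 15 for c in ("up", "down", "unchanged", "random")},
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_result(small_config):
    return run_pipeline(PipelineConfig(synthetic=small_config))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
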