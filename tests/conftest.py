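import numpy as np
import pytest

from lungseg.phantom import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def clean_phantom():
    """Zero-noise 256×256×20 thorax phantom without nodules."""
    return generate_phantom(PhantomConfig())


@pytest.fixture(scope="session")
def small_phantom():
    """Fast 128×128×8 phantom for pipeline-level tests."""
    return generate_phantom(PhantomConfig(width=128, height=128, n_slices=8))


@pytest.fixture(scope="session")
def small_run(small_phantom):
    """One full pipeline run on the small phantom, shared across tests."""
    from lungseg.pipeline import PipelineConfig, run_pipeline

    stack, truth = small_phantom
    return run_pipeline(stack, PipelineConfig(seed=1), reference=truth.lung_masks)


@pytest.fixture()
def rng():
    """Fresh deterministic generator per test (order-independent)."""
    return np.random.default_rng(1234)
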