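import numpy as np
import pytest

from cytoquant.config import MarkerThresholds, PipelineConfig
from cytoquant.pipeline import run_pipeline
from cytoquant.synthetic import SyntheticSpec, generate

# marker thresholds used for all synthetic runs: the generator renders
# positive-marker nuclei around 0.7 mean intensity and negatives near
# background, so 0.3 separates them cleanly
SOX10_T = 0.3
EDU_T = 0.3


def study_spec(seed: int, **overrides) -> SyntheticSpec:
    """The degraded study conditions: 100 cells, 10% burst nuclei, 10%
    burst bodies, 10% clumped pairs, 5% border-touching."""
    kwargs = dict(frac_burst_nuclei=0.1, frac_burst_bodies=0.1,
                  frac_clumped_pairs=0.1, frac_border_touching=0.05,
                  rng_seed=seed)
    kwargs.update(overrides)
    return SyntheticSpec(**kwargs)


@pytest.fixture(scope="session")
def study_config() -> PipelineConfig:
    return PipelineConfig(markers=MarkerThresholds(SOX10_T, EDU_T))


@pytest.fixture(scope="session")
def clean_case():
    """100 cells, 70% SOX10+, 50% EdU+ among SOX10+, no degradation."""
    spec = SyntheticSpec(rng_seed=11)
    return (spec, *generate(spec))


@pytest.fixture(scope="session")
def clean_result(clean_case, study_config):
    _, image, _ = clean_case
    return run_pipeline(image, study_config, image_id="clean")


@pytest.fixture(scope="session")
def small_case():
    """A small, fast synthetic image for unit tests."""
    spec = SyntheticSpec(n_cells=10, image_size=(360, 360), rng_seed=3)
    return (spec, *generate(spec))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
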