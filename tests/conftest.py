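import numpy as np
import pytest

import voltdenoise as vd


@pytest.fixture(scope="session")
def small_bundle() -> vd.simdata.GroundTruthBundle:
    """A small but fully featured synthetic recording (shared, read-only)."""
    cfg = vd.SimConfig(height=32, width=32, neuron_count=3, duration_s=3.0,
                       subthreshold_sd=0.08)
    return vd.generate_dataset(cfg, rng_seed=42)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
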