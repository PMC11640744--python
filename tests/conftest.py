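import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import chminmaxpat as cm

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def tiny_config():
    """A fast, fully separable synthetic configuration (24 segments)."""
    return cm.SynthConfig(
        n_records_per_class=6, segments_per_record=2, segment_seconds=2.0, seed=7
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config, tmp_path_factory):
    """Synthetic dataset written to disk: (manifest, out_dir)."""
    out = tmp_path_factory.mktemp("tiny_dataset")
    manifest = cm.generate_dataset(tiny_config, out)
    return manifest, out


@pytest.fixture(scope="session")
def tiny_segments(tiny_config):
    return cm.generate_segments(tiny_config)
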