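import numpy as np
import pytest

from ptychokit import make_spec, simulate


@pytest.fixture(scope="session")
def small_benchmark():
    """Noiseless 64x64/32x32/25-position phantom with ground truth."""
    spec = make_spec("small_test", seed=1)
    stack, truth_obj, truth_probe, offsets, manifest = simulate(spec)
    return {
        "spec": spec,
        "stack": stack,
        "object": truth_obj,
        "probe": truth_probe,
        "offsets": offsets,
        "manifest": manifest,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
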