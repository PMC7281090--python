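import numpy as np
import pytest

from silverquant.synthetic import SyntheticSpec, render_section


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_section():
    """One deterministic 256×256 synthetic section with ground truth."""
    spec = SyntheticSpec(dims=(256, 256), mpp=0.25, deposit_density=1200.0, seed=99)
    return render_section(spec, organ_label="tumor", slide_id="tumor_test")
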