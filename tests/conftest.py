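import numpy as np
import pytest

import mlmvar as m


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def spec_a():
    return m.build_model("A")


@pytest.fixture
def small_panel(spec_a):
    cfg = m.default_gen_config(spec_a, n_persons=8, n_times=12)
    return m.simulate_dataset(cfg, spec_a, 123)
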