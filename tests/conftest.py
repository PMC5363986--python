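import numpy as np
import pytest

import notchwnt as nw


@pytest.fixture(scope="session")
def params():
    return nw.default_params()


@pytest.fixture(scope="session")
def healthy_pair_traj(params):
    """One 36 h healthy-pair run at the standard conditions, shared."""
    scen = nw.build_scenario("healthy_pair", theta2=0.75, W=1.0,
                             params=params, horizon_h=36.0)
    return nw.run_deterministic(scen, params)


@pytest.fixture(scope="session")
def notch_pair_homogeneous(params):
    """Homogeneous decoupled Notch pair (the period-calibration run)."""
    return nw.run_notch_pair(params, ic=(0.5, 0.5), W=1.0, horizon_h=16.0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
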