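import numpy as np
import pytest

from cbfar import (ARProfile, ScriptConfig, build_challenge_script,
                   simulate_bundle)

SIM_RATE = 100.0


@pytest.fixture(scope="session")
def compact_script():
    return build_challenge_script(ScriptConfig().compact())


@pytest.fixture(scope="session")
def active_bundle(compact_script):
    return simulate_bundle(compact_script,
                           ARProfile.all_active(compact_script),
                           seed=1, rate=SIM_RATE)


@pytest.fixture(scope="session")
def passive_bundle(compact_script):
    return simulate_bundle(compact_script,
                           ARProfile.all_passive(compact_script),
                           seed=1, rate=SIM_RATE)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
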