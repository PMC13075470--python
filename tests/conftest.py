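import numpy as np
import pytest

import p2dvolt as pv


@pytest.fixture(scope="session")
def params():
    return pv.default_parameters()


@pytest.fixture(scope="session")
def baseline_cv(params):
    """Baseline modified-electrode CV at test resolution (grid-converged to
    <0.1% against the reference resolution)."""
    return pv.run_cv(params, nx=300, nr=60)


@pytest.fixture(scope="session")
def bare_cv(params):
    return pv.run_bare_cv(params, nx=600)


@pytest.fixture(scope="session")
def chrono_09(params):
    program = pv.PotentialProgram.step(E_step=-0.9, duration=80.0)
    return pv.run_chronoamperometry(params, program, nx=300, nr=60)
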