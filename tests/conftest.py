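import numpy as np
import pytest

from twoscale import Grid, build_mhb_model, find_steady_state, make_initial_conditions
from twoscale.mhb import sample_unimodal_family
from twoscale.steady import enumerate_steady_states


@pytest.fixture(scope="session")
def grid250():
    return Grid(L=2.0, N=250)


@pytest.fixture(scope="session")
def mhb_model():
    return build_mhb_model()


@pytest.fixture(scope="session")
def ss2(mhb_model, grid250):
    """Converged narrow (steady-state-2) profile from a restricted IC."""
    res = find_steady_state(
        mhb_model,
        grid250,
        make_initial_conditions("unimodal", 0.0, grid250, widths=0.18, amplitudes=0.7),
        t_max=160.0,
    )
    assert res.converged
    return res


@pytest.fixture(scope="session")
def enumeration(mhb_model, grid250):
    """Attractor enumeration over 24 space-filling unimodal initial conditions."""
    ics = sample_unimodal_family(grid250, 24, seed=1)
    states = enumerate_steady_states(
        mhb_model,
        grid250,
        lambda i: ics[i],
        n_samples=len(ics),
        dedup_tol=0.1,
        seed=11,
        check_stability=True,
        stability_trials=10,
        noise_amp=0.001,
        t_max=160.0,
    )
    return states
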