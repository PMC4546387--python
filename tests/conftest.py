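"""Shared fixtures: small synthetic traces and parameter sets.

Everything is generated programmatically; the simulator doubles as the
virtual rig for closed-loop tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from reifpop.core_model import EIFParams, RefractoryDynamics, rEIFParams
from reifpop.simulator import Trace, plain_eif


@pytest.fixture
def tl5_like_eif() -> EIFParams:
    """A parameter set with typical thick-tufted layer-5 magnitudes."""
    return EIFParams(C=284.0, tau=18.7, E=-68.5, V_T=-52.7, Delta_T=1.16)


@pytest.fixture
def bi_refractory() -> RefractoryDynamics:
    """Bi-exponential post-spike dynamics with a clear sag."""
    return RefractoryDynamics(
        g1=20.0, tau_g=20.0, V_T1=15.0, tau_T=13.0,
        E_mode="bi", E1=5.0, E2=15.0, tau_E1=50.0, tau_E2=10.0,
    )


@pytest.fixture
def bi_cell(tl5_like_eif, bi_refractory) -> rEIFParams:
    return rEIFParams(eif=tl5_like_eif, refractory=bi_refractory)


@pytest.fixture
def passive_cell() -> rEIFParams:
    """Effectively passive RC cell: threshold far away, tiny spike term."""
    eif = EIFParams(C=200.0, tau=20.0, E=-70.0, V_T=30.0, Delta_T=0.1)
    return plain_eif(eif)


def make_passive_trace(
    C: float = 200.0,
    tau: float = 20.0,
    E: float = -70.0,
    duration: float = 5000.0,
    dt: float = 0.05,
    seed: int = 0,
    sigma_i: float = 90.0,
) -> Trace:
    """Noiseless passive RC response to an OU-like current, Euler-integrated."""
    rng = np.random.default_rng(seed)
    n = int(round(duration / dt))
    # AR(1) current with ~5 ms correlation time
    a = np.exp(-dt / 5.0)
    I = np.empty(n)
    I[0] = 0.0
    w = sigma_i * np.sqrt(1 - a * a) * rng.standard_normal(n)
    for k in range(1, n):
        I[k] = a * I[k - 1] + w[k]
    V = np.empty(n)
    V[0] = E
    for k in range(n - 1):
        V[k + 1] = V[k] + dt * ((E - V[k]) / tau + I[k] / C)
    return Trace(dt=dt, I=I, V=V)


@pytest.fixture
def passive_trace() -> Trace:
    return make_passive_trace()
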