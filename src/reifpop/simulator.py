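"""Forward-Euler integration of the refractory EIF model.

The model is integrated with a forward Euler scheme at a 50 us step
(matching a 20 kHz acquisition rate).  Spike handling follows the standard
rEIF rules: integration stops when V reaches 30 mV (the spike event time),
halts for a refractory period t_ref = 4 ms, then resumes from the reset
voltage with the post-spike parameters (g, E, V_T) restarted at their jump
values.  The post-spike dynamics are non-cumulative (renewal): each spike
resets the post-spike clock.  Beyond 200 ms after a spike the parameters
are exactly at steady state, matching the 200 ms post-spike exclusion used
during extraction.

The action-potential downswing is not modelled; during the 4 ms halt the
recorded voltage is a linear ramp from the 30 mV crossing down to the reset
value, purely cosmetic, and those samples are flagged
(``trace.metadata['refractory_mask']``) so analyses can exclude them.

This module doubles as the package's virtual rig: :func:`virtual_cell`
draws a single cell from the built-in class populations so the extraction
pipeline can be exercised closed-loop against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

from .core_model import EIFParams, RefractoryDynamics, rEIFParams, EXP_ARG_CAP

__all__ = ["Trace", "SpikeTrain", "simulate", "virtual_cell", "V_SPIKE", "POST_SPIKE_WINDOW"]

#: voltage at which integration stops and a spike is registered, mV.
V_SPIKE = 30.0

#: horizon of the post-spike parameter dynamics, ms; beyond it parameters
#: are exactly steady-state.
POST_SPIKE_WINDOW = 200.0

#: canonical integration / acquisition step, ms (20 kHz).
DT_DEFAULT = 0.05


@dataclass
class Trace:
    """Uniformly sampled current/voltage time series.

    At least one of the channels must be present; when both are, they share
    the time base.  ``metadata`` is a free-form key/value store (the
    simulator puts the refractory-sample mask there).
    """

    dt: float
    I: Optional[np.ndarray] = None
    V: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.I is None and self.V is None:
            raise ValueError("a Trace needs at least one of I and V")
        if self.I is not None:
            self.I = np.asarray(self.I, dtype=float)
        if self.V is not None:
            self.V = np.asarray(self.V, dtype=float)
        if self.I is not None and self.V is not None and len(self.I) != len(self.V):
            raise ValueError("I and V channels must have equal length")

    def __len__(self) -> int:
        return len(self.I) if self.I is not None else len(self.V)

    @property
    def duration(self) -> float:
        return len(self) * self.dt

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self)) * self.dt


@dataclass(frozen=True)
class SpikeTrain:
    """Strictly increasing spike times (ms) over a recording of ``duration`` ms."""

    times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0 or t[-1] > self.duration):
            raise ValueError("spike times must be strictly increasing within [0, duration]")

    def __len__(self) -> int:
        return len(self.times)

    def rate(self) -> float:
        """Mean firing rate in Hz."""
        return 1000.0 * len(self.times) / self.duration


@njit(cache=False)
def _integrate(I, dt, C, tau, E0, VT0, DT, g1, tau_g, VT1, tau_T,
               c1, tau_ea, c2, tau_eb, t_ref, v_reset, v0, noise,
               v_spike, post_window, exp_cap):
    n = I.shape[0]
    V = np.empty(n)
    flags = np.zeros(n, dtype=np.uint8)
    max_spikes = n // max(int(t_ref / dt), 1) + 1
    spike_idx = np.empty(max_spikes, dtype=np.int64)
    n_spk = 0

    g0 = C / tau
    n_ref = int(round(t_ref / dt))
    have_noise = noise.shape[0] == n

    V[0] = v0
    last_spike = -1  # sample index of last spike peak; -1 = none yet
    k = 0
    while k < n - 1:
        v = V[k]
        # post-spike parameter values at the current time
        if last_spike >= 0:
            ts = (k - last_spike) * dt  # time since spike peak
            if ts <= post_window:
                x = ts - t_ref
                g = g0 + g1 * np.exp(-x / tau_g)
                vt = VT0 + VT1 * np.exp(-x / tau_T)
                e = E0 + c1 * np.exp(-x / tau_ea) + c2 * np.exp(-x / tau_eb)
            else:
                g, vt, e = g0, VT0, E0
        else:
            g, vt, e = g0, VT0, E0
        arg = (v - vt) / DT
        if arg > exp_cap:
            arg = exp_cap
        F = (g / C) * (e - v + DT * np.exp(arg))
        v_new = v + dt * (F + I[k] / C)
        if have_noise:
            v_new += noise[k]
        if v_new >= v_spike:
            # spike at sample k+1; clamp, ramp through the refractory halt
            peak = k + 1
            spike_idx[n_spk] = peak
            n_spk += 1
            V[peak] = v_spike
            flags[peak] = 1
            stop = peak + n_ref
            if stop >= n:
                for j in range(peak + 1, n):
                    frac = (j - peak) / n_ref
                    V[j] = v_spike + frac * (v_reset - v_spike)
                    flags[j] = 1
                k = n - 1
                break
            for j in range(peak + 1, stop):
                frac = (j - peak) / n_ref
                V[j] = v_spike + frac * (v_reset - v_spike)
                flags[j] = 1
            V[stop] = v_reset
            last_spike = peak
            k = stop
        else:
            V[k + 1] = v_new
            k += 1
    return V, flags, spike_idx[:n_spk]


def _refractory_arrays(p: rEIFParams) -> tuple:
    """Unified (c1, tau_ea, c2, tau_eb) representation of the E dynamics."""
    r = p.refractory
    if r.E_mode == "bi":
        return (-r.E1, r.tau_E1, r.E2, r.tau_E2)
    return (r.E_mono, r.tau_mono, 0.0, 1.0)


def simulate(
    p: rEIFParams,
    current: Trace,
    V0: Optional[float] = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    dt: float = DT_DEFAULT,
) -> tuple[Trace, SpikeTrain]:
    """Integrate the rEIF model against an injected-current trace.

    Parameters
    ----------
    p : rEIFParams
        Model parameters.
    current : Trace
        Trace with an I channel.  If its dt differs from the simulator step
        it is linearly resampled (with a warning in the output metadata).
    V0 : float, optional
        Initial voltage; defaults to the resting potential.
    noise_sd : float
        SD of additive white voltage noise in mV per sqrt(ms); used for
        intrinsic-unreliability experiments.  0 disables noise.
    seed : int
        Seed for the voltage noise (ignored when noise_sd == 0).

    Returns
    -------
    (Trace, SpikeTrain)
        The trace carries both I and V plus ``metadata['refractory_mask']``
        flagging the clamped spike/ramp samples.
    """
    if current.I is None:
        raise ValueError("current trace must carry an I channel")
    I = current.I
    meta: dict = {}
    if abs(current.dt - dt) > 1e-12:
        t_old = current.t
        n_new = int(round(len(I) * current.dt / dt))
        t_new = np.arange(n_new) * dt
        I = np.interp(t_new, t_old, I)
        meta["resampled_from_dt"] = current.dt
    if V0 is None:
        V0 = p.eif.E
    n = len(I)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise = noise_sd * np.sqrt(dt) * rng.standard_normal(n)
    else:
        noise = np.empty(0)
    c1, tau_ea, c2, tau_eb = _refractory_arrays(p)
    r = p.refractory
    V, flags, spike_idx = _integrate(
        np.ascontiguousarray(I, dtype=np.float64), dt,
        p.eif.C, p.eif.tau, p.eif.E, p.eif.V_T, p.eif.Delta_T,
        r.g1, r.tau_g, r.V_T1, r.tau_T, c1, tau_ea, c2, tau_eb,
        r.t_ref, p.v_reset, float(V0), noise,
        V_SPIKE, POST_SPIKE_WINDOW, EXP_ARG_CAP,
    )
    if not np.all(np.isfinite(V)):
        raise FloatingPointError("non-finite voltage encountered during integration")
    meta["refractory_mask"] = flags.astype(bool)
    trace = Trace(dt=dt, I=I, V=V, metadata=meta)
    spikes = SpikeTrain(times=spike_idx * dt, duration=n * dt)
    return trace, spikes


def plain_eif(p: EIFParams, V_reset: Optional[float] = None, t_ref: float = 4.0) -> rEIFParams:
    """Wrap steady-state parameters as an rEIF with no post-spike dynamics.

    With all jumps at zero the simulator reduces to the plain EIF with a
    fixed refractory halt and reset.
    """
    refr = RefractoryDynamics(
        g1=0.0, tau_g=1.0, V_T1=0.0, tau_T=1.0,
        E_mode="mono", E_mono=0.0, tau_mono=1.0,
        t_ref=t_ref, V_reset=V_reset,
    )
    return rEIFParams(eif=p, refractory=refr)


def virtual_cell(class_name: str, seed: int) -> rEIFParams:
    """Draw one cell from the built-in population of the given class.

    Deterministic under ``seed``; classes are 'L23', 'L4', 'SL5', 'TL5'.
    """
    from .population import builtin_class_spec, generate_reif_population

    spec = builtin_class_spec(class_name)
    return generate_reif_population(spec, 1, seed=seed)[0]
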