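"""Stimulation currents: naturalistic fluctuating drive and square pulses.

The naturalistic stimulus mimics in-vivo-like synaptic bombardment as the
sum of two Ornstein-Uhlenbeck processes with fast (AMPA-like, 3 ms) and
slow (GABA_A-like, 10 ms) correlation times,

    I(t) = gain * (dc + x_fast(t) + x_slow(t)),

where each x is a zero-mean OU process with stationary SD sigma.  Two
variance presets are used: low (sigma_slow = sigma_fast = 0.18) and high
(sigma_slow = 0.25, sigma_fast = 0.36), with DC biases 0.5 or 1 and a
multiplicative gain in pA chosen so the driven cell fires at 5-15 Hz.

Each OU component is advanced with the exact stationary update

    x_{k+1} = x_k * exp(-dt/tau) + sigma * sqrt(1 - exp(-2*dt/tau)) * xi_k,

(xi standard normal, x_0 drawn from the stationary law), so the process
statistics are independent of the integration step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .simulator import Trace

__all__ = [
    "OUStimulusConfig",
    "StepProtocolConfig",
    "generate_ou_current",
    "generate_step_current",
    "OU_PRESETS",
]

#: the two fluctuation-amplitude presets (dimensionless pre-gain SDs).
OU_PRESETS = {
    "low": {"sigma_fast": 0.18, "sigma_slow": 0.18},
    "high": {"sigma_fast": 0.36, "sigma_slow": 0.25},
}


@dataclass(frozen=True)
class OUStimulusConfig:
    """Configuration of the summed-OU fluctuating current."""

    duration: float
    gain: float
    sigma_fast: float = 0.18
    sigma_slow: float = 0.18
    dc: float = 0.5
    tau_fast: float = 3.0
    tau_slow: float = 10.0
    dt: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau_fast <= 0 or self.tau_slow <= 0:
            raise ValueError("OU time constants must be positive")
        if self.sigma_fast < 0 or self.sigma_slow < 0:
            raise ValueError("OU sigmas must be non-negative")
        if self.duration <= 0 or self.dt <= 0:
            raise ValueError("duration and dt must be positive")

    @classmethod
    def preset(cls, name: str, **kwargs) -> "OUStimulusConfig":
        """Build a config from a named variance preset ('low' or 'high')."""
        if name not in OU_PRESETS:
            raise ValueError(f"unknown preset {name!r}; choose from {sorted(OU_PRESETS)}")
        return cls(**{**OU_PRESETS[name], **kwargs})


@dataclass(frozen=True)
class StepProtocolConfig:
    """Square-pulse protocol: a train of 1 s steps with baselines between."""

    amplitudes: tuple
    step_duration: float = 1000.0
    inter_step_interval: float = 500.0
    dt: float = 0.05

    def __post_init__(self) -> None:
        if len(self.amplitudes) == 0:
            raise ValueError("at least one step amplitude is required")
        if self.step_duration < 400:
            raise ValueError(
                "step_duration must be >= 400 ms (a steady 200 ms window plus onset)"
            )
        if self.dt <= 0 or self.inter_step_interval < 0:
            raise ValueError("dt must be positive and inter_step_interval non-negative")


def _ou_path(n: int, tau: float, sigma: float, dt: float, rng: np.random.Generator) -> np.ndarray:
    """Exact stationary OU sample path of length n.

    The AR(1) recursion x_k = a*x_{k-1} + b*xi_k is evaluated with
    ``scipy.signal.lfilter`` (an IIR filter with denominator [1, -a]).
    """
    from scipy.signal import lfilter

    if sigma == 0.0:
        return np.zeros(n)
    a = np.exp(-dt / tau)
    b = sigma * np.sqrt(-np.expm1(-2.0 * dt / tau))
    u = b * rng.standard_normal(n)
    u[0] = sigma * rng.standard_normal()  # stationary initial condition
    return lfilter([1.0], [1.0, -a], u)


def generate_ou_current(cfg: OUStimulusConfig) -> Trace:
    """Generate the summed-OU fluctuating current as a current-only Trace."""
    n = int(round(cfg.duration / cfg.dt))
    rng = np.random.default_rng(cfg.seed)
    x_fast = _ou_path(n, cfg.tau_fast, cfg.sigma_fast, cfg.dt, rng)
    x_slow = _ou_path(n, cfg.tau_slow, cfg.sigma_slow, cfg.dt, rng)
    current = cfg.gain * (cfg.dc + x_fast + x_slow)
    meta = {"kind": "ou", "seed": cfg.seed, "gain": cfg.gain, "dc": cfg.dc}
    return Trace(dt=cfg.dt, I=current, metadata=meta)


def generate_step_current(cfg: StepProtocolConfig) -> Trace:
    """Concatenated baseline/step/baseline epochs, one per amplitude.

    The epoch boundaries (sample indices of each step's onset and offset)
    are reported in ``metadata['epochs']`` as a list of
    ``{'amplitude', 'start', 'stop'}`` entries.
    """
    n_base = int(round(cfg.inter_step_interval / cfg.dt))
    n_step = int(round(cfg.step_duration / cfg.dt))
    chunks = []
    epochs = []
    pos = 0
    for amp in cfg.amplitudes:
        chunks.append(np.zeros(n_base))
        pos += n_base
        chunks.append(np.full(n_step, float(amp)))
        epochs.append({"amplitude": float(amp), "start": pos, "stop": pos + n_step})
        pos += n_step
        chunks.append(np.zeros(n_base))
        pos += n_base
    current = np.concatenate(chunks)
    meta = {"kind": "steps", "epochs": epochs}
    return Trace(dt=cfg.dt, I=current, metadata=meta)


def calibrate_gain(
    params,
    cfg: OUStimulusConfig,
    rate_range: tuple = (5.0, 15.0),
    calibration_duration: float = 10_000.0,
    gain_bounds: tuple = (200.0, 2000.0),
    max_iter: int = 12,
    seed: Optional[int] = None,
):
    """Choose a gain that drives ``params`` at a firing rate inside ``rate_range``.

    Mirrors the in-experiment practice of scaling the injected current until
    the cell fires at 5-15 Hz: bisects on the gain against short simulations
    (``calibration_duration`` ms each).  Returns the calibrated gain in pA.
    The rate is targeted at the geometric midpoint of ``rate_range``; the
    search stops as soon as the measured rate falls inside the range.
    """
    from .simulator import simulate  # local import to avoid a cycle at module load

    lo, hi = gain_bounds
    target = float(np.sqrt(rate_range[0] * rate_range[1]))
    seed = cfg.seed if seed is None else seed

    def rate_at(gain: float) -> float:
        c = replace(cfg, gain=gain, duration=calibration_duration, seed=seed)
        _, spikes = simulate(params, generate_ou_current(c), V0=params.eif.E)
        return 1000.0 * len(spikes.times) / calibration_duration

    r_lo, r_hi = rate_at(lo), rate_at(hi)
    if r_lo >= rate_range[0]:
        return lo
    if r_hi <= rate_range[1]:
        return hi
    for _ in range(max_iter):
        mid = float(np.sqrt(lo * hi))
        r = rate_at(mid)
        if rate_range[0] <= r <= rate_range[1] and abs(r - target) < 3.0:
            return mid
        if r < target:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))
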