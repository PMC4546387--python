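"""Parameterisation of the (refractory) exponential integrate-and-fire model.

The subthreshold voltage of an EIF neuron obeys

    dV/dt = F(V) + I_in / C,
    F(V)  = (1/tau) * (E - V + Delta_T * exp((V - V_T) / Delta_T)),

with membrane time constant ``tau = C / g``, resting potential ``E``,
spike-onset threshold ``V_T`` and spike sharpness ``Delta_T``.  The
refractory EIF (rEIF) extends this with non-cumulative post-spike dynamics
of the conductance, resting potential and threshold: with ``t`` the time
since the last spike peak and ``t_ref`` the refractory time,

    g(t)   = g0 + g1 * exp(-(t - t_ref) / tau_g),
    E(t)   = E0 - E1 * exp(-(t - t_ref) / tau_E1)
                + E2 * exp(-(t - t_ref) / tau_E2)     (bi-exponential), or
    E(t)   = E0 + E_mono * exp(-(t - t_ref) / tau_mono)  (mono-exponential),
    V_T(t) = V_T0 + V_T1 * exp(-(t - t_ref) / tau_T),

where ``g0, E0, V_T0`` are the steady-state (EIF) values.  The
bi-exponential form produces an after-spike sag of the instantaneous
resting potential, the signature of the h-current; the post-spike E
timecourse is summarised by its jump, sag depth, sag time and
baseline-crossing time.

Units follow :mod:`reifpop.units` (mV, ms, pA, pF, nS).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "EIFParams",
    "RefractoryDynamics",
    "rEIFParams",
    "PostSpikeSummary",
    "InfeasibleSummaryError",
    "forcing_term",
    "refractory_timecourse",
    "summarize_E_dynamics",
    "invert_E_summary",
    "EXP_ARG_CAP",
    "PARAMS_VERSION",
]

#: cap on the argument of the spike-initiation exponential.  Any voltage for
#: which (V - V_T)/Delta_T exceeds this is far inside the spike upswing, so
#: capping changes no subthreshold behaviour while keeping arithmetic finite.
EXP_ARG_CAP = 40.0

#: schema tag written into serialised parameter files.
PARAMS_VERSION = "reif_params_v1"

#: refractory time after the spike peak during which integration is halted.
T_REF_DEFAULT = 4.0


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class EIFParams:
    """Steady-state EIF parameters.

    Attributes
    ----------
    C : float
        Membrane capacitance, pF.
    tau : float
        Membrane time constant, ms.
    E : float
        Resting (equilibrium) potential, mV.
    V_T : float
        Spike-onset threshold, mV.
    Delta_T : float
        Spike sharpness, mV.
    """

    C: float
    tau: float
    E: float
    V_T: float
    Delta_T: float

    def __post_init__(self) -> None:
        _require(self.C > 0, f"C must be positive, got {self.C}")
        _require(self.tau > 0, f"tau must be positive, got {self.tau}")
        _require(self.Delta_T > 0, f"Delta_T must be positive, got {self.Delta_T}")
        _require(
            self.V_T > self.E,
            f"V_T ({self.V_T}) must exceed E ({self.E}) for an excitable cell",
        )
        for name in ("C", "tau", "E", "V_T", "Delta_T"):
            _require(math.isfinite(getattr(self, name)), f"{name} must be finite")

    @property
    def g(self) -> float:
        """Input conductance C/tau, in nS when C is in pF and tau in ms."""
        return self.C / self.tau

    def to_dict(self) -> dict:
        d = asdict(self)
        d["version"] = PARAMS_VERSION
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EIFParams":
        return cls(C=d["C"], tau=d["tau"], E=d["E"], V_T=d["V_T"], Delta_T=d["Delta_T"])


@dataclass(frozen=True)
class RefractoryDynamics:
    """Post-spike parameter dynamics of the rEIF model.

    ``E_mode`` selects the form of the post-spike resting-potential
    relaxation: ``"bi"`` (jump followed by a sag below baseline, requires
    E1, E2, tau_E1, tau_E2) or ``"mono"`` (plain exponential decay of the
    jump, requires E_mono, tau_mono).

    ``V_reset`` is the voltage at which integration resumes ``t_ref`` after
    the spike peak.  When ``None`` it defaults to the steady-state threshold
    V_T0 of the companion :class:`EIFParams` (the experimental reset is a
    data-dependent quantity, typically just above V_T0, and has no tabulated
    population value; see docs/methods.md).
    """

    g1: float
    tau_g: float
    V_T1: float
    tau_T: float
    E_mode: str
    E1: Optional[float] = None
    E2: Optional[float] = None
    tau_E1: Optional[float] = None
    tau_E2: Optional[float] = None
    E_mono: Optional[float] = None
    tau_mono: Optional[float] = None
    t_ref: float = T_REF_DEFAULT
    V_reset: Optional[float] = None

    def __post_init__(self) -> None:
        _require(self.t_ref > 0, "t_ref must be positive")
        _require(self.tau_g > 0, "tau_g must be positive")
        _require(self.tau_T > 0, "tau_T must be positive")
        _require(math.isfinite(self.g1), "g1 must be finite")
        _require(math.isfinite(self.V_T1), "V_T1 must be finite")
        if self.E_mode == "bi":
            for name in ("E1", "E2", "tau_E1", "tau_E2"):
                _require(getattr(self, name) is not None, f"bi mode requires {name}")
            _require(self.tau_E1 > 0 and self.tau_E2 > 0, "E decay constants must be positive")
        elif self.E_mode == "mono":
            for name in ("E_mono", "tau_mono"):
                _require(getattr(self, name) is not None, f"mono mode requires {name}")
            _require(self.tau_mono > 0, "tau_mono must be positive")
        else:
            raise ValueError(f"E_mode must be 'mono' or 'bi', got {self.E_mode!r}")

    def to_dict(self) -> dict:
        return {k: v for k, v in asdict(self).items() if v is not None}

    @classmethod
    def from_dict(cls, d: dict) -> "RefractoryDynamics":
        keys = (
            "g1", "tau_g", "V_T1", "tau_T", "E_mode", "E1", "E2",
            "tau_E1", "tau_E2", "E_mono", "tau_mono", "t_ref", "V_reset",
        )
        kwargs = {k: d[k] for k in keys if k in d}
        return cls(**kwargs)


@dataclass(frozen=True)
class rEIFParams:
    """Full refractory-EIF parameter set: steady state plus post-spike dynamics."""

    eif: EIFParams
    refractory: RefractoryDynamics

    @property
    def v_reset(self) -> float:
        """Effective reset voltage (defaults to the steady-state threshold)."""
        if self.refractory.V_reset is not None:
            return self.refractory.V_reset
        return self.eif.V_T

    def to_dict(self) -> dict:
        d = {"version": PARAMS_VERSION}
        d.update({k: v for k, v in self.eif.to_dict().items() if k != "version"})
        d.update(self.refractory.to_dict())
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "rEIFParams":
        return cls(eif=EIFParams.from_dict(d), refractory=RefractoryDynamics.from_dict(d))


@dataclass(frozen=True)
class PostSpikeSummary:
    """Summary of the post-spike resting-potential timecourse.

    Times are measured from the end of the refractory period (i.e. the time
    origin of the exponentials).  ``E_jump`` is the initial displacement of
    E from baseline; for a sagging (bi-exponential) timecourse ``t_0`` is
    the baseline-crossing time, ``t_sag`` the time of the deepest undershoot
    and ``E_sag`` its depth (positive).  ``has_sag`` applies the empirical
    sag criterion E_sag > 0.5 mV.  When the timecourse never undershoots the
    baseline the sag fields are ``None``.
    """

    E_jump: float
    has_sag: bool
    E_sag: Optional[float] = None
    t_sag: Optional[float] = None
    t_0: Optional[float] = None


class InfeasibleSummaryError(ValueError):
    """No bi-exponential timecourse realises the requested summary."""


def forcing_term(p: EIFParams, V) -> np.ndarray | float:
    """EIF forcing term F(V) in mV/ms.

    The spike-initiation exponential argument is capped at
    :data:`EXP_ARG_CAP`; any voltage beyond the cap is already spike-bound
    so only the (large, finite) magnitude matters.
    """
    V = np.asarray(V, dtype=float)
    arg = np.minimum((V - p.V_T) / p.Delta_T, EXP_ARG_CAP)
    out = (p.E - V + p.Delta_T * np.exp(arg)) / p.tau
    return out if out.ndim else float(out)


def _e_offset(r: RefractoryDynamics, x) -> np.ndarray:
    """Displacement of E from baseline at time ``x`` past the refractory end."""
    x = np.asarray(x, dtype=float)
    if r.E_mode == "bi":
        return -r.E1 * np.exp(-x / r.tau_E1) + r.E2 * np.exp(-x / r.tau_E2)
    return r.E_mono * np.exp(-x / r.tau_mono)


def refractory_timecourse(p: rEIFParams, t_since_spike):
    """Post-spike parameter values (g, E, V_T) at ``t_since_spike`` >= t_ref.

    ``t_since_spike`` is measured from the spike peak; the exponentials are
    anchored at the end of the refractory period.  Accepts scalars or
    arrays; returns a matching triple.
    """
    t = np.asarray(t_since_spike, dtype=float)
    r = p.refractory
    if np.any(t < r.t_ref - 1e-12):
        raise ValueError(
            f"t_since_spike must be >= t_ref ({r.t_ref} ms); got min {t.min()}"
        )
    x = np.maximum(t - r.t_ref, 0.0)
    g = p.eif.g + r.g1 * np.exp(-x / r.tau_g)
    V_T = p.eif.V_T + r.V_T1 * np.exp(-x / r.tau_T)
    E = p.eif.E + _e_offset(r, x)
    if t.ndim == 0:
        return float(g), float(E), float(V_T)
    return g, E, V_T


# time horizon and resolution for root bracketing of the E timecourse
_T_MAX = 2000.0
_GRID_N = 2000


def summarize_E_dynamics(p: rEIFParams) -> PostSpikeSummary:
    """Summarise the post-spike E timecourse by jump, sag depth and timing.

    The jump is the displacement at the end of the refractory period.  For a
    bi-exponential timecourse the first baseline crossing ``t_0`` and the
    subsequent deepest undershoot (``t_sag``, ``E_sag``) are located by
    bracketing on a log-spaced grid over (0, 2000] ms followed by Brent
    refinement (1e-6 ms tolerance).  A timecourse that never crosses the
    baseline has no sag.  ``has_sag`` requires E_sag > 0.5 mV; a shallower
    undershoot keeps its measured values but is classified as no-sag.
    """
    r = p.refractory
    E_jump = float(_e_offset(r, 0.0))
    if r.E_mode == "mono":
        return PostSpikeSummary(E_jump=E_jump, has_sag=False)

    grid = np.concatenate([[0.0], np.geomspace(1e-3, _T_MAX, _GRID_N)])
    vals = _e_offset(r, grid)
    # first downward crossing of the baseline
    sign = np.sign(vals)
    down = np.nonzero((sign[:-1] > 0) & (sign[1:] <= 0))[0]
    if down.size == 0 or vals[0] <= 0:
        return PostSpikeSummary(E_jump=E_jump, has_sag=False)
    i = down[0]
    f = lambda x: float(_e_offset(r, x))
    t_0 = brentq(f, grid[i], grid[i + 1], xtol=1e-6)

    # deepest undershoot after the crossing: stationary point of the offset
    df = lambda x: float(
        r.E1 / r.tau_E1 * np.exp(-x / r.tau_E1)
        - r.E2 / r.tau_E2 * np.exp(-x / r.tau_E2)
    )
    post = grid[grid > t_0]
    if post.size == 0:
        return PostSpikeSummary(E_jump=E_jump, has_sag=False)
    dvals = np.array([df(x) for x in post])
    sgn = np.sign(dvals)
    flips = np.nonzero(sgn[:-1] * sgn[1:] < 0)[0]
    if flips.size:
        j = flips[0]
        t_sag = brentq(df, post[j], post[j + 1], xtol=1e-6)
    else:
        # minimum at the grid edge (decay slower than the horizon)
        t_sag = float(post[np.argmin(_e_offset(r, post))])
    E_sag = -f(t_sag)
    if E_sag <= 0:
        return PostSpikeSummary(E_jump=E_jump, has_sag=False)
    return PostSpikeSummary(
        E_jump=E_jump,
        has_sag=bool(E_sag > 0.5),
        E_sag=float(E_sag),
        t_sag=float(t_sag),
        t_0=float(t_0),
    )


def invert_E_summary(s: PostSpikeSummary) -> tuple[float, float, float, float]:
    """Recover bi-exponential parameters (E1, E2, tau_E1, tau_E2) from a summary.

    The four defining conditions (jump value, baseline crossing at t_0,
    stationarity at t_sag, depth E_sag at t_sag) reduce analytically to a
    single scalar equation in the rate difference d = 1/tau_E2 - 1/tau_E1:
    with Dt = t_sag - t_0,

        r1(d) = d / (exp(d*Dt) - 1),
        E1(d) = E_sag * exp(r1*t_sag) / (1 - exp(-d*Dt)),
        residual(d) = E1(d) * (exp(d*t_0) - 1) - E_jump,

    which is solved by bracketing on a log grid and Brent's method.  The
    result round-trips through :func:`summarize_E_dynamics` to within 1e-3
    relative on all four summary fields.

    Raises
    ------
    InfeasibleSummaryError
        If the summary violates the ordering t_0 < t_sag, is not a sag
        summary, or no bi-exponential satisfies it (the caller resamples).
    """
    if not s.has_sag or s.E_sag is None or s.t_sag is None or s.t_0 is None:
        raise InfeasibleSummaryError("summary does not describe a sagging timecourse")
    J, S, ts, t0 = s.E_jump, s.E_sag, s.t_sag, s.t_0
    if not (J > 0 and S > 0 and t0 > 0 and ts > t0):
        raise InfeasibleSummaryError(
            f"infeasible summary: need 0 < t_0 < t_sag and positive jump/sag, "
            f"got E_jump={J}, E_sag={S}, t_sag={ts}, t_0={t0}"
        )
    Dt = ts - t0

    def residual(d: float) -> float:
        r1 = d / math.expm1(d * Dt)
        e1 = S * math.exp(min(r1 * ts, 700.0)) / (-math.expm1(-d * Dt))
        if d * t0 > 700.0:  # far past any root; avoid overflow
            return 1e300
        return e1 * math.expm1(d * t0) - J

    ds = np.geomspace(1e-6, 50.0 / Dt, 400)
    with np.errstate(over="ignore"):
        r1s = ds / np.expm1(ds * Dt)
        e1s = S * np.exp(np.minimum(r1s * ts, 700.0)) / (-np.expm1(-ds * Dt))
        res = np.where(
            ds * t0 > 700.0, 1e300, e1s * np.expm1(np.minimum(ds * t0, 700.0)) - J
        )
    flips = np.nonzero(np.sign(res[:-1]) * np.sign(res[1:]) < 0)[0]
    if flips.size == 0:
        raise InfeasibleSummaryError(
            f"no bi-exponential realises summary (E_jump={J}, E_sag={S}, "
            f"t_sag={ts}, t_0={t0})"
        )
    i = flips[0]
    d = brentq(residual, ds[i], ds[i + 1], xtol=1e-12, rtol=1e-14)
    r1 = d / math.expm1(d * Dt)
    r2 = r1 + d
    E1 = S * math.exp(r1 * ts) / (-math.expm1(-d * Dt))
    E2 = E1 * math.exp(d * t0)
    return E1, E2, 1.0 / r1, 1.0 / r2
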