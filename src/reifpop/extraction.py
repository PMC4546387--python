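"""Dynamic I-V extraction of (r)EIF models from current-clamp recordings.

Given a fluctuating-current recording (injected current I_in and voltage V
at a 20 kHz time base), the method proceeds:

1. **Capacitance** by variance minimisation: over samples in a narrow
   subthreshold voltage window, C* = argmin_C Var(I_in - C dV/dt), which has
   the closed form C* = Cov(I_in, dV/dt) / Var(dV/dt).
2. **Ionic current** I_ion(t) = I_in(t) - C dV/dt(t).
3. **Dynamic I-V curve**: the mean of I_ion in 1 mV voltage bins, with all
   samples in the 200 ms after each spike excluded so only steady-state
   behaviour enters.
4. **EIF fit**: weighted least squares of F(V) = -I_dyn(V)/C against the
   exponential integrate-and-fire form, yielding (tau, E, V_T, Delta_T).
5. **Post-spike slices**: the same voltage-binned fit, with C and Delta_T
   frozen at their steady-state values, applied to samples grouped by time
   since the last spike, yielding per-window (g, E, V_T).
6. **Refractory dynamics**: exponential fits of the slice parameters
   against window midpoints give the post-spike jumps and decay constants;
   the E timecourse is fitted both mono- and bi-exponentially and the bi
   form is selected iff its implied sag depth exceeds 0.5 mV.

Derivatives are central differences at the acquisition rate with no
smoothing (symmetric white noise cancels from the variance-minimising
capacitance).  Samples flagged by the simulator as refractory-clamped (or
whose difference stencil touches one) are excluded everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .core_model import EIFParams, EXP_ARG_CAP, RefractoryDynamics, rEIFParams
from .protocol_metrics import detect_spikes
from .simulator import SpikeTrain, Trace

__all__ = [
    "DynamicIV",
    "SliceFit",
    "ExtractionConfig",
    "ExtractionResult",
    "estimate_capacitance",
    "compute_ionic_current",
    "compute_dynamic_iv",
    "fit_eif",
    "fit_post_spike_slices",
    "fit_refractory_dynamics",
    "extract_cell",
    "DEFAULT_SLICE_WINDOWS",
]

#: post-spike time windows (ms since spike peak) for the slice fits;
#: roughly geometric, sub-millisecond early.  Narrow early windows keep the
#: within-window drift of the relaxing parameters small compared to the
#: voltage spread, which otherwise attenuates the slice conductance
#: estimate (the per-slice SEs weight the downstream timecourse fits, so
#: the noisier narrow windows do not dominate).
DEFAULT_SLICE_WINDOWS = (
    (5.0, 5.5), (5.5, 6.0), (6.0, 6.5), (6.5, 7.0), (7.0, 8.0), (8.0, 9.0),
    (9.0, 10.0), (10.0, 12.0), (12.0, 14.0), (14.0, 17.0), (17.0, 21.0),
    (21.0, 26.0), (26.0, 33.0), (33.0, 42.0), (42.0, 55.0), (55.0, 75.0),
    (75.0, 100.0), (100.0, 140.0), (140.0, 200.0),
)

T_REF = 4.0


@dataclass(frozen=True)
class DynamicIV:
    """Voltage-binned mean ionic current with per-bin uncertainty."""

    bin_centers: np.ndarray  # mV
    mean_current: np.ndarray  # pA
    se_current: np.ndarray  # pA
    counts: np.ndarray
    exclusion_window: float  # ms of post-spike data dropped


@dataclass(frozen=True)
class SliceFit:
    """EIF parameters refit in one post-spike time slice (C, Delta_T frozen).

    ``V_T`` is NaN when the slice's voltage samples never reach the
    spike-initiation upturn (common early after a spike, when the threshold
    is strongly elevated): the threshold is then unidentifiable from that
    slice and is excluded from the downstream timecourse fit.
    """

    window: tuple  # (t_start, t_end) ms post-spike
    g: float  # nS
    E: float  # mV
    V_T: float  # mV, NaN if unidentified in this slice
    n_points: int
    converged: bool
    se: Optional[dict] = None
    #: voltage-binned empirical forcing of this slice, (V, F, se_F) arrays;
    #: kept so the threshold timecourse can be refined jointly across slices
    bins: Optional[tuple] = None


@dataclass(frozen=True)
class ExtractionConfig:
    """Tunable thresholds of the extraction pipeline."""

    bin_width: float = 1.0  # mV
    exclusion: float = 200.0  # ms post-spike dropped from steady-state stages
    min_count: int = 10  # samples per retained voltage bin
    cap_window_halfwidth: float = 1.0  # mV around the median subthreshold V
    min_cap_samples: int = 500
    fit_margin: float = 5.0  # mV above the F-minimum bin kept in EIF fits
    slice_windows: tuple = DEFAULT_SLICE_WINDOWS
    min_slice_samples: int = 200
    bootstrap: int = 0  # spike-resampled SE replicates for slice fits (0 = off)
    seed: int = 0
    spike_threshold: float = 0.0  # mV, for spike detection


@dataclass
class ExtractionResult:
    """Everything the pipeline produced for one cell."""

    C: float
    eif: EIFParams
    params: Optional[rEIFParams]  # None when refractory dynamics unavailable
    dynamic_iv: DynamicIV
    slices: list
    spikes: SpikeTrain
    diagnostics: dict


class ExtractionError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _dvdt(V: np.ndarray, dt: float) -> np.ndarray:
    """Voltage derivative: central differences, one-sided at the ends."""
    d = np.empty_like(V)
    d[1:-1] = (V[2:] - V[:-2]) / (2.0 * dt)
    d[0] = (V[1] - V[0]) / dt
    d[-1] = (V[-1] - V[-2]) / dt
    return d


def _stencil_valid(trace: Trace) -> np.ndarray:
    """Samples whose central-difference stencil avoids clamped samples."""
    n = len(trace)
    mask = trace.metadata.get("refractory_mask")
    if mask is None:
        return np.ones(n, dtype=bool)
    bad = np.asarray(mask, dtype=bool).copy()
    bad[:-1] |= bad[1:]
    bad[1:] |= np.asarray(mask, dtype=bool)[:-1]
    return ~bad


def _time_since_spike(n: int, dt: float, spike_times: np.ndarray) -> np.ndarray:
    """Per-sample time since the most recent spike peak (inf before the first)."""
    t = np.arange(n) * dt
    idx = np.searchsorted(spike_times, t, side="right")
    tss = np.full(n, np.inf)
    has = idx > 0
    tss[has] = t[has] - spike_times[idx[has] - 1]
    return tss


def estimate_capacitance(
    trace: Trace,
    v_window: Optional[tuple] = None,
    spikes: Optional[SpikeTrain] = None,
    exclusion: float = 200.0,
    cap_window_halfwidth: float = 1.0,
    min_samples: int = 500,
) -> float:
    """Capacitance (pF) by variance minimisation over a narrow voltage window.

    Restricts to samples whose voltage lies within ``v_window`` (default:
    median subthreshold voltage +/- ``cap_window_halfwidth``), excluding the
    ``exclusion`` ms after each spike, and returns the closed-form minimiser
    C* = Cov(I_in, dV/dt) / Var(dV/dt).
    """
    if trace.I is None or trace.V is None:
        raise ValueError("capacitance estimation needs both I and V channels")
    if trace.duration < 1000.0:
        raise ValueError("need at least 1 s of data")
    if spikes is None:
        spikes = detect_spikes(trace)
    n = len(trace)
    tss = _time_since_spike(n, trace.dt, spikes.times)
    eligible = (tss > exclusion) & _stencil_valid(trace)
    if v_window is None:
        sub = trace.V[eligible]
        if sub.size == 0:
            raise ExtractionError("capacitance: no subthreshold samples")
        med = float(np.median(sub))
        # widen progressively if the narrow default window is too sparse
        for h in (cap_window_halfwidth, 2 * cap_window_halfwidth, 4 * cap_window_halfwidth):
            v_window = (med - h, med + h)
            sel = eligible & (trace.V >= v_window[0]) & (trace.V <= v_window[1])
            if sel.sum() >= min_samples:
                break
    else:
        sel = eligible & (trace.V >= v_window[0]) & (trace.V <= v_window[1])
    if sel.sum() < min_samples:
        raise ExtractionError(
            f"capacitance: only {int(sel.sum())} eligible samples "
            f"(need {min_samples}) in window {v_window}"
        )
    dv = _dvdt(trace.V, trace.dt)[sel]
    if np.var(dv) == 0:
        raise ExtractionError("capacitance: dV/dt has zero variance")
    c = float(np.cov(trace.I[sel], dv)[0, 1] / np.var(dv, ddof=1))
    if c <= 0:
        raise ExtractionError(f"capacitance: non-physical estimate {c:.3g} pF")
    return c


def compute_ionic_current(trace: Trace, C: float) -> np.ndarray:
    """Ionic membrane current I_ion = I_in - C dV/dt, pA, per sample."""
    if trace.I is None or trace.V is None:
        raise ValueError("need both I and V channels")
    if C <= 0:
        raise ValueError("C must be positive")
    return trace.I - C * _dvdt(trace.V, trace.dt)


def _bin_current(
    V: np.ndarray, I_ion: np.ndarray, bin_width: float, min_count: int
) -> tuple:
    lo = np.floor(V.min() / bin_width) * bin_width
    edges = np.arange(lo, V.max() + bin_width, bin_width)
    idx = np.digitize(V, edges) - 1
    nb = len(edges) - 1
    counts = np.bincount(idx, minlength=nb)[:nb]
    sums = np.bincount(idx, weights=I_ion, minlength=nb)[:nb]
    sq = np.bincount(idx, weights=I_ion * I_ion, minlength=nb)[:nb]
    keep = counts >= max(min_count, 2)
    m = sums[keep] / counts[keep]
    var = sq[keep] / counts[keep] - m * m
    se = np.sqrt(np.maximum(var, 0.0) / counts[keep])
    centers = (edges[:-1] + 0.5 * bin_width)[keep]
    return centers, m, se, counts[keep]


def compute_dynamic_iv(
    trace: Trace,
    C: float,
    spikes: Optional[SpikeTrain] = None,
    bin_width: float = 1.0,
    exclusion: float = 200.0,
    min_count: int = 10,
) -> DynamicIV:
    """Voltage-binned mean ionic current, post-spike data excluded.

    Samples within ``exclusion`` ms after a spike peak (and clamped
    samples) are dropped; bins with fewer than ``min_count`` samples are
    discarded.
    """
    if spikes is None:
        spikes = detect_spikes(trace)
    I_ion = compute_ionic_current(trace, C)
    tss = _time_since_spike(len(trace), trace.dt, spikes.times)
    sel = (tss > exclusion) & _stencil_valid(trace)
    if not np.any(sel):
        raise ExtractionError("dynamic IV: no samples survive the exclusion")
    centers, m, se, counts = _bin_current(
        trace.V[sel], I_ion[sel], bin_width, min_count
    )
    if centers.size == 0:
        raise ExtractionError("dynamic IV: no voltage bin reaches min_count")
    return DynamicIV(
        bin_centers=centers, mean_current=m, se_current=se, counts=counts,
        exclusion_window=exclusion,
    )


def _eif_F(V, tau, E, V_T, Delta_T):
    arg = np.minimum((V - V_T) / Delta_T, EXP_ARG_CAP)
    return (E - V + Delta_T * np.exp(arg)) / tau


def _fit_region(centers: np.ndarray, F: np.ndarray, margin: float) -> np.ndarray:
    """Restrict to bins up to ``margin`` mV above the minimum of F.

    Beyond the spike-initiation upturn the EIF form no longer applies, so
    bins more than ``margin`` above the F-minimum voltage are dropped.
    """
    v_min = centers[int(np.argmin(F))]
    return centers <= v_min + margin


def fit_eif(
    iv: DynamicIV,
    C: float,
    fit_margin: float = 5.0,
    full_output: bool = False,
):
    """Weighted nonlinear least squares of the EIF forcing to a dynamic I-V.

    F(V) = -I_dyn(V)/C is fitted with weights 1/SE^2.  tau and E are
    initialised from a linear fit to the lowest-voltage half of the bins,
    V_T at the F-minimum bin and Delta_T at 1 mV; Delta_T is bounded in
    [0.05, 10] mV.  With ``full_output`` a ``(params, diagnostics)`` pair is
    returned; a fit hitting the Delta_T bound or failing to converge is
    flagged in the diagnostics.
    """
    centers = iv.bin_centers
    if centers.size < 6 or centers[-1] - centers[0] < 15.0:
        raise ExtractionError(
            "EIF fit: need >= 6 bins spanning >= 15 mV "
            f"(got {centers.size} bins over {centers[-1]-centers[0]:.1f} mV)"
        )
    F = -iv.mean_current / C
    seF = np.maximum(iv.se_current / C, 1e-12)
    keep = _fit_region(centers, F, fit_margin)
    Vb, Fb, sb = centers[keep], F[keep], seF[keep]

    half = max(len(Vb) // 2, 2)
    a, b = np.polyfit(Vb[:half], Fb[:half], 1)
    tau0 = -1.0 / a if a < 0 else 20.0
    E0 = -b / a if a < 0 else Vb[0]
    VT0 = float(Vb[int(np.argmin(Fb))])
    p0 = [np.clip(tau0, 1.0, 100.0), np.clip(E0, -110.0, -40.0), VT0, 1.0]
    bounds = ([0.5, -120.0, -90.0, 0.05], [200.0, -30.0, 0.0, 10.0])
    converged = True
    try:
        popt, _ = curve_fit(
            _eif_F, Vb, Fb, p0=p0, sigma=sb, bounds=bounds,
            xtol=1e-8, ftol=1e-8, maxfev=500 * 5,
        )
    except RuntimeError:
        converged = False
        popt = p0
    tau, E, V_T, Delta_T = (float(x) for x in popt)
    at_bound = Delta_T <= bounds[0][3] * 1.01 or Delta_T >= bounds[1][3] * 0.99
    params = EIFParams(C=C, tau=tau, E=E, V_T=V_T, Delta_T=Delta_T)
    if full_output:
        return params, {"converged": converged, "delta_t_at_bound": at_bound}
    return params


def _fit_slice(
    Vb: np.ndarray, Fb: np.ndarray, sb: np.ndarray, C: float, steady: EIFParams
) -> tuple:
    """Fit (g, E, V_T) with C and Delta_T frozen; returns (g, E, V_T, ok).

    When the empirical forcing shows no interior minimum (the
    spike-initiation upturn is not bracketed by the data) the threshold is
    unidentifiable: a weighted linear fit then supplies (g, E) and V_T is
    returned as NaN.
    """
    DT = steady.Delta_T

    if int(np.argmin(Fb)) >= len(Fb) - 2:
        # no upturn in range: F is effectively linear, F = (g/C) (E - V)
        w = 1.0 / sb**2
        (a, b), cov = np.polyfit(Vb, Fb, 1, w=np.sqrt(w), cov="unscaled")
        if a >= 0:
            return steady.g, steady.E, np.nan, False, None
        g = -a * C
        E = -b / a
        se_a, se_b = np.sqrt(np.diag(cov))
        se = {"g": float(se_a * C),
              "E": float(abs(E) * np.hypot(se_a / a, se_b / b)),
              "V_T": np.inf}
        return float(g), float(E), np.nan, True, se

    def model(V, g, E, V_T):
        arg = np.minimum((V - V_T) / DT, EXP_ARG_CAP)
        return (g / C) * (E - V + DT * np.exp(arg))

    best = None
    for dvt in (0.0, 8.0, 16.0):
        p0 = [steady.g, steady.E + min(dvt, 8.0), steady.V_T + dvt]
        try:
            popt, pcov = curve_fit(
                model, Vb, Fb, p0=p0, sigma=sb, absolute_sigma=True,
                bounds=([0.1, -120.0, -90.0], [1000.0, -20.0, 20.0]),
                xtol=1e-8, maxfev=2000,
            )
        except RuntimeError:
            continue
        ssr = float(np.sum(((model(Vb, *popt) - Fb) / sb) ** 2))
        if best is None or ssr < best[2]:
            best = (popt, pcov, ssr)
    if best is None:
        return steady.g, steady.E, steady.V_T, False, None
    g, E, V_T = best[0]
    perr = np.sqrt(np.maximum(np.diag(best[1]), 0.0))
    se = {"g": float(perr[0]), "E": float(perr[1]), "V_T": float(perr[2])}
    return float(g), float(E), float(V_T), True, se


def fit_post_spike_slices(
    trace: Trace,
    C: float,
    steady: EIFParams,
    spikes: Optional[SpikeTrain] = None,
    windows: Sequence[tuple] = DEFAULT_SLICE_WINDOWS,
    bin_width: float = 1.0,
    min_count: int = 5,
    min_slice_samples: int = 200,
    bootstrap: int = 0,
    seed: int = 0,
) -> list:
    """Spike-triggered EIF slice fits: (g, E, V_T) vs. time since the spike.

    For each window, samples at that time since the *last* spike are pooled
    across spikes, voltage-binned, and fitted with the EIF form holding C
    and Delta_T at their steady-state values (Delta_T shows no consistent
    post-spike trend).  Windows with fewer than ``min_slice_samples``
    eligible samples are skipped with a warning.  Optional per-parameter SEs
    by bootstrap resampling over spikes.
    """
    if spikes is None:
        spikes = detect_spikes(trace)
    if any(w[0] < T_REF for w in windows):
        raise ValueError(f"slice windows must start at or after t_ref = {T_REF} ms")
    I_ion = compute_ionic_current(trace, C)
    n = len(trace)
    tss = _time_since_spike(n, trace.dt, spikes.times)
    valid = _stencil_valid(trace)
    t = np.arange(n) * trace.dt
    spike_of_sample = np.searchsorted(spikes.times, t, side="right") - 1

    rng = np.random.default_rng(seed)
    out = []
    for w in sorted(windows):
        sel = (tss >= w[0]) & (tss < w[1]) & valid
        n_sel = int(sel.sum())
        if n_sel < min_slice_samples:
            warnings.warn(
                f"slice window {w}: only {n_sel} samples, skipped", stacklevel=2
            )
            continue
        Vb, m, se, counts = _bin_current(
            trace.V[sel], I_ion[sel], bin_width, min_count
        )
        if Vb.size < 4:
            warnings.warn(f"slice window {w}: too few voltage bins, skipped", stacklevel=2)
            continue
        Fb = -m / C
        sb = np.maximum(se / C, 1e-12)
        keep = _fit_region(Vb, Fb, 5.0)
        g, E, V_T, ok, se_out = _fit_slice(Vb[keep], Fb[keep], sb[keep], C, steady)
        slice_bins = (Vb[keep], Fb[keep], sb[keep])
        if bootstrap > 0 and ok:
            owner = spike_of_sample[sel]
            V_sel, I_sel = trace.V[sel], I_ion[sel]
            uniq = np.unique(owner)
            by_spike = {u: np.nonzero(owner == u)[0] for u in uniq}
            reps = {"g": [], "E": [], "V_T": []}
            for _ in range(bootstrap):
                pick = rng.choice(uniq, size=uniq.size, replace=True)
                idx = np.concatenate([by_spike[u] for u in pick])
                Vr, mr, ser, _ = _bin_current(V_sel[idx], I_sel[idx], bin_width, min_count)
                if Vr.size < 4:
                    continue
                Fr, sr = -mr / C, np.maximum(ser / C, 1e-12)
                kr = _fit_region(Vr, Fr, 5.0)
                gg, ee, vv, okr, _ = _fit_slice(Vr[kr], Fr[kr], sr[kr], C, steady)
                if okr:
                    reps["g"].append(gg)
                    reps["E"].append(ee)
                    reps["V_T"].append(vv)
            if len(reps["g"]) > 1:
                se_out = {k: float(np.std(v, ddof=1)) for k, v in reps.items()}
        out.append(SliceFit(window=tuple(w), g=g, E=E, V_T=V_T,
                            n_points=n_sel, converged=ok, se=se_out,
                            bins=slice_bins))
    return out


def _exp_fit(windows, y, y0, sigma=None, bounds_tau=(1.0, 500.0), bound_amp=500.0):
    """Fit window-averaged exponential relaxation toward ``y0``.

    Each ``y[i]`` is treated as the average of ``y0 + a*exp(-x/tau)`` over
    post-refractory time ``x`` in window i (a slice value estimates the
    window-mean of the underlying parameter, which matters for decays fast
    compared to the window width); ``sigma`` weights points by their slice
    SEs when available.  Multistart over tau; the jump amplitude is bounded
    to +/-``bound_amp`` because a decay much faster than the first window
    is unidentifiable and would otherwise blow up the back-extrapolated
    jump.  Returns (a, tau, ok).
    """
    a_lo = np.array([w[0] for w in windows]) - T_REF
    b_hi = np.array([w[1] for w in windows]) - T_REF
    width = b_hi - a_lo
    if sigma is not None:
        sigma = np.asarray(sigma, dtype=float)
        if not np.all(np.isfinite(sigma)) or np.any(sigma <= 0):
            sigma = None

    def model(_x, a, tau):
        return y0 + a * tau / width * (np.exp(-a_lo / tau) - np.exp(-b_hi / tau))

    a0 = np.clip(y[0] - y0, -bound_amp / 2, bound_amp / 2)
    best = None
    for tau0 in (5.0, 20.0, 80.0):
        p0a = float(np.clip(a0 * np.exp(a_lo[0] / tau0), -bound_amp, bound_amp))
        try:
            popt, _ = curve_fit(
                model, a_lo, y, p0=[p0a, tau0], sigma=sigma,
                bounds=([-bound_amp, bounds_tau[0]], [bound_amp, bounds_tau[1]]),
                maxfev=5000,
            )
        except RuntimeError:
            continue
        resid = (model(a_lo, *popt) - y) / (sigma if sigma is not None else 1.0)
        ssr = float(np.sum(resid**2))
        if best is None or ssr < best[1]:
            best = (popt, ssr)
    if best is None:
        return float(a0), 20.0, False
    return float(best[0][0]), float(best[0][1]), True


def _refine_threshold_timecourse(
    usable: Sequence[SliceFit],
    steady: EIFParams,
    V_T1: float,
    tau_T: float,
    ok: bool,
) -> tuple[float, float, bool]:
    """Joint refit of (V_T1, tau_T) against the pooled slice forcing bins.

    The per-slice threshold estimate is weakly identified whenever the
    spike-initiation upturn is barely (or not at all) reached by the data.
    Pooling the binned forcing of *all* slices and fitting the exponential
    threshold timecourse directly, with each slice's (g, E) frozen at its
    fitted value, uses the information the per-slice route discards: a
    slice whose data show no upturn still constrains the threshold from
    below.  Falls back to the per-slice result if the joint fit fails.
    """
    xs, Vs, Fs, ss, gs, Es = [], [], [], [], [], []
    for s in usable:
        if s.bins is None or not np.isfinite(s.g) or not np.isfinite(s.E):
            continue
        Vb, Fb, sb = s.bins
        xm = 0.5 * (s.window[0] + s.window[1]) - T_REF
        xs.append(np.full(len(Vb), xm))
        Vs.append(Vb)
        Fs.append(Fb)
        ss.append(sb)
        gs.append(np.full(len(Vb), s.g))
        Es.append(np.full(len(Vb), s.E))
    if not xs:
        return V_T1, tau_T, ok
    x = np.concatenate(xs)
    V = np.concatenate(Vs)
    F = np.concatenate(Fs)
    sig = np.concatenate(ss)
    g = np.concatenate(gs)
    E = np.concatenate(Es)
    C, DT = steady.C, steady.Delta_T

    def model(_v, a, tau):
        vt = steady.V_T + a * np.exp(-x / tau)
        arg = np.minimum((V - vt) / DT, EXP_ARG_CAP)
        return (g / C) * (E - V + DT * np.exp(arg))

    p0 = [float(np.clip(V_T1, -99.0, 99.0)), float(np.clip(tau_T, 1.5, 450.0))]
    try:
        popt, _ = curve_fit(
            model, V, F, p0=p0, sigma=sig,
            bounds=([-100.0, 1.0], [100.0, 500.0]), maxfev=5000,
        )
        return float(popt[0]), float(popt[1]), True
    except RuntimeError:
        return V_T1, tau_T, ok


def fit_refractory_dynamics(
    slices: Sequence[SliceFit],
    steady: EIFParams,
    sag_threshold: float = 0.5,
) -> tuple[RefractoryDynamics, dict]:
    """Exponential fits of the slice parameters vs. post-spike time.

    Slice values are placed at their window midpoints.  g and V_T get
    mono-exponential fits (jump + decay toward the steady-state value); E is
    fitted both mono- and bi-exponentially and the bi-exponential is kept
    iff its implied sag depth exceeds ``sag_threshold`` (0.5 mV).  Decay
    constants are bounded in [1, 500] ms.  Returns the dynamics and a
    diagnostics dict (convergence flags, both E fits' SSR).
    """
    from .core_model import PostSpikeSummary, summarize_E_dynamics  # noqa: F401

    usable = [s for s in slices if s.converged]
    if len(usable) < 5:
        raise ExtractionError(
            f"refractory fit: only {len(usable)} usable slices (need >= 5)"
        )
    wins = [s.window for s in usable]
    gv = np.array([s.g for s in usable])
    ev = np.array([s.E for s in usable])
    vtv = np.array([s.V_T for s in usable])

    def _se(key):
        out = np.array(
            [s.se[key] if s.se and np.isfinite(s.se.get(key, np.nan)) else np.nan
             for s in usable]
        )
        if np.any(~np.isfinite(out)):
            return None
        return np.maximum(out, 1e-6)

    g1, tau_g, ok_g = _exp_fit(wins, gv, steady.g, sigma=_se("g"))
    # threshold: only slices where the upturn was bracketed carry V_T info
    vt_ok = np.isfinite(vtv)
    if vt_ok.sum() >= 3:
        se_vt = np.array(
            [s.se["V_T"] if s.se else np.nan for s, ok in zip(usable, vt_ok) if ok]
        )
        V_T1, tau_T, ok_t = _exp_fit(
            [w for w, ok in zip(wins, vt_ok) if ok], vtv[vt_ok], steady.V_T,
            sigma=se_vt if np.all(np.isfinite(se_vt)) else None,
            bound_amp=100.0,
        )
    else:
        V_T1, tau_T, ok_t = 0.0, 20.0, False
    V_T1, tau_T, ok_t = _refine_threshold_timecourse(
        usable, steady, V_T1, tau_T, ok_t
    )

    # E: mono fit
    se_e = _se("E")
    em, tau_em, ok_em = _exp_fit(wins, ev, steady.E, sigma=se_e, bound_amp=100.0)
    a_lo = np.array([w[0] for w in wins]) - T_REF
    b_hi = np.array([w[1] for w in wins]) - T_REF
    width = b_hi - a_lo

    def _avg_exp(tau):
        return tau / width * (np.exp(-a_lo / tau) - np.exp(-b_hi / tau))

    wgt = se_e if se_e is not None else np.ones_like(ev)
    ssr_mono = float(np.sum(((steady.E + em * _avg_exp(tau_em) - ev) / wgt) ** 2))

    # E: window-averaged bi-exponential fit, multistart over decay pairs.
    # Parameterised by (jump J = E2 - E1 >= 0, E1, tau1, tau2) so the fit
    # cannot wander into negative-jump solutions with no baseline crossing.
    def bi(_x, J, E1, t1, t2):
        return steady.E - E1 * _avg_exp(t1) + (J + E1) * _avg_exp(t2)

    best = None
    jump0 = max(ev[0] - steady.E, 1.0)
    for t1 in (30.0, 60.0, 120.0):
        for t2 in (5.0, 15.0, 30.0):
            try:
                popt, _ = curve_fit(
                    bi, a_lo, ev, p0=[jump0, 2.0, t1, t2], sigma=se_e,
                    bounds=([0.0, 0.0, 1.0, 1.0], [100.0, 100.0, 500.0, 500.0]),
                    maxfev=5000,
                )
            except RuntimeError:
                continue
            ssr = float(np.sum(((bi(a_lo, *popt) - ev) / wgt) ** 2))
            if best is None or ssr < best[1]:
                best = (popt, ssr)

    use_bi = False
    bi_summary = None
    if best is not None:
        J, E1, tE1, tE2 = (float(v) for v in best[0])
        E2 = J + E1
        try:
            trial = RefractoryDynamics(
                g1=g1, tau_g=tau_g, V_T1=V_T1, tau_T=tau_T,
                E_mode="bi", E1=E1, E2=E2, tau_E1=tE1, tau_E2=tE2,
            )
            probe = rEIFParams(eif=steady, refractory=trial)
            bi_summary = summarize_E_dynamics(probe)
            use_bi = bi_summary.E_sag is not None and bi_summary.E_sag > sag_threshold
        except ValueError:
            use_bi = False

    if use_bi:
        refr = trial
    else:
        refr = RefractoryDynamics(
            g1=g1, tau_g=tau_g, V_T1=V_T1, tau_T=tau_T,
            E_mode="mono", E_mono=em, tau_mono=tau_em,
        )
    diag = {
        "converged": ok_g and ok_t and (ok_em or best is not None),
        "negative_jumps": bool(g1 < 0 or V_T1 < 0),
        "ssr_mono": ssr_mono,
        "ssr_bi": best[1] if best is not None else None,
        "bi_sag": None if bi_summary is None else bi_summary.E_sag,
    }
    return refr, diag


def extract_cell(trace: Trace, config: Optional[ExtractionConfig] = None) -> ExtractionResult:
    """Run the full dynamic I-V pipeline on one recording.

    Stages: spike detection, capacitance, dynamic I-V, EIF fit, post-spike
    slice fits, refractory-dynamics fits.  Deterministic given the trace and
    config (the bootstrap, when enabled, is seeded from the config).  A
    trace without spikes yields steady-state parameters only, with
    ``params=None`` and a diagnostic flag.
    """
    cfg = config or ExtractionConfig()
    diagnostics: dict = {}
    try:
        spikes = detect_spikes(trace, threshold=cfg.spike_threshold)
    except Exception as exc:  # pragma: no cover - defensive
        raise ExtractionError(f"spike detection: {exc}") from exc

    try:
        C = estimate_capacitance(
            trace, spikes=spikes, exclusion=cfg.exclusion,
            cap_window_halfwidth=cfg.cap_window_halfwidth,
            min_samples=cfg.min_cap_samples,
        )
    except ExtractionError:
        raise
    except Exception as exc:
        raise ExtractionError(f"capacitance: {exc}") from exc

    try:
        iv = compute_dynamic_iv(
            trace, C, spikes=spikes, bin_width=cfg.bin_width,
            exclusion=cfg.exclusion, min_count=cfg.min_count,
        )
        eif, fit_diag = fit_eif(iv, C, fit_margin=cfg.fit_margin, full_output=True)
        diagnostics["eif_fit"] = fit_diag
    except ExtractionError:
        raise
    except Exception as exc:
        raise ExtractionError(f"EIF fit: {exc}") from exc

    params = None
    slices: list = []
    if len(spikes) == 0:
        diagnostics["refractory"] = "no spikes: post-spike dynamics unavailable"
    else:
        try:
            slices = fit_post_spike_slices(
                trace, C, eif, spikes=spikes, windows=cfg.slice_windows,
                bin_width=cfg.bin_width, min_slice_samples=cfg.min_slice_samples,
                bootstrap=cfg.bootstrap, seed=cfg.seed,
            )
            refr, rdiag = fit_refractory_dynamics(slices, eif)
            diagnostics["refractory"] = rdiag
            params = rEIFParams(eif=eif, refractory=refr)
        except ExtractionError as exc:
            diagnostics["refractory"] = f"failed: {exc}"

    return ExtractionResult(
        C=C, eif=eif, params=params, dynamic_iv=iv, slices=slices,
        spikes=spikes, diagnostics=diagnostics,
    )
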