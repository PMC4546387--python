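"""Step-protocol measurements, spike detection/shape, and fit-quality metrics.

Step protocol: the input resistance R_in is the least-squares slope of the
steady step voltage (mean over the last 200 ms of each 1 s step) against
step amplitude, over subthreshold steps; the sag percentage is

    S = 100 * (V_min - V_st) / (V_st - V_rest)

on the most hyperpolarising step, with V_min the in-step minimum, V_st the
steady voltage and V_rest the pre-step baseline.

Spike-train agreement uses the coincidence factor

    Gamma = (N_coinc - 2*f*Delta*N1) / (0.5*(N1+N2)) / (1 - 2*f*Delta),

where N1, N2 are the spike counts of the reference and comparison trains,
N_coinc the number of one-to-one coincidences within precision Delta
(default 5 ms), f the rate of the *reference* train (this normalisation
follows the convention where the chance term is computed from the reference
rate; some literature variants use the comparison train), and 1 - 2*f*Delta
normalises so Gamma = 1 for an identical train and Gamma ~ 0 for an
independent Poisson train.

Subthreshold agreement is the RMS voltage deviation excluding windows 2 ms
before to 4 ms after each spike peak (of either train).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .simulator import SpikeTrain, Trace

__all__ = [
    "StepProtocolResult",
    "SpikeShape",
    "GammaResult",
    "analyze_steps",
    "detect_spikes",
    "measure_spike_shape",
    "gamma_coincidence",
    "subthreshold_rmsd",
    "reliability_screen",
    "RELIABILITY_THRESHOLD",
]

#: minimum acceptable repeat-trial coincidence factor; below it a cell is
#: considered intrinsically unreliable and discarded.
RELIABILITY_THRESHOLD = 0.75


@dataclass(frozen=True)
class StepProtocolResult:
    """Quantities measured from the square-pulse protocol."""

    R_in: float  # MOhm
    G_in: float  # nS
    sag_percent: Optional[float]
    step_voltages: np.ndarray  # steady voltage per step, mV (NaN where excluded)
    V_rest: float
    excluded_steps: tuple = ()


@dataclass(frozen=True)
class SpikeShape:
    """Average action-potential shape over isolated spikes."""

    A_amp: float  # mV, peak minus initiation threshold
    A_dur: float  # ms, width at half amplitude
    A_rise: float  # mV/ms, maximal rate of rise between threshold and peak
    n_isolated_spikes: int


@dataclass(frozen=True)
class GammaResult:
    """Coincidence-factor decomposition."""

    gamma: float
    N1: int
    N2: int
    N_coinc: int
    f: float  # reference-train rate, Hz
    delta: float  # precision, ms
    expected_coinc: float
    normalizer: float
    flagged: bool = False


def detect_spikes(
    trace: Trace, threshold: float = 0.0, refractory_min: float = 2.0
) -> SpikeTrain:
    """Detect spikes as upward threshold crossings, timed at the local peak.

    Crossings closer than ``refractory_min`` to the previous accepted spike
    are ignored (merges doublets produced by noise around threshold).
    """
    if trace.V is None:
        raise ValueError("trace must carry a V channel")
    V = trace.V
    dt = trace.dt
    above = V >= threshold
    crossings = np.nonzero(~above[:-1] & above[1:])[0] + 1
    times = []
    last = -np.inf
    n_min = max(int(round(refractory_min / dt)), 1)
    for k in crossings:
        if k * dt - last < refractory_min:
            continue
        # local peak: first sample after which V stops rising, bounded by
        # the point where V falls back below threshold
        j = k
        while j + 1 < len(V) and V[j + 1] >= V[j]:
            j += 1
        times.append(j * dt)
        last = j * dt
    return SpikeTrain(times=np.array(times), duration=len(V) * dt)


def analyze_steps(
    traces: Sequence[Trace],
    amplitudes: Sequence[float],
    step_start: float,
    step_duration: float = 1000.0,
    steady_window: float = 200.0,
    baseline_window: float = 200.0,
) -> StepProtocolResult:
    """Input resistance, conductance and sag percentage from step responses.

    Each trace holds the voltage response to one step of the paired
    amplitude (pA), with the step spanning
    ``[step_start, step_start + step_duration)`` ms.  Steps containing
    spikes are excluded from the R_in regression (with a record in
    ``excluded_steps``).  The sag is measured on the most hyperpolarising
    step.
    """
    if len(traces) != len(amplitudes):
        raise ValueError("need one trace per amplitude")
    if len(traces) < 2:
        raise ValueError("need at least two step amplitudes")
    amps = np.asarray(amplitudes, dtype=float)

    v_st = np.full(len(traces), np.nan)
    v_rest = np.full(len(traces), np.nan)
    v_min = np.full(len(traces), np.nan)
    excluded = []
    for i, tr in enumerate(traces):
        if tr.V is None:
            raise ValueError("step traces must carry a V channel")
        dt = tr.dt
        i0 = int(round(step_start / dt))
        i1 = int(round((step_start + step_duration) / dt))
        ib = int(round(max(step_start - baseline_window, 0.0) / dt))
        iw = int(round((step_start + step_duration - steady_window) / dt))
        seg = tr.V[i0:i1]
        spikes = detect_spikes(Trace(dt=dt, V=seg))
        if len(spikes):
            excluded.append(i)
            continue
        v_rest[i] = tr.V[ib:i0].mean()
        v_st[i] = tr.V[iw:i1].mean()
        v_min[i] = seg.min()

    ok = ~np.isnan(v_st)
    if ok.sum() < 2:
        raise ValueError("fewer than two spike-free steps; cannot fit R_in")
    # slope of V_st (mV) vs amplitude (pA) is in GOhm; convert to MOhm
    slope = np.polyfit(amps[ok], v_st[ok], 1)[0]
    r_in = slope * 1000.0
    if r_in <= 0:
        raise ValueError(f"non-positive fitted input resistance ({r_in:.3g} MOhm)")
    g_in = 1000.0 / r_in

    sag = None
    hyp = [i for i in np.nonzero(ok)[0] if amps[i] < 0]
    if hyp:
        i = min(hyp, key=lambda j: amps[j])
        denom = v_st[i] - v_rest[i]
        if abs(denom) > 1e-12:
            sag = 100.0 * (v_min[i] - v_st[i]) / denom
    return StepProtocolResult(
        R_in=float(r_in),
        G_in=float(g_in),
        sag_percent=None if sag is None else float(sag),
        step_voltages=v_st,
        V_rest=float(np.nanmean(v_rest)),
        excluded_steps=tuple(excluded),
    )


def measure_spike_shape(
    trace: Trace,
    spikes: SpikeTrain,
    min_isi: float = 200.0,
    threshold_window: float = 3.0,
) -> SpikeShape:
    """Average amplitude, half-width and maximal rise of isolated spikes.

    A spike is isolated if the preceding inter-spike interval exceeds
    ``min_isi`` (the first spike qualifies if it occurs later than
    ``min_isi`` after the recording start).  The initiation threshold is the
    voltage at the peak of the second time-derivative in the
    ``threshold_window`` ms before the peak; amplitude is peak minus
    threshold; duration the width at half amplitude above threshold
    (linear-interpolated crossings); rise the maximal first derivative
    between threshold time and peak.
    """
    if trace.V is None:
        raise ValueError("trace must carry a V channel")
    V = trace.V
    dt = trace.dt
    t_spk = spikes.times
    isis = np.diff(t_spk, prepend=0.0)
    isolated = t_spk[isis > min_isi]
    if isolated.size == 0:
        raise ValueError("no isolated spikes (preceding ISI must exceed min_isi)")

    amps, durs, rises = [], [], []
    nw = int(round(threshold_window / dt))
    for ts in isolated:
        pk = int(round(ts / dt))
        lo = max(pk - nw, 1)
        if pk + 1 >= len(V) or pk - lo < 3:
            continue
        seg = V[lo - 1 : pk + 2]
        d2 = (seg[2:] - 2 * seg[1:-1] + seg[:-2]) / dt**2
        k_thr = lo + int(np.argmax(d2))
        v_thr = V[k_thr]
        amp = V[pk] - v_thr
        if amp <= 0:
            continue
        half = v_thr + amp / 2.0
        # rising crossing of the half level
        i = pk
        while i > 0 and V[i - 1] > half:
            i -= 1
        tl = (i - 1 + (half - V[i - 1]) / (V[i] - V[i - 1])) * dt if i > 0 else i * dt
        # falling crossing
        j = pk
        while j + 1 < len(V) and V[j + 1] > half:
            j += 1
        tr_ = (j + (V[j] - half) / (V[j] - V[j + 1])) * dt if j + 1 < len(V) else j * dt
        durs.append(tr_ - tl)
        dv = np.diff(V[k_thr : pk + 1]) / dt
        rises.append(dv.max() if dv.size else np.nan)
        amps.append(amp)
    if not amps:
        raise ValueError("no measurable isolated spikes")
    return SpikeShape(
        A_amp=float(np.mean(amps)),
        A_dur=float(np.mean(durs)),
        A_rise=float(np.nanmean(rises)),
        n_isolated_spikes=len(amps),
    )


def _greedy_coincidences(ref: np.ndarray, cmp: np.ndarray, delta: float) -> int:
    """One-to-one coincidence count by greedy matching in time order."""
    i = j = n = 0
    while i < len(ref) and j < len(cmp):
        if abs(ref[i] - cmp[j]) <= delta:
            n += 1
            i += 1
            j += 1
        elif ref[i] < cmp[j]:
            i += 1
        else:
            j += 1
    return n


def gamma_coincidence(ref: SpikeTrain, cmp: SpikeTrain, delta: float = 5.0) -> GammaResult:
    """Chance-corrected coincidence factor between two spike trains.

    Coincidences are counted by greedy one-to-one matching in time order
    (each spike used at most once; a pair is accepted iff their times differ
    by at most ``delta``), which attains the maximum possible matching for
    sorted trains.  The chance term 2*f*delta*N1 uses the reference-train
    rate.  An empty train yields a defined, flagged result with Gamma <= 0.
    """
    n1, n2 = len(ref.times), len(cmp.times)
    duration = ref.duration
    f_per_ms = n1 / duration
    norm = 1.0 - 2.0 * f_per_ms * delta
    if norm <= 0:
        raise ValueError(
            f"reference rate {1000*f_per_ms:.1f} Hz too high for delta={delta} ms "
            "(normaliser must be positive)"
        )
    n_coinc = _greedy_coincidences(ref.times, cmp.times, delta)
    q = 2.0 * f_per_ms * delta
    expected = q * n1
    flagged = n1 == 0 or n2 == 0
    if n1 + n2 == 0:
        gamma = 0.0
    else:
        # numerator and denominator share the q*count form so that an
        # identical comparison train yields exactly 1.0
        half = 0.5 * (n1 + n2)
        gamma = (n_coinc - q * n1) / (half - q * half)
    return GammaResult(
        gamma=float(gamma),
        N1=n1,
        N2=n2,
        N_coinc=n_coinc,
        f=1000.0 * f_per_ms,
        delta=delta,
        expected_coinc=expected,
        normalizer=norm,
        flagged=flagged,
    )


def _exclusion_mask(
    n: int, dt: float, spike_times: np.ndarray, pre: float, post: float
) -> np.ndarray:
    """Boolean mask of samples inside any [t-pre, t+post] spike window."""
    mask = np.zeros(n + 1, dtype=float)
    lo = np.clip(np.ceil((spike_times - pre) / dt).astype(int), 0, n)
    hi = np.clip(np.floor((spike_times + post) / dt).astype(int) + 1, 0, n)
    np.add.at(mask, lo, 1.0)
    np.add.at(mask, hi, -1.0)
    return np.cumsum(mask[:-1]) > 0


def subthreshold_rmsd(
    v_ref: Trace,
    v_cmp: Trace,
    spikes: SpikeTrain | np.ndarray,
    pre: float = 2.0,
    post: float = 4.0,
) -> float:
    """RMS voltage deviation outside peri-spike windows.

    ``spikes`` should contain the union of both trains' spike times; samples
    within ``pre`` ms before to ``post`` ms after any spike are excluded.
    """
    if v_ref.V is None or v_cmp.V is None:
        raise ValueError("both traces must carry V channels")
    if len(v_ref) != len(v_cmp) or abs(v_ref.dt - v_cmp.dt) > 1e-12:
        raise ValueError("traces must share length and dt")
    times = spikes.times if isinstance(spikes, SpikeTrain) else np.asarray(spikes, float)
    excl = _exclusion_mask(len(v_ref), v_ref.dt, times, pre, post)
    keep = ~excl
    if not np.any(keep):
        raise ValueError("no samples left outside the spike exclusion windows")
    d = v_ref.V[keep] - v_cmp.V[keep]
    return float(np.sqrt(np.mean(d * d)))


def reliability_screen(gamma_rep: float) -> bool:
    """Keep a cell iff its repeat-trial coincidence factor is >= 0.75.

    The boundary is inclusive: a cell at exactly the threshold is kept.
    """
    return gamma_rep >= RELIABILITY_THRESHOLD
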