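# Methods

This note records the model, the extraction and generation procedures, the
numerical choices, and the limits of what the synthetic validation shows.
Units throughout: mV, ms, pA, pF, nS, MΩ (a consistent system: `I/C` with
I in pA and C in pF is directly mV/ms, and `g = C/τ` is in nS).

## The rEIF model and its simulation

The subthreshold dynamics are `dV/dt = F(V,t) + I_in/C` with the EIF
forcing `F = (g(t)/C)(E(t) − V + Δ_T exp((V − V_T(t))/Δ_T))`. The argument
of the spike-initiation exponential is capped at 40; any voltage past that
cap is deep inside the spike upswing, so the cap changes no subthreshold
behaviour while keeping every float finite.

Integration is forward Euler at `dt = 0.05 ms`, matching a 20 kHz
acquisition rate. A spike is the first sample at which `V ≥ 30 mV`; that
crossing sample is the canonical event time. The action-potential
downswing is not modelled: integration halts for `t_ref = 4 ms`, the
recorded voltage in the halt is a cosmetic linear ramp to the reset value
and those samples are flagged (`refractory_mask`) and excluded from every
analysis. Integration resumes at the reset voltage with the post-spike
parameters at their jump values. Post-spike dynamics are non-cumulative
(renewal): a new spike restarts the post-spike clock. Beyond 200 ms after
a spike the parameters are exactly steady-state, consistent with the
200 ms post-spike exclusion used during extraction. Input traces with a
different `dt` are linearly resampled with a note in the output metadata.

**Reset voltage.** Experimentally the reset is the voltage measured 4 ms
after the spike peak, a data-dependent quantity with no tabulated
population statistics. When a parameter set does not carry an explicit
`V_reset`, the package defaults it to the steady-state threshold `V_T0`
(the measured reset is typically just above it). This default is a
documented stand-in, not a measured value.

**E-dynamics summary and inversion.** The post-spike resting potential is
summarised by jump, baseline-crossing time `t_0`, sag time `t_sag` and sag
depth `E_sag` (sag criterion: `E_sag > 0.5 mV`). Crossing and stationarity
are located by bracketing on a log-spaced grid over (0, 2000] ms with
Brent refinement to 1e-6 ms. The inverse problem — bi-exponential
amplitudes and time constants from a summary — reduces analytically to one
scalar equation in the rate difference `d = 1/τ_E2 − 1/τ_E1`: with
`Δt = t_sag − t_0`, `r1(d) = d/(exp(dΔt) − 1)` and
`E1(d) = E_sag·exp(r1·t_sag)/(1 − exp(−dΔt))`, the jump condition
`E1(d)(exp(d·t_0) − 1) = E_jump` is solved by bracketing and Brent.
Summaries for which this equation has no root admit *no* bi-exponential
realisation (verified against a dense two-dimensional grid search during
development); the generator treats them as infeasible and redraws. A
shallow undershoot (`0 < E_sag ≤ 0.5 mV`) keeps its measured values but is
classified as no-sag.

## Stimulation

Naturalistic currents are two summed Ornstein–Uhlenbeck processes
(`τ_fast = 3 ms`, `τ_slow = 10 ms`), with a low (`σ = 0.18/0.18`) and a
high (`σ_fast = 0.36, σ_slow = 0.25`) fluctuation preset, DC offsets 0.5
or 1, and a multiplicative gain in pA. Each OU component uses the exact
stationary update `x ← x·e^(−dt/τ) + σ·sqrt(1 − e^(−2dt/τ))·ξ`, so the
process statistics are independent of the step size. The experimental
practice of scaling the gain until the cell fires at 5–15 Hz is available
as `calibrate_gain`, a bisection against short simulations; it targets the
geometric midpoint of the band and stops once inside it.

## Extraction (dynamic I-V)

1. **Capacitance**: `C* = Cov(I_in, dV/dt)/Var(dV/dt)` over samples whose
   voltage lies within ±1 mV of the median subthreshold voltage, excluding
   the 200 ms after each spike. The voltage window half-width is a package
   choice (the method itself does not fix one) and widens automatically
   (×2, ×4) when fewer than 500 samples qualify, as happens for
   fast-firing cells. `dV/dt` is a central difference at the acquisition
   rate with no smoothing — white measurement noise is symmetric and
   cancels from the variance minimiser. Samples whose difference stencil
   touches a refractory-clamped sample are excluded everywhere.
2. **Dynamic I-V**: mean, SE and count of `I_ion` in 1 mV voltage bins;
   bins with fewer than 10 samples are dropped.
3. **EIF fit**: weighted (1/SE²) least squares of `F(V) = −I_dyn/C`.
   Initialisation: τ and E from a linear fit to the lower half of the
   bins, `V_T` at the F-minimum bin, `Δ_T = 1 mV`. `Δ_T` is bounded in
   [0.05, 10] mV; a fit pinned at the bound or failing to converge is
   flagged. The fit uses only bins up to 5 mV above the F-minimum voltage:
   beyond the spike-initiation upturn the EIF form no longer applies.
4. **Slice fits**: samples are grouped by time since the last spike and
   refitted with `C` and `Δ_T` frozen (the sharpness shows no consistent
   post-spike trend), free `(g, E, V_T)`. The default windows are
   sub-millisecond early — (5, 5.5), (5.5, 6), … — widening geometrically
   to (140, 200) ms. Narrow early windows matter: just after the reset the
   voltage is slaved to the rapidly relaxing E(t), so within a wide window
   the voltage correlates with time-in-window and the regression slope
   (the conductance) is attenuated. Per-slice parameter SEs come from the
   weighted-fit covariance; an optional bootstrap over whole spikes
   (seeded, 100 replicates, off by default) can replace them. When a
   slice's voltage samples never reach the spike-initiation upturn (the
   F-minimum falls at the top of the data range) the threshold is
   unidentifiable there: the slice falls back to a weighted linear fit for
   `(g, E)` and reports `V_T = NaN`.
5. **Refractory fits**: exponential relaxations are fitted to the slice
   values, with each slice value treated as the *window average* of the
   relaxation (not its midpoint value — for decays comparable to the
   window width the distinction is significant), weighted by the slice
   SEs. Decay constants are bounded in [1, 500] ms and jump amplitudes to
   a physical range, because a decay much faster than the first window is
   unidentifiable and would otherwise blow up the back-extrapolated jump;
   negative fitted jumps are allowed but flagged. The threshold timecourse
   is then refined by a joint fit of `(V_T1, τ_T)` against the pooled
   binned forcing of all slices with each slice's `(g, E)` frozen — this
   uses the information the per-slice route discards, since a slice with
   no visible upturn still bounds the threshold from below. For E, both a
   mono-exponential and a jump-constrained bi-exponential
   (`E_jump = E2 − E1 ≥ 0`, multistart over decay pairs) are fitted; the
   bi form is selected iff its implied sag depth exceeds 0.5 mV.

## Step protocol and spike shape

`R_in` is the least-squares slope of the steady step voltage (mean of the
last 200 ms of each 1 s step) against amplitude over spike-free steps
(MΩ = 1000 × mV/pA); `G_in = 1000/R_in` nS. The sag percentage is
`100·(V_min − V_st)/(V_st − V_rest)` on the most hyperpolarising step.
Spike shape is measured on isolated spikes (preceding ISI > 200 ms):
initiation threshold at the peak second derivative in the 3 ms before the
peak (double central differencing on the raw 20 kHz trace; the 3 ms search
window is a package choice), amplitude peak-minus-threshold, duration the
interpolated width at half amplitude, rise the maximal first derivative
between threshold and peak.

## Performance metrics

Γ counts one-to-one coincidences within `Δ = 5 ms` by greedy matching in
time order, which attains the maximum matching on sorted trains (checked
against exhaustive search). The chance term `2fΔN_1` uses the
reference-train rate, and the numerator and normaliser share the same
floating-point form so `Γ(ref, ref) = 1.0` exactly. For independent
Poisson trains the one-to-one convention biases Γ down by O((2fΔ)²) —
about −0.01 at 10 Hz — which is a property of the counting convention, not
an implementation artefact. The reliability screen keeps cells with
repeat-trial `Γ_rep ≥ 0.75`, boundary inclusive. Subthreshold RMSD
excludes 2 ms before to 4 ms after every spike of both trains.

## Population generation

Built-in class statistics (marginal means and SDs, transformed-space
covariances, Spearman correlations, sag fractions, and the
class-independent mono-exponential fallback for no-sag cells) live in a
static JSON resource. Log-normal marginals are specified by natural-scale
`(μ, σ)` and converted by exact moment matching
(`s² = ln(1 + (σ/μ)²)`, `m = ln μ − s²/2`). For the five EIF parameters
the transformed-space covariance matrix is used verbatim; its diagonal is
mildly inconsistent with the marginal-table-implied log variances (data
rounded to two significant figures from the same recordings), and the
covariance matrix wins, shifting e.g. the TL5 mean capacitance by ~0.1 %.
The recorded Spearman correlations are used only for validation: a
Gaussian copula cannot match a printed covariance and a printed Spearman
simultaneously.

Sampling is multivariate normal (Cholesky) in transformed space with
exponentiation of the log members; draws violating `V_T > E` are rejected
and redrawn (rejection rates are far below 1 % for all built-in classes
since the mean rest-to-threshold distance is ~4 SDs of its spread). The
post-spike block is drawn independently of the EIF block and
component-wise independently — no empirical covariance for it is published
in table form — and a covariance can be supplied through the spec to
override this default. Each cell's E dynamics are bi-exponential with the
class's sag probability: the summary quadruple `(E_jump, E_sag, t_sag,
t_0)` is drawn from its log-normals and inverted, redrawing on
infeasibility (capped at 100 attempts).

**A consequence worth knowing.** Conditioning on feasibility changes the
conditional moments of the summary parameters: infeasible draws are
disproportionately those with small jumps relative to their sag, so among
accepted sag cells the mean `E_jump` sits above the unconditional marginal
mean (about +0.5 mV for L2/3, where ~15 % of raw draws are infeasible;
more for TL5, where it is ~37 %). This is an unavoidable property of
sampling the summary parameters independently and rejecting infeasible
combinations; matching the marginal mean exactly would require a joint
(correlated) model of the four summary parameters, which no published
table supports. The acceptance suite asserts the unconditional mean and
therefore flags this known bias rather than hiding it.

## What the synthetic validation does and does not show

The virtual rig drives rEIF cells with OU currents and re-extracts their
parameters, so closed-loop tests verify the *estimator* against the
*model's own* ground truth: recovery there is limited only by binning,
discretisation and finite data. Real recordings add electrode filtering
(assumed already corrected upstream — the package deliberately contains no
defiltering), measurement noise, spike-threshold variability (which
inflates the effective `Δ_T` above the single-spike sharpness), channel
noise and slow drift; closed-loop accuracy is therefore an upper bound on
real-data accuracy. Cells in the tails of the population — post-spike
decay constants of a few ms, which die inside the refractory exclusion —
are genuinely unidentifiable from slice fits at any realistic recording
length; medians over cells are the meaningful recovery statistic, and the
closed-loop checks use 10 cells per class at 60 s of stimulation each,
firing at 5–15 Hz.

## Numerical conventions

- Exponential overflow cap: argument 40 (`e^40 ≈ 2.4e17`).
- Root finding: log-spaced bracketing grids + Brent, tolerance 1e-6 ms.
- Nonlinear fits: `scipy.optimize.curve_fit` (Levenberg–Marquardt /
  trust-region-reflective with bounds), `xtol = ftol = 1e-8`, multistart
  over decay constants where the SSR landscape has local minima.
- All randomness flows through `numpy.random.default_rng(seed)`; every
  generator, simulation and CLI invocation is reproducible from its seed.
- Determinism: identical seeds give byte-identical serialised cohorts.
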