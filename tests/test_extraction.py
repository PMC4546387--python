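"""Dynamic I-V pipeline: capacitance, I-V curve, EIF and refractory fits."""

import warnings

import numpy as np
import pytest

from reifpop.core_model import EIFParams, RefractoryDynamics, rEIFParams
from reifpop.extraction import (
    DynamicIV,
    ExtractionConfig,
    SliceFit,
    compute_dynamic_iv,
    compute_ionic_current,
    estimate_capacitance,
    extract_cell,
    fit_eif,
    fit_refractory_dynamics,
    _bin_current,
)
from reifpop.simulator import SpikeTrain, Trace, simulate, virtual_cell
from reifpop.stimulus import OUStimulusConfig, generate_ou_current

from conftest import make_passive_trace


def grid_search_capacitance(trace, sel, lo=10.0, hi=1000.0, step=0.1):
    """Brute-force oracle: argmin over C of Var(I - C dV/dt) on a grid."""
    V, I, dt = trace.V, trace.I, trace.dt
    dv = np.empty_like(V)
    dv[1:-1] = (V[2:] - V[:-2]) / (2 * dt)
    dv[0] = (V[1] - V[0]) / dt
    dv[-1] = (V[-1] - V[-2]) / dt
    dv, I = dv[sel], I[sel]
    grid = np.arange(lo, hi + step, step)
    # Var(I - C dv) over grid, vectorised via second moments
    var_i = np.var(I)
    var_d = np.var(dv)
    cov = np.cov(I, dv)[0, 1]
    variances = var_i - 2 * grid * cov + grid**2 * var_d
    return grid[int(np.argmin(variances))]


class TestCapacitance:
    def test_passive_trace_recovers_true_value(self, passive_trace):
        C = estimate_capacitance(passive_trace)
        assert C == pytest.approx(200.0, rel=0.01)

    def test_closed_form_equals_grid_search(self, passive_trace):
        C = estimate_capacitance(passive_trace)
        med = np.median(passive_trace.V)
        sel = (passive_trace.V >= med - 1.0) & (passive_trace.V <= med + 1.0)
        C_grid = grid_search_capacitance(passive_trace, sel)
        assert abs(C - C_grid) <= 0.1

    def test_closed_loop_recovery_on_virtual_cell(self):
        from reifpop.stimulus import calibrate_gain

        cell = virtual_cell("TL5", 12)
        cfg = OUStimulusConfig.preset("low", duration=40_000.0, gain=700.0, dc=0.5, seed=12)
        gain = calibrate_gain(cell, cfg)
        cfg = OUStimulusConfig.preset("low", duration=40_000.0, gain=gain, dc=0.5, seed=12)
        tr, _ = simulate(cell, generate_ou_current(cfg), V0=cell.eif.E)
        C = estimate_capacitance(tr)
        assert C == pytest.approx(cell.eif.C, rel=0.05)

    def test_too_short_trace_rejected(self):
        tr = Trace(dt=0.05, I=np.zeros(1000), V=np.full(1000, -70.0))
        with pytest.raises(ValueError):
            estimate_capacitance(tr)


class TestIonicCurrent:
    def test_constant_voltage_passes_current_through(self):
        n = 2000
        I = np.linspace(-50, 50, n)
        tr = Trace(dt=0.05, I=I, V=np.full(n, -65.0))
        np.testing.assert_allclose(compute_ionic_current(tr, 150.0), I)

    def test_linear_ramp(self):
        # dV/dt of 1 mV/ms at C=100 pF with no input: I_ion = -100 pA
        n = 2000
        tr = Trace(dt=0.05, I=np.zeros(n), V=-70.0 + 0.05 * np.arange(n))
        ion = compute_ionic_current(tr, 100.0)
        np.testing.assert_allclose(ion[1:-1], -100.0, atol=1e-9)

    def test_pure_capacitor_cancels(self):
        rng = np.random.default_rng(0)
        V = np.cumsum(rng.standard_normal(5000)) * 0.01 - 70.0
        dt = 0.05
        dv = np.empty_like(V)
        dv[1:-1] = (V[2:] - V[:-2]) / (2 * dt)
        dv[0] = (V[1] - V[0]) / dt
        dv[-1] = (V[-1] - V[-2]) / dt
        tr = Trace(dt=dt, I=130.0 * dv, V=V)
        np.testing.assert_allclose(compute_ionic_current(tr, 130.0), 0.0, atol=1e-9)


class TestDynamicIV:
    def test_toy_fixture_bin_means(self):
        # six samples at two voltages, constant V (dV/dt = 0 so I_ion = I)
        V = np.array([-70.2, -70.3, -70.1, -60.2, -60.3, -60.1])
        I = np.array([10.0, 20.0, 30.0, -10.0, -20.0, -30.0])
        centers, m, se, counts = _bin_current(V, I, bin_width=1.0, min_count=2)
        assert len(centers) == 2
        assert m[0] == pytest.approx(20.0)
        assert m[1] == pytest.approx(-20.0)
        assert counts.tolist() == [3, 3]

    def test_passive_cell_is_linear_with_correct_slope(self, passive_trace):
        C = estimate_capacitance(passive_trace)
        iv = compute_dynamic_iv(passive_trace, C, spikes=SpikeTrain(np.array([]), passive_trace.duration))
        slope, intercept = np.polyfit(iv.bin_centers, iv.mean_current, 1)
        # I_dyn = g (V - E): slope g = C/tau = 10 nS, zero at E = -70
        assert slope == pytest.approx(10.0, rel=0.05)
        assert -intercept / slope == pytest.approx(-70.0, abs=0.5)

    def test_post_spike_exclusion_removes_samples(self):
        n = 20_000  # 1 s at 20 kHz
        rng = np.random.default_rng(1)
        V = -70.0 + rng.standard_normal(n)
        tr = Trace(dt=0.05, I=np.zeros(n), V=V)
        spikes = SpikeTrain(np.array([500.0]), tr.duration)
        iv = compute_dynamic_iv(tr, 100.0, spikes=spikes, exclusion=200.0)
        # samples in (500, 700] ms are gone: 4000 samples plus the stencil edges
        assert iv.counts.sum() <= n - 4000
        full = compute_dynamic_iv(tr, 100.0, spikes=SpikeTrain(np.array([]), tr.duration))
        assert full.counts.sum() - iv.counts.sum() >= 4000


class TestFitEIF:
    def _iv_from_eif(self, p, noise_sd=0.0, seed=0):
        from reifpop.core_model import forcing_term

        V = np.arange(-80.0, -48.0, 1.0) + 0.5
        F = forcing_term(p, V)
        I = -F * p.C
        rng = np.random.default_rng(seed)
        if noise_sd > 0:
            I = I + noise_sd * (I.max() - I.min()) * rng.standard_normal(len(I))
        se = np.full(len(V), max(noise_sd * (I.max() - I.min()), 1e-3))
        return DynamicIV(bin_centers=V, mean_current=I, se_current=se,
                         counts=np.full(len(V), 100), exclusion_window=200.0)

    def test_noiseless_recovery_is_exact(self):
        p = EIFParams(C=284.0, tau=18.7, E=-68.5, V_T=-52.7, Delta_T=1.16)
        iv = self._iv_from_eif(p)
        est = fit_eif(iv, p.C)
        assert est.tau == pytest.approx(p.tau, rel=1e-4)
        assert est.E == pytest.approx(p.E, rel=1e-4)
        assert est.V_T == pytest.approx(p.V_T, rel=1e-4)
        assert est.Delta_T == pytest.approx(p.Delta_T, rel=1e-4)

    def test_noisy_recovery_median_error(self):
        p = EIFParams(C=284.0, tau=18.7, E=-68.5, V_T=-52.7, Delta_T=1.16)
        errs_E, errs_VT = [], []
        for seed in range(50):
            iv = self._iv_from_eif(p, noise_sd=0.05, seed=seed)
            est = fit_eif(iv, p.C)
            errs_E.append(abs(est.E - p.E))
            errs_VT.append(abs(est.V_T - p.V_T))
        assert np.median(errs_E) < 1.0
        assert np.median(errs_VT) < 1.0

    def test_sharpness_at_fit_floor_is_flagged(self):
        # upswing as sharp as the fit floor: the result carries a flag
        # (either Delta_T pinned at its bound or failure to converge)
        p = EIFParams(C=100.0, tau=15.0, E=-70.0, V_T=-50.0, Delta_T=0.05)
        V = np.arange(-80.0, -49.0, 1.0) + 0.5
        from reifpop.core_model import forcing_term

        F = forcing_term(p, V)
        iv = DynamicIV(
            bin_centers=V, mean_current=-F * p.C,
            se_current=np.full(len(V), 1e-3),
            counts=np.full(len(V), 100), exclusion_window=200.0,
        )
        _, diag = fit_eif(iv, p.C, full_output=True)
        assert diag["delta_t_at_bound"] or not diag["converged"]

    def test_too_few_bins_rejected(self):
        p = EIFParams(C=100.0, tau=15.0, E=-70.0, V_T=-50.0, Delta_T=1.0)
        iv = self._iv_from_eif(p)
        small = DynamicIV(
            bin_centers=iv.bin_centers[:4], mean_current=iv.mean_current[:4],
            se_current=iv.se_current[:4], counts=iv.counts[:4], exclusion_window=200.0,
        )
        with pytest.raises(Exception):
            fit_eif(small, p.C)


class TestRefractoryFits:
    def _slices_from_dynamics(self, eif, refr, windows):
        """Exact window-averaged slice values from the model equations."""
        out = []
        for (a, b) in windows:
            x0, x1 = a - 4.0, b - 4.0
            w = x1 - x0

            def avg(tau):
                return tau / w * (np.exp(-x0 / tau) - np.exp(-x1 / tau))

            g = eif.g + refr.g1 * avg(refr.tau_g)
            vt = eif.V_T + refr.V_T1 * avg(refr.tau_T)
            if refr.E_mode == "bi":
                e = eif.E - refr.E1 * avg(refr.tau_E1) + refr.E2 * avg(refr.tau_E2)
            else:
                e = eif.E + refr.E_mono * avg(refr.tau_mono)
            out.append(SliceFit(window=(a, b), g=g, E=e, V_T=vt,
                                n_points=10_000, converged=True))
        return out

    WINDOWS = ((5.0, 8.0), (8.0, 12.0), (12.0, 18.0), (18.0, 27.0), (27.0, 40.0),
               (40.0, 60.0), (60.0, 90.0), (90.0, 140.0), (140.0, 200.0))

    def test_exact_slices_recover_bi_dynamics(self, tl5_like_eif, bi_refractory):
        slices = self._slices_from_dynamics(tl5_like_eif, bi_refractory, self.WINDOWS)
        refr, diag = fit_refractory_dynamics(slices, tl5_like_eif)
        assert refr.E_mode == "bi"
        assert refr.g1 == pytest.approx(bi_refractory.g1, rel=0.01)
        assert refr.tau_g == pytest.approx(bi_refractory.tau_g, rel=0.01)
        assert refr.V_T1 == pytest.approx(bi_refractory.V_T1, rel=0.01)
        assert refr.tau_T == pytest.approx(bi_refractory.tau_T, rel=0.01)

    def test_mono_cell_selects_mono_mode(self, tl5_like_eif):
        mono = RefractoryDynamics(
            g1=15.0, tau_g=20.0, V_T1=14.0, tau_T=12.0,
            E_mode="mono", E_mono=16.1, tau_mono=15.1,
        )
        slices = self._slices_from_dynamics(tl5_like_eif, mono, self.WINDOWS)
        refr, _ = fit_refractory_dynamics(slices, tl5_like_eif)
        assert refr.E_mode == "mono"
        assert refr.E_mono == pytest.approx(16.1, rel=0.05)

    def test_too_few_slices_rejected(self, tl5_like_eif, bi_refractory):
        slices = self._slices_from_dynamics(
            tl5_like_eif, bi_refractory, self.WINDOWS[:3]
        )
        with pytest.raises(Exception):
            fit_refractory_dynamics(slices, tl5_like_eif)


class TestExtractCell:
    def test_spikeless_trace_yields_steady_state_only(self, passive_trace):
        res = extract_cell(passive_trace)
        assert res.params is None
        assert "no spikes" in str(res.diagnostics["refractory"])
        assert res.eif.tau == pytest.approx(20.0, rel=0.1)
        assert res.eif.E == pytest.approx(-70.0, abs=1.0)

    def test_deterministic_given_trace(self):
        from reifpop.stimulus import calibrate_gain

        cell = virtual_cell("L4", 21)
        cfg = OUStimulusConfig.preset("low", duration=30_000.0, gain=900.0, dc=0.5, seed=21)
        gain = calibrate_gain(cell, cfg)
        cfg = OUStimulusConfig.preset("low", duration=30_000.0, gain=gain, dc=0.5, seed=21)
        tr, _ = simulate(cell, generate_ou_current(cfg), V0=cell.eif.E)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = extract_cell(tr)
            b = extract_cell(tr)
        assert a.C == b.C
        assert a.eif == b.eif
        assert (a.params is None) == (b.params is None)
        if a.params is not None:
            assert a.params.refractory == b.params.refractory

    def test_zero_jump_cell_slices_stay_near_steady(self, tl5_like_eif):
        from reifpop.extraction import fit_post_spike_slices
        from reifpop.simulator import plain_eif

        from reifpop.stimulus import calibrate_gain

        p = plain_eif(tl5_like_eif)
        cfg = OUStimulusConfig.preset("low", duration=30_000.0, gain=800.0, dc=0.7, seed=31)
        gain = calibrate_gain(p, cfg)
        cfg = OUStimulusConfig.preset("low", duration=30_000.0, gain=gain, dc=0.7, seed=31)
        tr, spikes = simulate(p, generate_ou_current(cfg), V0=p.eif.E)
        assert len(spikes) > 50
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            slices = fit_post_spike_slices(tr, p.eif.C, p.eif, spikes=spikes)
        late = [s for s in slices if s.converged and s.window[0] >= 20.0]
        assert late
        for s in late:
            assert s.g == pytest.approx(tl5_like_eif.g, rel=0.15)
            assert s.E == pytest.approx(tl5_like_eif.E, abs=1.5)
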