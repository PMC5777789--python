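"""Tests for peak extraction, Boltzmann/recovery fitting and group stats."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import curve_fit, minimize_scalar

from itokit.ephys_fit import (
    DegenerateDataError,
    build_iv_curve,
    compare_groups,
    current_density,
    fit_activation,
    fit_inactivation,
    fit_recovery,
    peak_current,
    summarize_group,
)
from itokit.ito_model import SweepRecording


def _sweep(t, i, name="activation", step=60.0):
    return SweepRecording(protocol_name=name, step_index=0,
                          step_voltage_mv=step, time_ms=t, current_pa=i)


class TestPeakExtraction:
    def test_flat_trace_zero_peak(self):
        t = np.arange(0, 100.0, 0.1)
        assert peak_current(_sweep(t, np.zeros_like(t)), (50.0, 99.9)) == 0.0

    def test_decaying_exponential_peaks_at_onset(self):
        t = np.arange(0, 100.0, 0.1)
        i = np.where(t >= 50.0, 100.0 * np.exp(-(t - 50.0) / 50.0), 0.0)
        assert peak_current(_sweep(t, i), (50.0, 99.9)) == pytest.approx(100.0)

    def test_baseline_is_subtracted(self):
        t = np.arange(0, 100.0, 0.1)
        i = np.full_like(t, 7.0)
        i[t >= 50.0] += 40.0
        assert peak_current(_sweep(t, i), (50.0, 99.9)) == pytest.approx(40.0)

    def test_smoothing_suppresses_noise_order_statistic(self):
        """A raw max over noisy samples inflates the peak by ~3 sd; the
        analysis smoother cuts that inflation several-fold."""
        t = np.arange(0, 600.0, 0.1)
        shape = np.where(t >= 50.0, (1.0 - np.exp(-(t - 50.0) / 0.5))
                         * np.exp(-(t - 50.0) / 80.0), 0.0)
        signal = shape / shape.max() * 1000.0
        raw_err, smooth_err = [], []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            noisy = _sweep(t, signal + 10.0 * rng.standard_normal(t.shape))
            raw_err.append(peak_current(noisy, (50.0, 599.9)) - 1000.0)
            smooth_err.append(
                peak_current(noisy, (50.0, 599.9), smooth_ms=1.0) - 1000.0)
        assert np.mean(raw_err) > 10.0      # order-statistic inflation ~1.5 sd
        assert np.mean(np.abs(smooth_err)) < 5.0

    def test_window_outside_sweep_rejected(self):
        t = np.arange(0, 100.0, 0.1)
        with pytest.raises(ValueError, match="window"):
            peak_current(_sweep(t, np.zeros_like(t)), (50.0, 200.0))

    def test_matches_closed_form_gate_solution(self, noisefree_cells):
        """Peak of the sampled sweep equals the analytic two-gate maximum.

        The oracle maximizes g*(a_inf+(a0-a_inf)e^(-t/tau_a)) *
        (i_inf+(i0-i_inf)e^(-t/tau_i))*(V-E) directly.
        """
        cell = noisefree_cells["WT"]
        p = cell.true_params
        sweep = cell.sweeps_for("activation")[-1]  # +60 mV
        measured = peak_current(sweep, (50.0, sweep.time_ms[-1]))

        a0, i0 = p.a_inf(-80.0), p.i_inf(-80.0)
        ainf, iinf = p.a_inf(60.0), p.i_inf(60.0)
        ta, ti = float(p.tau_a(60.0)), float(p.tau_i(60.0))

        def neg_current(t):
            a = ainf + (a0 - ainf) * math.exp(-t / ta)
            i = iinf + (i0 - iinf) * math.exp(-t / ti)
            return -p.g_to * a * i * (60.0 - p.e_rev)

        res = minimize_scalar(neg_current, bounds=(0.0, 500.0), method="bounded")
        analytic_peak = -res.fun * cell.capacitance_pf
        assert measured == pytest.approx(analytic_peak, rel=0.05)


class TestDensityAndIV:
    def test_density_examples(self):
        assert current_density(5579.0, 10.0) == pytest.approx(557.9)
        assert current_density(8077.9, 10.0) == pytest.approx(807.79)
        assert current_density(0.0, 33.0) == 0.0

    def test_nonpositive_capacitance_rejected(self):
        with pytest.raises(ValueError):
            current_density(100.0, 0.0)

    def test_iv_shape_and_monotonicity(self, noisefree_cells):
        iv = build_iv_curve(noisefree_cells["WT"])
        assert len(iv) == 11
        assert list(iv["step_voltage_mv"]) == sorted(iv["step_voltage_mv"])
        # noise-free: density strictly increasing over [-10, +60] mV
        upper = iv[iv["step_voltage_mv"] >= -10.0]["density_pa_pf"].to_numpy()
        assert np.all(np.diff(upper) > 0)

    def test_missing_activation_family_rejected(self, noisefree_cells):
        cell = noisefree_cells["WT"]
        stripped = type(cell)(cell_id="x", genotype="WT", capacitance_pf=12.0,
                              true_params=None,
                              sweeps=cell.sweeps_for("recovery"))
        with pytest.raises(ValueError, match="activation"):
            build_iv_curve(stripped)


def _boltzmann_curve(v, vhalf, k, increasing=True):
    s = (vhalf - v) if increasing else (v - vhalf)
    return 1.0 / (1.0 + np.exp(s / k))


class TestBoltzmannFits:
    @pytest.mark.parametrize("vhalf,k", [(-13.69, 11.35), (-22.98, 9.67)])
    def test_activation_parameter_recovery(self, vhalf, k):
        v = np.arange(-40.0, 61.0, 10.0)
        e_rev = -85.45
        density = _boltzmann_curve(v, vhalf, k) * 3.9 * (v - e_rev)
        iv = pd.DataFrame({"step_voltage_mv": v, "density_pa_pf": density})
        fit = fit_activation(iv, e_rev=e_rev)
        assert fit.vhalf_mv == pytest.approx(vhalf, abs=0.01)
        assert fit.k_mv == pytest.approx(k, abs=0.01)

    @pytest.mark.parametrize("vhalf,k", [(-41.16, 5.37), (-54.30, 8.56)])
    def test_inactivation_parameter_recovery(self, vhalf, k):
        v = np.arange(-100.0, 1.0, 10.0)
        peaks = _boltzmann_curve(v, vhalf, k, increasing=False) * 4200.0
        fit = fit_inactivation(pd.DataFrame({"prepulse_mv": v, "peak": peaks}))
        assert fit.vhalf_mv == pytest.approx(vhalf, abs=0.01)
        assert fit.k_mv == pytest.approx(k, abs=0.01)

    def test_exact_data_gives_zero_residual(self):
        v = np.array([-40.0, -20.0, 0.0, 20.0, 40.0])
        y = _boltzmann_curve(v, -10.0, 9.0)
        iv = pd.DataFrame({"step_voltage_mv": v,
                           "density_pa_pf": y * (v + 90.0)})
        fit = fit_activation(iv, e_rev=-90.0)
        assert fit.rss == pytest.approx(0.0, abs=1e-16)

    def test_flat_data_rejected(self):
        v = np.arange(-100.0, 1.0, 10.0)
        with pytest.raises(DegenerateDataError):
            fit_inactivation(pd.DataFrame({"prepulse_mv": v,
                                           "peak": np.full_like(v, 5.0)}))

    def test_too_few_points_rejected(self):
        df = pd.DataFrame({"prepulse_mv": [-100.0, -50.0, 0.0],
                           "peak": [1.0, 0.5, 0.0]})
        with pytest.raises(DegenerateDataError, match="at least 4"):
            fit_inactivation(df)

    def test_reversal_inside_step_range_rejected(self):
        v = np.arange(-40.0, 61.0, 10.0)
        iv = pd.DataFrame({"step_voltage_mv": v, "density_pa_pf": v + 50.0})
        with pytest.raises(ValueError, match="reversal"):
            fit_activation(iv, e_rev=0.0)

    @given(offset=st.floats(-500, 500), scale=st.floats(0.1, 50))
    @settings(derandomize=True, max_examples=20, deadline=None)
    def test_offset_and_scale_invariance(self, offset, scale):
        """Constant offsets and positive rescaling leave V1/2 and k unchanged."""
        v = np.arange(-100.0, 1.0, 10.0)
        peaks = _boltzmann_curve(v, -45.0, 6.0, increasing=False) * 4000.0
        base = fit_inactivation(pd.DataFrame({"prepulse_mv": v, "peak": peaks}))
        mod = fit_inactivation(pd.DataFrame(
            {"prepulse_mv": v, "peak": peaks * scale + offset}))
        assert mod.vhalf_mv == pytest.approx(base.vhalf_mv, abs=1e-6)
        assert mod.k_mv == pytest.approx(base.k_mv, abs=1e-6)

    def test_conductance_vs_current_normalization_magnitude(self, noisefree_fits,
                                                            noisefree_cells):
        """Quantify the methodological choice: fitting normalized *current*
        instead of chord conductance drags the apparent V1/2 depolarized by
        roughly the driving-force gradient — about 15 mV on WT data."""
        iv = noisefree_fits["WT"].iv
        v = iv["step_voltage_mv"].to_numpy()
        y = iv["density_pa_pf"].to_numpy()
        y = y / y.max()

        def model(v, vhalf, k, amp, base):
            return base + amp / (1.0 + np.exp((vhalf - v) / k))

        popt, _ = curve_fit(model, v, y, p0=[-10.0, 8.0, 1.0, 0.0],
                            maxfev=10000)
        shift = popt[0] - noisefree_fits["WT"].activation.vhalf_mv
        assert 5.0 < shift < 25.0


class TestRecoveryFit:
    @pytest.mark.parametrize("tau", [27.33, 81.17])
    def test_tau_recovery_from_exact_data(self, tau):
        x = np.array([2.0, 5.0, 10.0, 20.0, 50.0, 100.0, 200.0, 350.0, 500.0])
        y = 1.0 - np.exp(-x / tau)
        fit = fit_recovery(pd.DataFrame({"interval_ms": x, "p2_over_p1": y}))
        assert fit.tau_ms == pytest.approx(tau, abs=0.01)
        assert fit.y0 == pytest.approx(1.0, abs=1e-4)
        assert fit.a1 == pytest.approx(-1.0, abs=1e-4)

    def test_exponential_identity_at_tau(self):
        """y(tau) = 1 - 1/e for y0=1, A1=-1."""
        x = np.array([2.0, 10.0, 27.33, 50.0, 120.0, 400.0])
        y = 1.0 - np.exp(-x / 27.33)
        fit = fit_recovery(pd.DataFrame({"interval_ms": x, "p2_over_p1": y}))
        value_at_tau = fit.y0 + fit.a1 * math.exp(-1.0)
        assert value_at_tau == pytest.approx(1.0 - math.exp(-1.0), abs=1e-6)

    def test_out_of_range_ratios_rejected(self):
        df = pd.DataFrame({"interval_ms": [2.0, 5.0, 10.0, 20.0],
                           "p2_over_p1": [0.1, 0.5, 1.5, 1.0]})
        with pytest.raises(ValueError, match="ratios"):
            fit_recovery(df)

    def test_flat_recovery_rejected(self):
        df = pd.DataFrame({"interval_ms": [2.0, 5.0, 10.0, 20.0],
                           "p2_over_p1": [0.5, 0.5, 0.5, 0.5]})
        with pytest.raises(DegenerateDataError):
            fit_recovery(df)


class TestGroupStatistics:
    def test_sem_of_small_sample(self, noisefree_fits):
        import dataclasses
        cells = [dataclasses.replace(noisefree_fits["WT"], cell_id=f"c{v}",
                                     density_60_pa_pf=float(v))
                 for v in (1.0, 2.0, 3.0)]
        gs = summarize_group(cells)
        assert gs.mean("density_60") == pytest.approx(2.0)
        assert gs.sem("density_60") == pytest.approx(0.5774, abs=1e-4)

    def test_summary_requires_two_cells(self, noisefree_fits):
        with pytest.raises(ValueError, match="at least 2"):
            summarize_group([noisefree_fits["WT"]])

    def test_identical_cells_have_zero_sem(self, noisefree_fits):
        f = noisefree_fits["WT"]
        gs = summarize_group([f, f, f])
        assert gs.n_cells == 3
        assert gs.sem("act_vhalf") == 0.0
        assert gs.mean("density_60") == pytest.approx(f.density_60_pa_pf)

    def test_t_test_identical_samples(self):
        out = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out["t"] == pytest.approx(0.0, abs=1e-12)
        assert out["p"] == pytest.approx(1.0)

    def test_t_test_pooled_variance_hand_value(self):
        out = compare_groups([1.0, 3.0], [2.0, 4.0])
        assert out["t"] == pytest.approx(-0.7071, abs=1e-4)

    def test_percent_difference_of_printed_densities(self):
        out = compare_groups([557.9, 557.9], [807.79, 807.79])
        assert out["percent_difference"] == pytest.approx(44.79, abs=0.01)
        assert out["zero_variance"] is True

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            compare_groups([1.0], [2.0, 3.0])
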