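"""Unit and property tests for the Ito Hodgkin-Huxley formulation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from itokit.ito_model import (
    E_REV_DEFAULT,
    GateState,
    ItoParams,
    ProtocolDefinition,
    ito_current,
    make_genotype_params,
    nernst_potassium,
    simulate_voltage_clamp,
    steady_state_activation,
    steady_state_inactivation,
)

WT = make_genotype_params("WT")
MUT = make_genotype_params("T361S")


class TestSteadyStates:
    def test_midpoint_is_half(self):
        assert steady_state_activation(WT.act_vhalf, WT) == pytest.approx(0.5)
        assert steady_state_inactivation(WT.inact_vhalf, WT) == pytest.approx(0.5)

    def test_wt_activation_at_zero_mv(self):
        # 1/(1+exp(-13.69/11.35)) evaluated by hand
        assert steady_state_activation(0.0, WT) == pytest.approx(0.7696, abs=1e-4)

    def test_wt_availability_at_holding(self):
        # 1/(1+exp((-80+41.16)/5.37)) evaluated by hand
        assert steady_state_inactivation(-80.0, WT) == pytest.approx(0.99927, abs=2e-5)

    @given(vhalf=st.floats(-60, 0), k=st.floats(3, 15))
    @settings(derandomize=True, max_examples=25)
    def test_nine_tenths_identity(self, vhalf, k):
        """y = 0.9 at vhalf + k*ln 9 (activation) / vhalf - k*ln 9 (inactivation)."""
        p = WT.with_(act_vhalf=vhalf, act_k=k, inact_vhalf=vhalf, inact_k=k)
        assert steady_state_activation(vhalf + k * math.log(9), p) == \
            pytest.approx(0.9, abs=1e-12)
        assert steady_state_inactivation(vhalf - k * math.log(9), p) == \
            pytest.approx(0.9, abs=1e-12)

    def test_activation_monotone_with_limits(self):
        v = np.linspace(-120, 80, 401)
        y = steady_state_activation(v, WT)
        assert np.all(np.diff(y) > 0)
        assert steady_state_activation(-1e3, WT) < 1e-12
        assert steady_state_activation(1e3, WT) > 1 - 1e-12

    @given(v=st.floats(-40, 60))
    @settings(derandomize=True, max_examples=50)
    def test_mutant_activates_more_at_test_potentials(self, v):
        """The hyperpolarized shift makes T361S a_inf exceed WT everywhere in [-40, 60] mV."""
        assert steady_state_activation(v, MUT) > steady_state_activation(v, WT)


class TestCurrentAndParams:
    def test_current_zero_cases(self):
        assert ito_current(30.0, GateState(a=0.0, i=1.0), WT) == 0.0
        assert ito_current(WT.e_rev, GateState(a=0.5, i=0.5), WT) == 0.0

    def test_current_arithmetic(self):
        p = WT.with_(g_to=0.1, e_rev=-85.0)
        assert ito_current(60.0, GateState(a=1.0, i=1.0), p) == \
            pytest.approx(14.5)

    def test_outward_above_reversal(self):
        assert ito_current(0.0, GateState(a=0.5, i=0.5), WT) > 0

    def test_printed_parameter_sets(self):
        assert WT.act_vhalf == -13.69 and WT.act_k == 11.35
        assert WT.inact_vhalf == -41.16 and WT.inact_k == 5.37
        assert MUT.act_vhalf == -22.98 and MUT.inact_vhalf == -54.30
        assert WT.act_vhalf - MUT.act_vhalf == pytest.approx(9.29)
        assert WT.inact_vhalf - MUT.inact_vhalf == pytest.approx(13.14)
        assert MUT.g_to == pytest.approx(1.5 * WT.g_to)

    def test_unknown_genotype_rejected(self):
        with pytest.raises(ValueError, match="unknown genotype"):
            make_genotype_params("A545P")

    def test_recovery_tau_anchored_at_holding(self):
        assert float(WT.tau_i(-80.0)) == pytest.approx(27.33, rel=1e-9)
        assert float(MUT.tau_i(-80.0)) == pytest.approx(81.17, rel=1e-9)

    def test_tau_positive_over_clamp_range(self):
        v = np.linspace(-120, 80, 201)
        assert np.all(WT.tau_i(v) > 0) and np.all(MUT.tau_i(v) > 0)

    def test_nernst_reversal(self):
        # 5 mM out / 144 mM in at 22 degC
        assert nernst_potassium() == pytest.approx(-85.45, abs=0.1)
        assert E_REV_DEFAULT == nernst_potassium()

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            WT.with_(act_k=-1.0)
        with pytest.raises(ValueError):
            WT.with_(g_to=-0.1)
        with pytest.raises(ValueError):
            GateState(a=1.2, i=0.0)

    def test_params_roundtrip_dict(self):
        assert ItoParams.from_dict(WT.to_dict()) == WT


def _single_step_protocol(v_step, hold_ms=50.0, step_ms=500.0):
    return ProtocolDefinition(
        name="activation",
        sweeps=(((-80.0, hold_ms), (v_step, step_ms)),),
        step_values=(v_step,))


class TestVoltageClamp:
    def test_gate_relaxation_matches_closed_form(self):
        """Simulated current equals the analytic two-gate solution exactly."""
        proto = _single_step_protocol(20.0)
        sweep = simulate_voltage_clamp(WT, proto)[0]
        t = sweep.time_ms
        in_step = t >= 50.0
        rel = t[in_step] - 50.0
        a0, i0 = WT.a_inf(-80.0), WT.i_inf(-80.0)
        a = WT.a_inf(20.0) + (a0 - WT.a_inf(20.0)) * np.exp(-rel / WT.tau_a(20.0))
        i = WT.i_inf(20.0) + (i0 - WT.i_inf(20.0)) * np.exp(-rel / float(WT.tau_i(20.0)))
        expected = WT.g_to * a * i * (20.0 - WT.e_rev)
        np.testing.assert_allclose(sweep.current_pa[in_step], expected,
                                   rtol=1e-12, atol=1e-12)

    def test_holding_current_is_negligible(self):
        """At -80 mV the channel is nearly closed: the resting current is tiny."""
        proto = _single_step_protocol(-80.0, hold_ms=50.0, step_ms=5000.0)
        sweep = simulate_voltage_clamp(WT, proto)[0]
        peak_60 = WT.g_to * (60.0 - WT.e_rev)  # upper bound scale
        assert np.max(np.abs(sweep.current_pa)) < 0.005 * peak_60

    def test_peak_bounded_by_initial_availability(self):
        sweep = simulate_voltage_clamp(WT, _single_step_protocol(60.0))[0]
        bound = WT.g_to * WT.i_inf(-80.0) * (60.0 - WT.e_rev)
        assert np.max(sweep.current_pa) <= bound + 1e-9

    def test_peak_linear_in_conductance(self):
        """Doubling g_to doubles the clamp peak to within 0.1%."""
        proto = _single_step_protocol(60.0)
        p1 = simulate_voltage_clamp(WT, proto)[0].current_pa.max()
        p2 = simulate_voltage_clamp(WT.with_(g_to=2 * WT.g_to),
                                    proto)[0].current_pa.max()
        assert p2 / p1 == pytest.approx(2.0, rel=1e-3)

    def test_capacitance_scales_current(self):
        proto = _single_step_protocol(60.0)
        dens = simulate_voltage_clamp(WT, proto, capacitance_pf=1.0)[0]
        abs_ = simulate_voltage_clamp(WT, proto, capacitance_pf=12.0)[0]
        np.testing.assert_allclose(abs_.current_pa, 12.0 * dens.current_pa)

    def test_rejects_bad_dt_and_empty_protocol(self):
        proto = _single_step_protocol(0.0)
        with pytest.raises(ValueError, match="dt_ms"):
            simulate_voltage_clamp(WT, proto, dt_ms=0.0)
        with pytest.raises(ValueError, match="dt_ms"):
            simulate_voltage_clamp(WT, proto, dt_ms=0.2)
        with pytest.raises(ValueError):
            ProtocolDefinition(name="x", sweeps=(), step_values=(0.0,))

    def test_rejects_out_of_range_voltage(self):
        with pytest.raises(ValueError, match="outside"):
            _single_step_protocol(100.0)
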