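"""Hodgkin–Huxley model of the cardiac transient outward potassium current.

The transient outward current (Ito) is carried in human atrium by Kv4.3
channels (gene *KCND3*) assembled with the auxiliary subunit KChIP2.  This
module provides a two-gate Hodgkin–Huxley description of that current,

    I_to = g_to * a * i * (V - E_rev)        [pA/pF]

with an activation gate ``a`` and an inactivation gate ``i`` relaxing
toward voltage-dependent steady states,

    a_inf(V) = 1 / (1 + exp((act_vhalf - V) / act_k))     (increasing in V)
    i_inf(V) = 1 / (1 + exp((V - inact_vhalf) / inact_k)) (decreasing in V)

Both slope factors are reported positive; the orientation of each curve is
carried by the equation, not the sign of k.  Two parameter sets ship with
the package: wild-type Kv4.3 and the atrial-fibrillation-associated T361S
pore mutant, using the half-(in)activation voltages, slope factors and
recovery time constants measured for each genotype, with mutant maximal
conductance scaled 1.5-fold over wild type.

The model serves two masters:

* under **voltage clamp** the gate ODEs are piecewise-linear and are
  integrated exactly (exponential update per command segment), producing
  noiseless sweep recordings that the synthetic cohort generator decorates
  with cell variability and recording noise;
* under **current clamp** the same parameterization plugs into the atrial
  action-potential model (`itokit.atrial_ap`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
import numpy as np

__all__ = [
    "FARADAY",
    "GAS_CONSTANT",
    "nernst_potassium",
    "E_REV_DEFAULT",
    "TAU_ACT_DEFAULT_MS",
    "TAU_DEP_DEFAULT_MS",
    "G_TO_WT_DEFAULT",
    "GENOTYPE_KINETICS",
    "ItoParams",
    "GateState",
    "ProtocolDefinition",
    "SweepRecording",
    "steady_state_activation",
    "steady_state_inactivation",
    "tau_activation",
    "tau_inactivation",
    "ito_current",
    "make_genotype_params",
    "simulate_voltage_clamp",
]

FARADAY = 96485.33212  # C / mol
GAS_CONSTANT = 8.31446261815324  # J / (mol K)

#: Recording-solution potassium, mM (bath / pipette: K-gluconate + KCl).
K_OUT_MM = 5.0
K_IN_MM = 144.0
CLAMP_TEMP_C = 22.0


def nernst_potassium(k_out_mm: float = K_OUT_MM, k_in_mm: float = K_IN_MM,
                     temp_c: float = CLAMP_TEMP_C) -> float:
    """Potassium Nernst potential, mV, for the given concentrations."""
    t_kelvin = temp_c + 273.15
    return 1000.0 * GAS_CONSTANT * t_kelvin / FARADAY * math.log(k_out_mm / k_in_mm)


#: EK of the recording solutions at 22 degC, ~ -85.5 mV; the default Ito
#: reversal potential under voltage clamp.
E_REV_DEFAULT = nernst_potassium()

#: Activation time constant, ms.  Kv4.3+KChIP2 activation is fast relative
#: to both inactivation and the 0.1 ms sampling interval; a small constant
#: tau keeps the peak gating factor max_t a(t)*i(t) effectively voltage
#: independent so peak-based analysis recovers the generating Boltzmanns
#: without protocol bias.
TAU_ACT_DEFAULT_MS = 0.5

#: Inactivation time constant at strongly depolarized potentials, ms;
#: chosen so 500-ms steps show essentially complete current decay while
#: keeping the early peak sharp enough for unbiased peak extraction.
TAU_DEP_DEFAULT_MS = 80.0

#: Wild-type maximal conductance, nS/pF, calibrated once so the noise-free
#: simulated WT peak density at +60 mV equals the measured group mean of
#: 557.9 pA/pF (see synth_cohort.calibrate_g_to).  The mutant value is
#: 1.5x this, mirroring the mutation's increased surface expression.
G_TO_WT_DEFAULT = 3.9979061782459326

#: Printed per-genotype kinetics: half-activation / half-inactivation
#: voltages (mV), slope factors (mV) and recovery time constant (ms).
GENOTYPE_KINETICS: dict[str, dict[str, float]] = {
    "WT": {
        "act_vhalf": -13.69, "act_k": 11.35,
        "inact_vhalf": -41.16, "inact_k": 5.37,
        "tau_rec_ms": 27.33,
    },
    "T361S": {
        "act_vhalf": -22.98, "act_k": 9.67,
        "inact_vhalf": -54.30, "inact_k": 8.56,
        "tau_rec_ms": 81.17,
    },
}

_VOLTAGE_RANGE = (-120.0, 80.0)


@dataclass(frozen=True)
class ItoParams:
    """Complete Ito parameterization for one genotype.

    tau_inact is an anchored sigmoid between the depolarized decay constant
    ``tau_dep_ms`` and the recovery constant ``tau_rec_ms``:

        w(V) = sigma(V) / sigma(-80),  sigma(V) = 1/(1 + exp((V+50)/8))
        tau_i(V) = tau_dep_ms + (tau_rec_ms - tau_dep_ms) * w(V)

    The normalization by sigma(-80) pins tau_i(-80 mV) to the measured
    recovery time constant exactly (the holding potential at which recovery
    from inactivation was characterized).
    """

    genotype: str
    g_to: float                     # nS/pF
    act_vhalf: float                # mV
    act_k: float                    # mV, > 0
    inact_vhalf: float              # mV
    inact_k: float                  # mV, > 0
    tau_rec_ms: float               # recovery tau at -80 mV, ms
    tau_act_ms: float = TAU_ACT_DEFAULT_MS
    tau_dep_ms: float = TAU_DEP_DEFAULT_MS
    e_rev: float = E_REV_DEFAULT    # mV

    def __post_init__(self) -> None:
        if self.act_k <= 0 or self.inact_k <= 0:
            raise ValueError("slope factors must be positive")
        if self.g_to < 0:
            raise ValueError("g_to must be non-negative")
        if self.tau_act_ms <= 0 or self.tau_rec_ms <= 0 or self.tau_dep_ms <= 0:
            raise ValueError("time constants must be positive")

    # -- steady states -----------------------------------------------------
    def a_inf(self, v):
        return steady_state_activation(v, self)

    def i_inf(self, v):
        return steady_state_inactivation(v, self)

    # -- time constants ----------------------------------------------------
    def tau_a(self, v):
        return tau_activation(v, self)

    def tau_i(self, v):
        return tau_inactivation(v, self)

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "genotype": self.genotype,
            "g_to": self.g_to,
            "act_vhalf": self.act_vhalf,
            "act_k": self.act_k,
            "inact_vhalf": self.inact_vhalf,
            "inact_k": self.inact_k,
            "tau_rec_ms": self.tau_rec_ms,
            "tau_act_ms": self.tau_act_ms,
            "tau_dep_ms": self.tau_dep_ms,
            "e_rev": self.e_rev,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ItoParams":
        return cls(**{k: d[k] for k in (
            "genotype", "g_to", "act_vhalf", "act_k", "inact_vhalf",
            "inact_k", "tau_rec_ms", "tau_act_ms", "tau_dep_ms", "e_rev")})

    def with_(self, **kw) -> "ItoParams":
        return replace(self, **kw)


@dataclass
class GateState:
    """Hodgkin–Huxley gate pair; both dimensionless fractions in [0, 1]."""

    a: float
    i: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.a <= 1.0 and 0.0 <= self.i <= 1.0):
            raise ValueError("gate variables must lie in [0, 1]")


def steady_state_activation(v, p: ItoParams):
    """Boltzmann steady-state activation, increasing in V; 0.5 at act_vhalf."""
    return 1.0 / (1.0 + np.exp((p.act_vhalf - np.asarray(v, dtype=float)) / p.act_k))


def steady_state_inactivation(v, p: ItoParams):
    """Boltzmann steady-state availability, decreasing in V; 0.5 at inact_vhalf."""
    return 1.0 / (1.0 + np.exp((np.asarray(v, dtype=float) - p.inact_vhalf) / p.inact_k))


def tau_activation(v, p: ItoParams):
    """Activation time constant, ms (voltage independent by default)."""
    return np.full_like(np.asarray(v, dtype=float), p.tau_act_ms) \
        if np.ndim(v) else p.tau_act_ms


_TAU_SIG_VHALF = -50.0
_TAU_SIG_K = 8.0
_TAU_SIG_AT_HOLD = 1.0 / (1.0 + math.exp((-80.0 - _TAU_SIG_VHALF) / _TAU_SIG_K))


def tau_inactivation(v, p: ItoParams):
    """Inactivation/recovery time constant, ms; equals tau_rec_ms at -80 mV."""
    v = np.asarray(v, dtype=float)
    w = (1.0 / (1.0 + np.exp((v - _TAU_SIG_VHALF) / _TAU_SIG_K))) / _TAU_SIG_AT_HOLD
    return p.tau_dep_ms + (p.tau_rec_ms - p.tau_dep_ms) * w


def ito_current(v, g: GateState, p: ItoParams):
    """Ohmic Ito current density, pA/pF; positive (outward) for V > E_rev."""
    return p.g_to * g.a * g.i * (np.asarray(v, dtype=float) - p.e_rev)


def make_genotype_params(genotype: str, *, g_to: float | None = None,
                         tau_act_ms: float = TAU_ACT_DEFAULT_MS,
                         tau_dep_ms: float = TAU_DEP_DEFAULT_MS,
                         e_rev: float = E_REV_DEFAULT) -> ItoParams:
    """Printed parameter set for ``genotype`` ("WT" or "T361S").

    The mutant conductance defaults to 1.5x the calibrated wild-type value,
    reflecting its increased cell-surface expression.
    """
    try:
        kin = GENOTYPE_KINETICS[genotype]
    except KeyError:
        raise ValueError(
            f"unknown genotype {genotype!r}; expected one of "
            f"{sorted(GENOTYPE_KINETICS)}") from None
    if g_to is None:
        g_to = G_TO_WT_DEFAULT * (1.5 if genotype == "T361S" else 1.0)
    return ItoParams(genotype=genotype, g_to=g_to, tau_act_ms=tau_act_ms,
                     tau_dep_ms=tau_dep_ms, e_rev=e_rev, **kin)


# ---------------------------------------------------------------------------
# Voltage-clamp protocol simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProtocolDefinition:
    """A family of voltage-clamp sweeps.

    Each sweep is an ordered list of (voltage mV, duration ms) command
    segments; ``step_values`` carries the per-sweep independent variable
    (step or prepulse voltage in mV, or recovery gap duration in ms).
    """

    name: str
    sweeps: tuple[tuple[tuple[float, float], ...], ...]
    step_values: tuple[float, ...]
    holding_mv: float = -80.0
    inter_sweep_interval_ms: float = 5000.0
    sample_rate_hz: float = 10000.0

    def __post_init__(self) -> None:
        if len(self.sweeps) != len(self.step_values):
            raise ValueError("one step_value per sweep required")
        for sweep in self.sweeps:
            for v, dur in sweep:
                if dur <= 0:
                    raise ValueError("segment durations must be positive")
                if not (_VOLTAGE_RANGE[0] <= v <= _VOLTAGE_RANGE[1]):
                    raise ValueError(
                        f"command voltage {v} mV outside {_VOLTAGE_RANGE}")

    @property
    def n_sweeps(self) -> int:
        return len(self.sweeps)


@dataclass
class SweepRecording:
    """One sampled sweep: current trace under a known command waveform."""

    protocol_name: str
    step_index: int
    step_voltage_mv: float          # the sweep's independent variable
    time_ms: np.ndarray
    current_pa: np.ndarray

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.current_pa = np.asarray(self.current_pa, dtype=float)
        if self.time_ms.shape != self.current_pa.shape:
            raise ValueError("time and current arrays must have equal length")


def simulate_voltage_clamp(p: ItoParams, protocol: ProtocolDefinition,
                           dt_ms: float | None = None,
                           capacitance_pf: float = 1.0) -> list[SweepRecording]:
    """Simulate the protocol, exactly integrating the gate ODEs per segment.

    Under a piecewise-constant command voltage each gate relaxes as
    ``x(t) = x_inf + (x0 - x_inf) * exp(-t / tau_x)``; the update is applied
    in closed form per segment, so the only discretization is the sampling
    grid itself.  Gates start from steady state at the holding potential
    (the inter-sweep interval is long relative to recovery).  Output is
    noiseless; with ``capacitance_pf = 1`` the trace is numerically the
    current density in pA/pF.
    """
    if dt_ms is None:
        dt_ms = 1000.0 / protocol.sample_rate_hz
    if dt_ms <= 0:
        raise ValueError("dt_ms must be positive")
    if dt_ms > 0.1 + 1e-12:
        raise ValueError("dt_ms must be <= 0.1 ms")
    if protocol.n_sweeps == 0:
        raise ValueError("protocol has no sweeps")

    a_hold = float(p.a_inf(protocol.holding_mv))
    i_hold = float(p.i_inf(protocol.holding_mv))

    sweeps: list[SweepRecording] = []
    for idx, (segments, step_value) in enumerate(
            zip(protocol.sweeps, protocol.step_values)):
        total = sum(dur for _, dur in segments)
        n = int(round(total / dt_ms))
        t = np.arange(n + 1) * dt_ms
        current = np.empty_like(t)

        a0, i0 = a_hold, i_hold
        t_start = 0.0
        for seg_idx, (v, dur) in enumerate(segments):
            t_end = t_start + dur
            last = seg_idx == len(segments) - 1
            if last:
                mask = (t >= t_start - 1e-9)
            else:
                mask = (t >= t_start - 1e-9) & (t < t_end - 1e-9)
            rel = t[mask] - t_start
            a_inf = float(p.a_inf(v))
            i_inf = float(p.i_inf(v))
            tau_a = float(p.tau_a(v))
            tau_i = float(p.tau_i(v))
            a_t = a_inf + (a0 - a_inf) * np.exp(-rel / tau_a)
            i_t = i_inf + (i0 - i_inf) * np.exp(-rel / tau_i)
            current[mask] = (p.g_to * a_t * i_t * (v - p.e_rev)
                             * capacitance_pf)
            # exact state at the segment boundary
            a0 = a_inf + (a0 - a_inf) * math.exp(-dur / tau_a)
            i0 = i_inf + (i0 - i_inf) * math.exp(-dur / tau_i)
            t_start = t_end

        sweeps.append(SweepRecording(
            protocol_name=protocol.name, step_index=idx,
            step_voltage_mv=float(step_value), time_ms=t, current_pa=current))
    return sweeps
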