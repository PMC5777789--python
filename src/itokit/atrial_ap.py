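"""Paced human atrial action-potential model with pluggable Ito.

The question this module answers: given the measured wild-type vs T361S
differences in Ito gating (hyperpolarized activation/inactivation, slowed
recovery) and the mutant's 1.5-fold conductance increase, what happens to
the atrial action potential duration (APD90) across pacing rates?

The baseline cell is a self-contained human-atrial-like ionic model in
Hodgkin–Huxley form with fixed intracellular ion concentrations: fast
sodium (m^3 h j), L-type calcium (d f), rapid and slow delayed rectifiers
(xr, xs), ultrarapid atrial potassium (ua^3 ui), inward rectifier, a sodium
background leak, and the package's two-gate Ito.  Gate kinetics for the
background currents follow standard human-atrial formulations; the
conductances are calibrated (and frozen here) to an atrial phenotype:
resting potential near -76 mV, overshoot near +25 mV, APD90 at a basic
cycle length (BCL) of 1000 ms in the 200-350 ms window, and APD90
shortening at faster rates (rate adaptation, carried mainly by incomplete
recovery of L-type calcium inactivation at short diastolic intervals).

The cell is paced with a 1 ms, -40 pA/pF stimulus train after a 10 s
unpaced equilibration; APD90 is measured on the 40th beat, from maximum
upstroke velocity to 90% repolarization, per beat, with linear
interpolation between samples.  Integration uses a stiff-capable
variable-step solver (LSODA by default); the stimulus is handled by
splitting each beat at the stimulus edges so the right-hand side seen by
the solver is smooth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .ito_model import ItoParams, make_genotype_params

__all__ = [
    "APModelConfig",
    "APResult",
    "AtrialCellModel",
    "ap_ito_params",
    "GTO_AP_WT",
    "compute_apd90",
    "run_paced_simulation",
    "rate_adaptation",
    "compare_wt_mutant",
    "DEFAULT_BCLS_MS",
]

#: The six pacing cycle lengths examined, ms.
DEFAULT_BCLS_MS = (1000.0, 900.0, 800.0, 700.0, 600.0, 500.0)

#: Body-temperature ionic conditions (mM) for the myocyte model.
NA_OUT, NA_IN = 140.0, 11.2
K_OUT, K_IN = 5.4, 139.0
RTF_37 = 26.712846  # mV, RT/F at 310.15 K

E_NA = RTF_37 * math.log(NA_OUT / NA_IN)
E_K = RTF_37 * math.log(K_OUT / K_IN)

#: Wild-type atrial Ito conductance (nS/pF) in the AP model.  The clamp
#: cohort's conductance reflects heterologous overexpression; this value is
#: the calibrated myocyte-level conductance of the baseline cell.
GTO_AP_WT = 0.165


@dataclass(frozen=True)
class APModelConfig:
    """Settings for a paced action-potential run (currents in pA/pF)."""

    stim_amplitude_pa_pf: float = -40.0   # inward
    stim_duration_ms: float = 1.0
    bcl_ms: float = 1000.0
    n_beats: int = 40
    rtol: float = 1e-6
    atol: float = 1e-8
    max_step_ms: float = math.inf
    method: str = "LSODA"
    ito_scale: float = 1.5        # Ito conductance multiplier (mutant arm)
    density_scale: float = 1.0    # post-gating multiplier (mutant arm)
    equilibration_ms: float = 10000.0
    sample_ms: float = 0.25       # output grid for APD measurement
    cm_pf: float = 1.0            # per-capacitance current basis

    def __post_init__(self) -> None:
        if self.bcl_ms <= self.stim_duration_ms:
            raise ValueError("bcl_ms must exceed the stimulus duration")
        if self.n_beats < 1:
            raise ValueError("n_beats must be >= 1")
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("solver tolerances must be positive")


@dataclass
class APResult:
    """Output of one paced run."""

    genotype: str
    bcl_ms: float
    time_ms: np.ndarray           # last two beats, re-zeroed at their start
    vm_mv: np.ndarray
    ito_pa_pf: np.ndarray
    apd90_ms: np.ndarray          # per beat; NaN where flagged
    captured: np.ndarray          # per beat bool (upstroke crossed -40 mV)
    repolarized: np.ndarray       # per beat bool (reached the 90% level)
    resting_vm_mv: float
    peak_vm_mv: float

    @property
    def apd90_final_ms(self) -> float:
        return float(self.apd90_ms[-1])


class AtrialCellModel:
    """Baseline human-atrial-like myocyte with a pluggable Ito.

    The interface other baseline cells must provide: ``state_names``,
    ``initial_state()``, and ``rhs(t, y, ito, stim_pa_pf)``; anything with
    that surface can replace this class in :func:`run_paced_simulation`.
    """

    state_names = ("v", "m", "h", "j", "d", "f", "xr", "xs",
                   "ua", "ui", "a", "ito_i")

    def __init__(self, *,
                 g_na: float = 7.8,
                 g_cal: float = 0.20,
                 g_k1: float = 0.09,
                 g_kr: float = 0.0294,
                 g_ks: float = 0.10,
                 g_kur_scale: float = 1.0,
                 g_b_na: float = 0.00251,
                 f_ca: float = 0.6,
                 e_ca_eff: float = 65.0):
        self.g_na = g_na
        self.g_cal = g_cal
        self.g_k1 = g_k1
        self.g_kr = g_kr
        self.g_ks = g_ks
        self.g_kur_scale = g_kur_scale
        self.g_b_na = g_b_na
        self.f_ca = f_ca
        self.e_ca_eff = e_ca_eff

    # -- gate kinetics (standard human-atrial formulations) ---------------

    @staticmethod
    def _gates_inf_tau(v: float):
        exp = math.exp
        # fast sodium
        dv = v + 47.13
        if abs(dv) < 1e-7:
            am = 3.2
        else:
            am = 0.32 * dv / (1.0 - exp(-0.1 * dv))
        bm = 0.08 * exp(-v / 11.0)
        if v < -40.0:
            ah = 0.135 * exp(-(v + 80.0) / 6.8)
            bh = 3.56 * exp(0.079 * v) + 3.1e5 * exp(0.35 * v)
            aj = ((-1.2714e5 * exp(0.2444 * v) - 3.474e-5 * exp(-0.04391 * v))
                  * (v + 37.78) / (1.0 + exp(0.311 * (v + 79.23))))
            bj = 0.1212 * exp(-0.01052 * v) / (1.0 + exp(-0.1378 * (v + 40.14)))
        else:
            ah = 0.0
            bh = 1.0 / (0.13 * (1.0 + exp(-(v + 10.66) / 11.1)))
            aj = 0.0
            bj = 0.3 * exp(-2.535e-7 * v) / (1.0 + exp(-0.1 * (v + 32.0)))
        # L-type calcium
        d_inf = 1.0 / (1.0 + exp(-(v + 10.0) / 8.0))
        dv10 = v + 10.0
        if abs(dv10) < 1e-7:
            tau_d = 4.579 / (1.0 + exp(-dv10 / 6.24))
        else:
            e1 = exp(-dv10 / 6.24)
            tau_d = (1.0 - e1) / (0.035 * dv10 * (1.0 + e1))
        f_inf = 1.0 / (1.0 + exp((v + 28.0) / 6.9))
        tau_f = 9.0 / (0.0197 * exp(-(0.0337 ** 2) * dv10 * dv10) + 0.02)
        # rapid delayed rectifier
        dv141 = v + 14.1
        if abs(dv141) < 1e-7:
            axr = 0.0015
        else:
            axr = 0.0003 * dv141 / (1.0 - exp(-dv141 / 5.0))
        dv33 = v - 3.3328
        if abs(dv33) < 1e-7:
            bxr = 3.7836e-4
        else:
            bxr = 7.3898e-5 * dv33 / (exp(dv33 / 5.1237) - 1.0)
        tau_xr = 1.0 / (axr + bxr)
        xr_inf = 1.0 / (1.0 + exp(-dv141 / 6.5))
        # slow delayed rectifier
        dv199 = v - 19.9
        if abs(dv199) < 1e-7:
            axs = 6.8e-4
            bxs = 3.15e-4
        else:
            axs = 4e-5 * dv199 / (1.0 - exp(-dv199 / 17.0))
            bxs = 3.5e-5 * dv199 / (exp(dv199 / 9.0) - 1.0)
        tau_xs = 0.5 / (axs + bxs)
        xs_inf = 1.0 / math.sqrt(1.0 + exp(-dv199 / 12.7))
        # ultrarapid potassium
        aua = 0.65 / (exp(-(v + 10.0) / 8.5) + exp(-(v - 30.0) / 59.0))
        bua = 0.65 / (2.5 + exp((v + 82.0) / 17.0))
        tau_ua = 1.0 / (3.0 * (aua + bua))
        ua_inf = 1.0 / (1.0 + exp(-(v + 30.3) / 9.6))
        aui = 1.0 / (21.0 + exp(-(v - 185.0) / 28.0))
        bui = exp((v - 158.0) / 16.0)
        tau_ui = 1.0 / (3.0 * (aui + bui))
        ui_inf = 1.0 / (1.0 + exp((v - 99.45) / 27.48))
        return (am, bm, ah, bh, aj, bj, d_inf, tau_d, f_inf, tau_f,
                xr_inf, tau_xr, xs_inf, tau_xs,
                ua_inf, tau_ua, ui_inf, tau_ui)

    # -- currents ----------------------------------------------------------

    def currents(self, v: float, y: Sequence[float], ito: ItoParams) -> dict:
        """Instantaneous current densities, pA/pF (diagnostic helper)."""
        _, m, h, j, d, f, xr, xs, ua, ui, a, ii = y
        exp = math.exp
        i_na = self.g_na * m ** 3 * h * j * (v - E_NA)
        i_cal = self.g_cal * d * f * self.f_ca * (v - self.e_ca_eff)
        i_k1 = self.g_k1 * (v - E_K) / (1.0 + exp(0.07 * (v + 80.0)))
        i_kr = self.g_kr * xr * (v - E_K) / (1.0 + exp((v + 15.0) / 22.4))
        i_ks = self.g_ks * xs * xs * (v - E_K)
        g_kur = self.g_kur_scale * (0.005 + 0.05 / (1.0 + exp(-(v - 15.0) / 13.0)))
        i_kur = g_kur * ua ** 3 * ui * (v - E_K)
        i_to = ito.g_to * a * ii * (v - E_K)
        i_b_na = self.g_b_na * (v - E_NA)
        return {"i_na": i_na, "i_cal": i_cal, "i_k1": i_k1, "i_kr": i_kr,
                "i_ks": i_ks, "i_kur": i_kur, "i_to": i_to, "i_b_na": i_b_na}

    def rhs(self, t: float, y: np.ndarray, ito: ItoParams,
            stim_pa_pf: float) -> list[float]:
        v, m, h, j, d, f, xr, xs, ua, ui, a, ii = y
        exp = math.exp
        (am, bm, ah, bh, aj, bj, d_inf, tau_d, f_inf, tau_f,
         xr_inf, tau_xr, xs_inf, tau_xs,
         ua_inf, tau_ua, ui_inf, tau_ui) = self._gates_inf_tau(v)

        i_na = self.g_na * m ** 3 * h * j * (v - E_NA)
        i_cal = self.g_cal * d * f * self.f_ca * (v - self.e_ca_eff)
        i_k1 = self.g_k1 * (v - E_K) / (1.0 + exp(0.07 * (v + 80.0)))
        i_kr = self.g_kr * xr * (v - E_K) / (1.0 + exp((v + 15.0) / 22.4))
        i_ks = self.g_ks * xs * xs * (v - E_K)
        g_kur = self.g_kur_scale * (0.005 + 0.05 / (1.0 + exp(-(v - 15.0) / 13.0)))
        i_kur = g_kur * ua ** 3 * ui * (v - E_K)
        i_to = ito.g_to * a * ii * (v - E_K)
        i_b_na = self.g_b_na * (v - E_NA)

        i_ion = (i_na + i_cal + i_k1 + i_kr + i_ks + i_kur + i_to + i_b_na)

        a_inf = 1.0 / (1.0 + exp((ito.act_vhalf - v) / ito.act_k))
        i_inf = 1.0 / (1.0 + exp((v - ito.inact_vhalf) / ito.inact_k))
        tau_a = ito.tau_act_ms
        tau_i = float(ito.tau_i(v))

        return [
            -(i_ion + stim_pa_pf),
            am * (1.0 - m) - bm * m,
            ah * (1.0 - h) - bh * h,
            aj * (1.0 - j) - bj * j,
            (d_inf - d) / tau_d,
            (f_inf - f) / tau_f,
            (xr_inf - xr) / tau_xr,
            (xs_inf - xs) / tau_xs,
            (ua_inf - ua) / tau_ua,
            (ui_inf - ui) / tau_ui,
            (a_inf - a) / tau_a,
            (i_inf - ii) / tau_i,
        ]

    def steady_gates(self, v: float, ito: ItoParams) -> list[float]:
        (am, bm, ah, bh, aj, bj, d_inf, _, f_inf, _, xr_inf, _,
         xs_inf, _, ua_inf, _, ui_inf, _) = self._gates_inf_tau(v)
        a_inf = 1.0 / (1.0 + math.exp((ito.act_vhalf - v) / ito.act_k))
        i_inf = 1.0 / (1.0 + math.exp((v - ito.inact_vhalf) / ito.inact_k))
        return [am / (am + bm), ah / (ah + bh), aj / (aj + bj),
                d_inf, f_inf, xr_inf, xs_inf, ua_inf, ui_inf, a_inf, i_inf]

    def initial_state(self, ito: ItoParams, v0: float | None = None) -> np.ndarray:
        """State at the model's rest: V where the steady-state I-V is zero."""
        if v0 is None:
            from scipy.optimize import brentq

            def net(v):
                y = [v] + self.steady_gates(v, ito)
                return sum(self.currents(v, y, ito).values())

            v0 = brentq(net, -95.0, -55.0, xtol=1e-10)
        return np.array([v0] + self.steady_gates(v0, ito))


def ap_ito_params(genotype: str, config: APModelConfig) -> ItoParams:
    """Ito parameterization for the AP model arm of a genotype.

    Kinetics come from the clamp characterization of the genotype; the
    conductance is the myocyte-level wild-type value scaled by
    ``ito_scale`` and ``density_scale`` (set ito_scale=1.5 for the mutant
    arm's increased expression), and the reversal potential is the
    myocyte EK at 37 degC.
    """
    base = make_genotype_params(genotype)
    return base.with_(g_to=GTO_AP_WT * config.ito_scale * config.density_scale,
                      e_rev=E_K)


# ---------------------------------------------------------------------------
# APD90 measurement
# ---------------------------------------------------------------------------

def compute_apd90(time_ms: np.ndarray, vm_mv: np.ndarray,
                  stim_times_ms: Sequence[float],
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-beat APD90 from a voltage trace.

    For each stimulus: amplitude = peak Vm - pre-stimulus Vm; APD90 runs
    from the time of maximum upstroke velocity to the first subsequent
    downward crossing of (peak - 0.9*amplitude), linearly interpolated.
    Returns (apd90, captured, repolarized); apd90 is NaN where the beat
    failed to capture (no upstroke past -40 mV) or to repolarize before the
    next stimulus.
    """
    time_ms = np.asarray(time_ms, dtype=float)
    vm_mv = np.asarray(vm_mv, dtype=float)
    stim_times_ms = list(stim_times_ms)
    if len(stim_times_ms) == 0:
        raise ValueError("at least one stimulus time required")
    edges = stim_times_ms + [time_ms[-1] + 1e-9]

    apd = np.full(len(stim_times_ms), np.nan)
    captured = np.zeros(len(stim_times_ms), dtype=bool)
    repolarized = np.zeros(len(stim_times_ms), dtype=bool)
    for b, (t0, t1) in enumerate(zip(edges[:-1], edges[1:])):
        sel = (time_ms >= t0) & (time_ms < t1)
        if sel.sum() < 4:
            continue
        t = time_ms[sel]
        v = vm_mv[sel]
        pre_idx = np.searchsorted(time_ms, t0) - 1
        v_pre = vm_mv[max(pre_idx, 0)]
        pk = int(np.argmax(v))
        v_peak = v[pk]
        amplitude = v_peak - v_pre
        if v_peak < -40.0 or amplitude <= 0:
            continue  # no upstroke: flagged by captured=False
        captured[b] = True
        # onset: maximum upstroke velocity up to (and including) the peak
        dvdt = np.gradient(v[:pk + 1], t[:pk + 1]) if pk >= 1 else np.array([0.0])
        t_up = t[int(np.argmax(dvdt))]
        level = v_peak - 0.9 * amplitude
        below = np.nonzero(v[pk:] <= level)[0]
        if len(below) == 0:
            continue  # not repolarized before next stimulus: flagged
        ic = pk + below[0]
        if ic == pk:
            t_cross = t[ic]
        else:
            f = (level - v[ic - 1]) / (v[ic] - v[ic - 1])
            t_cross = t[ic - 1] + f * (t[ic] - t[ic - 1])
        repolarized[b] = True
        apd[b] = t_cross - t_up
    return apd, captured, repolarized


# ---------------------------------------------------------------------------
# Paced simulation
# ---------------------------------------------------------------------------

def run_paced_simulation(config: APModelConfig, ito: ItoParams,
                         cell: AtrialCellModel | None = None) -> APResult:
    """Pace the cell for ``config.n_beats`` at ``config.bcl_ms``.

    The run starts from the model's rest after an unpaced equilibration;
    each beat is integrated in two smooth segments (stimulus on / off).
    Capture or repolarization failures are flagged per beat in the result,
    never silently dropped.
    """
    if cell is None:
        cell = AtrialCellModel()
    y0 = cell.initial_state(ito)
    solver_kw = dict(method=config.method, rtol=config.rtol, atol=config.atol)
    if math.isfinite(config.max_step_ms):
        solver_kw["max_step"] = config.max_step_ms

    def integrate(y, t_span, stim, t_eval=None):
        sol = solve_ivp(lambda t, yy: cell.rhs(t, yy, ito, stim),
                        t_span, y, t_eval=t_eval, **solver_kw)
        if not sol.success:
            raise RuntimeError(f"integration failed: {sol.message}")
        return sol

    # unpaced equilibration
    if config.equilibration_ms > 0:
        sol = integrate(y0, (0.0, config.equilibration_ms), 0.0)
        y0 = sol.y[:, -1]
    resting_vm = float(y0[0])

    bcl = config.bcl_ms
    sd = config.stim_duration_ms
    ts_all: list[np.ndarray] = []
    vs_all: list[np.ndarray] = []
    ys_last: list[np.ndarray] = []
    y = y0
    for beat in range(config.n_beats):
        t0 = beat * bcl
        grid1 = np.arange(t0, t0 + sd, config.sample_ms)
        sol1 = integrate(y, (t0, t0 + sd), config.stim_amplitude_pa_pf,
                         t_eval=np.append(grid1, t0 + sd))
        y = sol1.y[:, -1]
        grid2 = np.arange(t0 + sd, t0 + bcl, config.sample_ms)
        sol2 = integrate(y, (t0 + sd, t0 + bcl), 0.0,
                         t_eval=np.append(grid2, t0 + bcl))
        y = sol2.y[:, -1]
        ts_all.append(np.concatenate([sol1.t[:-1], sol2.t[:-1]]))
        vs_all.append(np.concatenate([sol1.y[0, :-1], sol2.y[0, :-1]]))
        if beat >= config.n_beats - 2:
            ys_last.append(np.concatenate([sol1.y[:, :-1], sol2.y[:, :-1]],
                                          axis=1))

    t_full = np.concatenate(ts_all)
    v_full = np.concatenate(vs_all)
    stim_times = [k * bcl for k in range(config.n_beats)]
    apd, captured, repolarized = compute_apd90(t_full, v_full, stim_times)

    y_last = np.concatenate(ys_last, axis=1)
    n_last = y_last.shape[1]
    t_last = t_full[-n_last:] - t_full[-n_last]
    ito_trace = (ito.g_to * y_last[10] * y_last[11] * (y_last[0] - E_K))

    return APResult(
        genotype=ito.genotype, bcl_ms=bcl,
        time_ms=t_last, vm_mv=y_last[0], ito_pa_pf=ito_trace,
        apd90_ms=apd, captured=captured, repolarized=repolarized,
        resting_vm_mv=resting_vm, peak_vm_mv=float(v_full.max()))


def rate_adaptation(config: APModelConfig, ito: ItoParams,
                    bcls_ms: Sequence[float] = DEFAULT_BCLS_MS,
                    cell: AtrialCellModel | None = None) -> pd.DataFrame:
    """APD90 at the final beat for each BCL (independent paced runs).

    Rows with capture/repolarization failures carry NaN APD90 and
    ``flagged=True``.
    """
    if len(bcls_ms) == 0:
        raise ValueError("bcls_ms must be non-empty")
    rows = []
    for bcl in bcls_ms:
        res = run_paced_simulation(replace(config, bcl_ms=float(bcl)), ito,
                                   cell=cell)
        ok = bool(res.captured[-1] and res.repolarized[-1])
        rows.append({"bcl_ms": float(bcl), "apd90_ms": res.apd90_final_ms,
                     "flagged": not ok})
    return pd.DataFrame(rows)


def compare_wt_mutant(config: APModelConfig,
                      bcls_ms: Sequence[float] = DEFAULT_BCLS_MS,
                      cell: AtrialCellModel | None = None) -> dict:
    """Paired WT / T361S runs with identical solver settings.

    The WT arm uses the wild-type kinetics at the baseline conductance; the
    mutant arm uses the T361S kinetics with conductance scaled by
    ``config.ito_scale`` (default 1.5, the measured expression increase)
    and ``config.density_scale``.
    Returns rate-adaptation tables, per-BCL APD90 differences, and the AP +
    Ito traces of the final beats at the first BCL.
    """
    wt_cfg = replace(config, ito_scale=1.0, density_scale=1.0)
    mut_cfg = config
    wt_ito = ap_ito_params("WT", wt_cfg)
    mut_ito = ap_ito_params("T361S", mut_cfg)

    wt_table = rate_adaptation(wt_cfg, wt_ito, bcls_ms, cell=cell)
    mut_table = rate_adaptation(mut_cfg, mut_ito, bcls_ms, cell=cell)

    delta = mut_table["apd90_ms"] - wt_table["apd90_ms"]
    comparison = pd.DataFrame({
        "bcl_ms": wt_table["bcl_ms"],
        "apd90_wt_ms": wt_table["apd90_ms"],
        "apd90_t361s_ms": mut_table["apd90_ms"],
        "delta_apd90_ms": delta,
        "delta_apd90_frac": delta / wt_table["apd90_ms"],
        "flagged": wt_table["flagged"] | mut_table["flagged"],
    })

    first_bcl = float(bcls_ms[0])
    wt_trace = run_paced_simulation(
        replace(wt_cfg, bcl_ms=first_bcl), wt_ito, cell=cell)
    mut_trace = run_paced_simulation(
        replace(mut_cfg, bcl_ms=first_bcl), mut_ito, cell=cell)
    return {"comparison": comparison, "wt": wt_trace, "mutant": mut_trace}
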