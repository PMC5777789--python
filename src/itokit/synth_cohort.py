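"""Synthetic multi-cell patch-clamp cohorts for the Ito analysis pipeline.

No recordings from the original HEK293 experiments are deposited anywhere,
so this module generates surrogate cohorts with the statistical structure
the analysis assumes: per-cell kinetic parameters drawn around the
genotype's group means with dispersion matched to the printed SEMs
(sd = SEM * sqrt(n)), a lognormal capacitance spread, and additive Gaussian
recording noise.  All three experimental protocols are emulated:

* activation — 500 ms steps from -80 mV to -40 ... +60 mV (10 mV steps);
* steady-state inactivation — 1000 ms prepulses -100 ... 0 mV followed by a
  300 ms test pulse to +60 mV;
* recovery from inactivation — double pulse: P1 +60 mV 500 ms, gap at
  -80 mV of 2 ... 500 ms, P2 +60 mV 200 ms.

Every sweep begins with 50 ms at the holding potential so the analysis has
a pre-step baseline window.  Cohorts round-trip losslessly through a plain
text directory layout (CSV sweeps + YAML sidecars); the generating ground
truth is kept in a separate sidecar so fitting can be run blind.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ito_model import (
    GENOTYPE_KINETICS,
    G_TO_WT_DEFAULT,
    ItoParams,
    ProtocolDefinition,
    SweepRecording,
    make_genotype_params,
    simulate_voltage_clamp,
)

__all__ = [
    "PRE_STEP_HOLD_MS",
    "RECOVERY_GAPS_MS",
    "PRINTED_GROUP_STATS",
    "VariabilityConfig",
    "CellRecord",
    "default_protocols",
    "default_variability",
    "calibrate_g_to",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "CohortIOError",
]

#: Holding-potential settle time recorded at the start of every sweep, ms.
PRE_STEP_HOLD_MS = 50.0

#: Recovery-protocol gap durations at the holding potential, ms.
RECOVERY_GAPS_MS = (2.0, 5.0, 10.0, 20.0, 50.0, 100.0, 200.0, 350.0, 500.0)

#: Group statistics as printed: mean, SEM and n per genotype; the source of
#: the cohort dispersion targets (sd = SEM * sqrt(n)).
PRINTED_GROUP_STATS: dict[str, dict[str, tuple[float, float, int]]] = {
    "WT": {
        "act_vhalf": (-13.69, 1.48, 15),
        "act_k": (11.35, 0.77, 15),
        "inact_vhalf": (-41.16, 0.47, 17),
        "inact_k": (5.37, 0.39, 17),
        "tau_rec_ms": (27.33, 2.80, 15),
        "density_60": (557.9, 40.61, 15),
    },
    "T361S": {
        "act_vhalf": (-22.98, 0.75, 17),
        "act_k": (9.67, 0.39, 17),
        "inact_vhalf": (-54.30, 1.25, 18),
        "inact_k": (8.56, 0.36, 18),
        "tau_rec_ms": (81.17, 10.18, 17),
        "density_60": (807.79, 80.99, 17),
    },
}


def default_protocols() -> dict[str, ProtocolDefinition]:
    """The three voltage-clamp protocols used throughout the study.

    Step ranges bracket both genotypes' half-(in)activation voltages with
    at least three points on each Boltzmann shoulder.
    """
    hold = -80.0
    act_steps = tuple(float(v) for v in range(-40, 61, 10))
    activation = ProtocolDefinition(
        name="activation",
        sweeps=tuple(((hold, PRE_STEP_HOLD_MS), (v, 500.0))
                     for v in act_steps),
        step_values=act_steps,
        holding_mv=hold,
    )
    pre_steps = tuple(float(v) for v in range(-100, 1, 10))
    inactivation = ProtocolDefinition(
        name="inactivation",
        sweeps=tuple(((hold, PRE_STEP_HOLD_MS), (v, 1000.0), (60.0, 300.0))
                     for v in pre_steps),
        step_values=pre_steps,
        holding_mv=hold,
    )
    recovery = ProtocolDefinition(
        name="recovery",
        sweeps=tuple(((hold, PRE_STEP_HOLD_MS), (60.0, 500.0),
                      (hold, gap), (60.0, 200.0))
                     for gap in RECOVERY_GAPS_MS),
        step_values=RECOVERY_GAPS_MS,
        holding_mv=hold,
    )
    return {"activation": activation, "inactivation": inactivation,
            "recovery": recovery}


@dataclass(frozen=True)
class VariabilityConfig:
    """Cell-to-cell dispersion and recording-noise settings for one genotype.

    Parameter sds target the printed SEMs at the printed n; g_to_cv targets
    the printed density SEM.  ``parameter_scale`` / ``noise_scale`` multiply
    every sd (0 turns variability / noise off entirely, giving a cohort of
    identical, noiseless cells).
    """

    act_vhalf_sd: float
    act_k_sd: float
    inact_vhalf_sd: float
    inact_k_sd: float
    tau_rec_sd: float
    g_to_cv: float
    cap_median_pf: float = 12.0
    cap_gsd: float = 1.3
    noise_frac: float = 0.01       # noise sd as a fraction of peak current
    noise_floor_pa: float = 5.0
    parameter_scale: float = 1.0
    noise_scale: float = 1.0

    def silenced(self) -> "VariabilityConfig":
        """Copy with variability and noise off (identical noiseless cells)."""
        return replace(self, parameter_scale=0.0, noise_scale=0.0)


def default_variability(genotype: str) -> VariabilityConfig:
    """Dispersion calibrated so group SEMs at the printed n match print."""
    stats = PRINTED_GROUP_STATS[genotype]

    def sd(key: str) -> float:
        _, sem, n = stats[key]
        return sem * math.sqrt(n)

    dens_mean, dens_sem, dens_n = stats["density_60"]
    return VariabilityConfig(
        act_vhalf_sd=sd("act_vhalf"),
        act_k_sd=sd("act_k"),
        inact_vhalf_sd=sd("inact_vhalf"),
        inact_k_sd=sd("inact_k"),
        tau_rec_sd=sd("tau_rec_ms"),
        g_to_cv=dens_sem * math.sqrt(dens_n) / dens_mean,
    )


@dataclass
class CellRecord:
    """One synthetic cell: metadata, ground truth, and its recorded sweeps."""

    cell_id: str
    genotype: str
    capacitance_pf: float
    true_params: ItoParams | None
    sweeps: list[SweepRecording] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.capacitance_pf <= 0:
            raise ValueError("capacitance must be positive")

    def sweeps_for(self, protocol_name: str) -> list[SweepRecording]:
        out = [s for s in self.sweeps if s.protocol_name == protocol_name]
        return sorted(out, key=lambda s: s.step_index)


def calibrate_g_to(target_density_pa_pf: float = 557.9,
                   genotype: str = "WT") -> float:
    """Conductance (nS/pF) giving the target noise-free peak density at +60 mV.

    Peak current is linear in g_to, so a single unit-conductance simulation
    of the +60 mV activation sweep, measured exactly as the analysis stage
    measures it, fixes the scale.  The shipped ``G_TO_WT_DEFAULT`` was
    frozen from this calibration.
    """
    from .ephys_fit import ANALYSIS_SMOOTH_MS, peak_current

    p = make_genotype_params(genotype).with_(g_to=1.0)
    proto = default_protocols()["activation"]
    top = ProtocolDefinition(
        name="activation", sweeps=(proto.sweeps[-1],),
        step_values=(proto.step_values[-1],), holding_mv=proto.holding_mv)
    sweep = simulate_voltage_clamp(p, top)[0]
    peak = peak_current(sweep, (PRE_STEP_HOLD_MS, sweep.time_ms[-1]),
                        smooth_ms=ANALYSIS_SMOOTH_MS)
    return target_density_pa_pf / peak


def _draw_cell_params(genotype: str, var: VariabilityConfig,
                      rng: np.random.Generator) -> ItoParams:
    base = make_genotype_params(genotype)
    s = var.parameter_scale
    if s == 0.0:
        return base
    act_vhalf = base.act_vhalf + s * var.act_vhalf_sd * rng.standard_normal()
    act_k = max(1.0, base.act_k + s * var.act_k_sd * rng.standard_normal())
    inact_vhalf = base.inact_vhalf + s * var.inact_vhalf_sd * rng.standard_normal()
    inact_k = max(1.0, base.inact_k + s * var.inact_k_sd * rng.standard_normal())
    tau_rec = max(2.0, base.tau_rec_ms + s * var.tau_rec_sd * rng.standard_normal())
    g_to = base.g_to * max(0.05, 1.0 + s * var.g_to_cv * rng.standard_normal())
    return base.with_(act_vhalf=act_vhalf, act_k=act_k,
                      inact_vhalf=inact_vhalf, inact_k=inact_k,
                      tau_rec_ms=tau_rec, g_to=g_to)


def generate_cohort(genotype: str, n_cells: int, seed: int,
                    variability: VariabilityConfig | None = None,
                    protocols: dict[str, ProtocolDefinition] | None = None,
                    ) -> list[CellRecord]:
    """Generate ``n_cells`` synthetic cells of one genotype.

    Deterministic: the same (genotype, n_cells, seed, config) produces a
    bit-identical cohort.  Per-cell random substreams are spawned from the
    master seed, so cohorts of different sizes share their leading cells.
    """
    if genotype not in GENOTYPE_KINETICS:
        raise ValueError(f"unknown genotype {genotype!r}")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if variability is None:
        variability = default_variability(genotype)
    if protocols is None:
        protocols = default_protocols()

    master = np.random.SeedSequence([seed, 0 if genotype == "WT" else 1])
    children = master.spawn(n_cells)
    cohort: list[CellRecord] = []
    for idx, child in enumerate(children):
        rng = np.random.default_rng(child)
        cap = variability.cap_median_pf * math.exp(
            math.log(variability.cap_gsd) * rng.standard_normal())
        params = _draw_cell_params(genotype, variability, rng)
        sweeps: list[SweepRecording] = []
        for name in ("activation", "inactivation", "recovery"):
            sweeps.extend(simulate_voltage_clamp(
                params, protocols[name], capacitance_pf=cap))
        if variability.noise_scale > 0.0:
            peak = max(np.max(np.abs(s.current_pa))
                       for s in sweeps if s.protocol_name == "activation")
            sd = variability.noise_scale * max(
                variability.noise_frac * peak, variability.noise_floor_pa)
            for s in sweeps:
                s.current_pa = s.current_pa + sd * rng.standard_normal(
                    s.current_pa.shape)
        cohort.append(CellRecord(
            cell_id=f"{genotype}_{idx:03d}", genotype=genotype,
            capacitance_pf=cap, true_params=params, sweeps=sweeps))
    return cohort


# ---------------------------------------------------------------------------
# On-disk layout (plain text):
#   <dir>/cohort.yaml                      genotype, cells, protocol table
#   <dir>/cells/<cell_id>/cell.yaml        metadata + sweep manifest
#   <dir>/cells/<cell_id>/truth.yaml       ground-truth params (sidecar)
#   <dir>/cells/<cell_id>/<proto>_<k>.csv  time_ms,current_pa
# ---------------------------------------------------------------------------

class CohortIOError(RuntimeError):
    """Malformed or incomplete cohort directory."""


def _protocol_to_dict(p: ProtocolDefinition) -> dict:
    return {
        "name": p.name,
        "holding_mv": p.holding_mv,
        "inter_sweep_interval_ms": p.inter_sweep_interval_ms,
        "sample_rate_hz": p.sample_rate_hz,
        "step_values": list(p.step_values),
        "sweeps": [[[v, d] for v, d in sweep] for sweep in p.sweeps],
    }


def _protocol_from_dict(d: dict) -> ProtocolDefinition:
    return ProtocolDefinition(
        name=d["name"], holding_mv=d["holding_mv"],
        inter_sweep_interval_ms=d["inter_sweep_interval_ms"],
        sample_rate_hz=d["sample_rate_hz"],
        step_values=tuple(float(v) for v in d["step_values"]),
        sweeps=tuple(tuple((float(v), float(dur)) for v, dur in sweep)
                     for sweep in d["sweeps"]))


def write_cohort(cohort: list[CellRecord], directory: str | Path,
                 protocols: dict[str, ProtocolDefinition] | None = None,
                 ) -> Path:
    """Write a cohort as plain-text files; returns the directory path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if protocols is None:
        protocols = default_protocols()
    genotypes = sorted({c.genotype for c in cohort})
    meta = {
        "format": "itokit-cohort/1",
        "genotype": genotypes[0] if len(genotypes) == 1 else genotypes,
        "n_cells": len(cohort),
        "cell_ids": [c.cell_id for c in cohort],
        "protocols": {k: _protocol_to_dict(v) for k, v in protocols.items()},
    }
    (directory / "cohort.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
    cells_dir = directory / "cells"
    for cell in cohort:
        cdir = cells_dir / cell.cell_id
        cdir.mkdir(parents=True, exist_ok=True)
        manifest = []
        for s in cell.sweeps:
            fname = f"{s.protocol_name}_{s.step_index:02d}.csv"
            pd.DataFrame({"time_ms": s.time_ms, "current_pa": s.current_pa}
                         ).to_csv(cdir / fname, index=False,
                                  float_format="%.17g")
            manifest.append({"file": fname, "protocol": s.protocol_name,
                             "step_index": s.step_index,
                             "step_voltage_mv": s.step_voltage_mv})
        (cdir / "cell.yaml").write_text(yaml.safe_dump({
            "cell_id": cell.cell_id, "genotype": cell.genotype,
            "capacitance_pf": cell.capacitance_pf, "sweeps": manifest},
            sort_keys=False))
        if cell.true_params is not None:
            (cdir / "truth.yaml").write_text(
                yaml.safe_dump(cell.true_params.to_dict(), sort_keys=False))
    return directory


def read_cohort(directory: str | Path, with_truth: bool = True,
                ) -> tuple[list[CellRecord], dict[str, ProtocolDefinition]]:
    """Read a cohort directory; returns (cells, protocols).

    With ``with_truth=False`` the ground-truth sidecars are ignored, so the
    fitting stage can run blind.
    """
    directory = Path(directory)
    meta_path = directory / "cohort.yaml"
    if not meta_path.is_file():
        raise CohortIOError(f"{meta_path}: cohort metadata sidecar missing")
    try:
        meta = yaml.safe_load(meta_path.read_text())
    except yaml.YAMLError as exc:
        raise CohortIOError(f"{meta_path}: malformed YAML ({exc})") from exc
    if not isinstance(meta, dict) or meta.get("format") != "itokit-cohort/1":
        raise CohortIOError(f"{meta_path}: not an itokit cohort (bad format tag)")
    protocols = {k: _protocol_from_dict(v)
                 for k, v in meta.get("protocols", {}).items()}

    cells: list[CellRecord] = []
    for cell_id in meta.get("cell_ids", []):
        cdir = directory / "cells" / cell_id
        cell_meta_path = cdir / "cell.yaml"
        if not cell_meta_path.is_file():
            raise CohortIOError(f"{cell_meta_path}: cell metadata missing")
        cmeta = yaml.safe_load(cell_meta_path.read_text())
        truth = None
        if with_truth:
            tpath = cdir / "truth.yaml"
            if tpath.is_file():
                truth = ItoParams.from_dict(yaml.safe_load(tpath.read_text()))
        sweeps = []
        for entry in cmeta["sweeps"]:
            fpath = cdir / entry["file"]
            if not fpath.is_file():
                raise CohortIOError(f"{fpath}: sweep file missing")
            try:
                df = pd.read_csv(fpath, float_precision="round_trip")
                sweeps.append(SweepRecording(
                    protocol_name=entry["protocol"],
                    step_index=int(entry["step_index"]),
                    step_voltage_mv=float(entry["step_voltage_mv"]),
                    time_ms=df["time_ms"].to_numpy(),
                    current_pa=df["current_pa"].to_numpy()))
            except (KeyError, ValueError) as exc:
                raise CohortIOError(f"{fpath}: malformed sweep ({exc})") from exc
        cells.append(CellRecord(
            cell_id=cmeta["cell_id"], genotype=cmeta["genotype"],
            capacitance_pf=float(cmeta["capacitance_pf"]),
            true_params=truth, sweeps=sweeps))
    return cells, protocols
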