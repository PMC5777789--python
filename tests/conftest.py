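"""Shared fixtures: noise-free reference cells and small cohorts.

Everything is generated programmatically at test time; session scope keeps
the voltage-clamp simulations (the slowest shared ingredient) to one run.
"""

from __future__ import annotations

import pytest

from itokit.ephys_fit import analyze_cell
from itokit.ito_model import make_genotype_params, simulate_voltage_clamp
from itokit.synth_cohort import CellRecord, default_protocols

GENOTYPES = ("WT", "T361S")


@pytest.fixture(scope="session")
def protocols():
    return default_protocols()


def _noisefree_cell(genotype: str, protocols) -> CellRecord:
    params = make_genotype_params(genotype)
    sweeps = []
    for name in ("activation", "inactivation", "recovery"):
        sweeps.extend(simulate_voltage_clamp(params, protocols[name],
                                             capacitance_pf=12.0))
    return CellRecord(cell_id=f"{genotype}_ref", genotype=genotype,
                      capacitance_pf=12.0, true_params=params, sweeps=sweeps)


@pytest.fixture(scope="session")
def noisefree_cells(protocols):
    """One noiseless, variability-free cell per genotype (ground truth = printed params)."""
    return {g: _noisefree_cell(g, protocols) for g in GENOTYPES}


@pytest.fixture(scope="session")
def noisefree_fits(noisefree_cells):
    """Full single-cell analysis of the noise-free reference cells."""
    return {g: analyze_cell(c) for g, c in noisefree_cells.items()}
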