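"""Machine-readable report tables for presets × scenarios.

Builds the standard summary tables of a model run: per-case cell-type
output tables, α feasibility scans, and matching (γ/η) matrices.  All
tables are deterministic: fixed row order, fixed column order and fixed
float formatting, so identical configurations produce byte-identical
CSV files.  Each derived column is written at 4 decimals next to a
2-decimal rounded column for quick comparison.
"""

from __future__ import annotations

from dataclasses import replace

import pandas as pd

from .balance_matching import MatchResult, solve_eta_double, solve_gamma, solve_triple
from .cell_type_solver import alpha_feasibility_scan, solve_cell_fluxes
from .core_params import ParameterPreset
from .demand_stoichiometry import DOUBLE_MIXES, DemandScenario, Subtype
from .leaf_optics import absorption_cascade
from .whole_leaf_energetics import scenario_budget

__all__ = [
    "celltype_table",
    "scan_table",
    "matching_table",
    "format_table",
]

# row label -> record key, in fixed display order
_CELLTYPE_ROWS = [
    ("BS:M absorptance ratio (a_BS:a_M)", "ratio_BS_M"),
    ("PSI_CET:PSII ratio (Cx:T)", "Cx_T"),
    ("Fraction of Cx in BS cells (beta)", "beta"),
    ("BS:M photosystem ratio", "photosys_BS_M"),
    ("BS:M absorptance ratio per photosystem (k_BS:k_M)", "k_BS_k_M"),
    ("Whole-leaf PSI:PSII ratio", "psi_psii_leaf"),
    ("PSI:PSII ratio in BS cells", "psi_psii_BS"),
    ("PSI:PSII ratio in M cells", "psi_psii_M"),
    ("Fraction of M-absorbed light that drives LET (u)", "u"),
    ("Fraction of BS-absorbed light that drives LET (v)", "v"),
    ("Whole-leaf f_CET", "f_CET"),
    ("f_CET in BS cells", "f_CET_BS"),
    ("f_CET in M cells", "f_CET_M"),
    ("BS:M total electron flux ratio", "e_flux_BS_M"),
    ("CET_BS:(CET_BS+CET_M)", "cet_share_BS"),
    ("Fraction of NADPH produced in BS cells (f_nadph_BS)", "f_nadph_BS"),
    ("Fraction of ATP produced in BS cells (f_atp_BS)", "f_atp_BS"),
    ("Fraction of total BS ATP that is from CET", "atp_BS_from_CET"),
    ("Fraction of ATP that is from LET", "frac_atp_LET"),
    ("Phi_CO2 (mol mol-1)", "Phi_CO2"),
]


def _case_record(preset: ParameterPreset, scenario: DemandScenario) -> dict[str, float]:
    budget = scenario_budget(scenario, preset.efficiency)
    optics = absorption_cascade(preset.leaf)
    sol = solve_cell_fluxes(budget, optics, preset.photosystems, preset.efficiency)
    rec = sol.as_record()
    rec["ratio_BS_M"] = optics.ratio_BS_M
    rec["f_CET"] = budget.f_CET
    rec["frac_atp_LET"] = budget.frac_atp_LET
    rec["Phi_CO2"] = budget.Phi_CO2
    return rec


def celltype_table(
    presets: list[ParameterPreset], scenario: DemandScenario
) -> pd.DataFrame:
    """Cell-type output table: one column per preset, fixed row order."""
    data = {}
    for preset in presets:
        rec = _case_record(preset, scenario)
        data[preset.name] = [rec[key] for _, key in _CELLTYPE_ROWS]
    return pd.DataFrame(data, index=[label for label, _ in _CELLTYPE_ROWS])


def scan_table(
    preset: ParameterPreset, scenario: DemandScenario, grid_step: float = 0.005
) -> tuple[pd.DataFrame, tuple[float, float] | None]:
    """Per-α scan table plus the feasible interval for one preset."""
    budget = scenario_budget(scenario, preset.efficiency)
    optics = absorption_cascade(preset.leaf)
    scan = alpha_feasibility_scan(
        budget, optics, preset.photosystems.f_bsPSI, preset.efficiency, grid_step
    )
    table = scan.table.copy()
    table.insert(0, "preset", preset.name)
    return table, scan.interval


def matching_table(
    presets: list[ParameterPreset],
    scenario: DemandScenario,
    rho_MDH: float = 0.39,
    include_triple: bool = True,
) -> pd.DataFrame:
    """Matching matrix: production fractions, γ per currency, η per mechanism.

    One column per preset.  The NADP-ME-family subtypes use the NADP-ME
    pure balance for γ; the aspartate–malate and PEP-CK mechanisms are
    solved as secondary routes grafted onto the preset's primary subtype.
    """
    rows = [
        "f_nadph_BS (production)",
        "f_atp_BS (production)",
        "gamma from NADPH",
        "gamma from ATP",
        "eta (aspartate-malate mechanism)",
        "eta (PEP-CK mechanism)",
        "eta1 (triple)",
        "eta2 (triple)",
    ]
    data: dict[str, list[float | None]] = {}
    for preset in presets:
        budget = scenario_budget(scenario, preset.efficiency)
        optics = absorption_cascade(preset.leaf)
        production = solve_cell_fluxes(
            budget, optics, preset.photosystems, preset.efficiency
        )
        base = scenario
        g_n, _ = solve_gamma(scenario.subtype, base, production, "NADPH")
        g_a, _ = solve_gamma(scenario.subtype, base, production, "ATP")
        aspmal = solve_eta_double(Subtype.NADPME_ASPMAL, base, production)
        if scenario.subtype is Subtype.NAD_ME:
            pepck = solve_eta_double(Subtype.NADME_PEPCK, base, production)
        else:
            pepck = solve_eta_double(Subtype.NADPME_PEPCK, base, production)
        col: list[float | None] = [
            production.f_nadph_BS,
            production.f_atp_BS,
            g_n,
            g_a,
            aspmal.eta,
            pepck.eta,
        ]
        if include_triple:
            triple = solve_triple(base, production, rho_MDH)
            col += [triple.eta1, triple.eta2]
        else:
            col += [None, None]
        data[preset.name] = col
    return pd.DataFrame(data, index=rows)


def format_table(table: pd.DataFrame, decimals: int = 4) -> pd.DataFrame:
    """Value table with a side-by-side 2-d.p. rounded block for comparison."""
    numeric = table.select_dtypes("number")
    rounded = numeric.round(2).add_suffix(" (2dp)")
    return pd.concat([table.round(decimals), rounded], axis=1)
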