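"""Demand–supply matching: solving γ, η and (γ, η₁, η₂).

The cell-type solver gives the fractions of whole-leaf NADPH and ATP
*production* in the bundle sheath (f_nadph_BS, f_atp_BS).  The demand
tables give the BS:total *requirement* ratios as functions of γ (the BS
share of 3-PGA reduction) and, for mixed decarboxylation types, η (the
primary-route fraction).  Setting requirement ratio equal to production
fraction gives the value of each unknown that balances supply and
demand in both cell types.

Every requirement ratio is a ratio of quantities affine in the
unknowns, so each matching equation — written as the residual
``BS_requirement − fraction · total_requirement = 0`` — is affine in
(γ, η) with no cross terms.  The solvers therefore evaluate the
residual at the unit corners and solve the resulting linear system
exactly; no iteration is involved.  Out-of-[0, 1] solutions are
first-class diagnostic results, flagged infeasible, never clamped.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .cell_type_solver import CellTypeSolution, solve_cell_fluxes
from .core_params import ParameterPreset
from .demand_stoichiometry import (
    DOUBLE_MIXES,
    DemandScenario,
    Subtype,
    cell_requirements,
)
from .leaf_optics import absorption_cascade
from .whole_leaf_energetics import scenario_budget

__all__ = [
    "MatchResult",
    "solve_gamma",
    "solve_eta_double",
    "solve_triple",
    "self_consistent_match",
    "DegenerateSystemError",
    "NonConvergenceError",
]

Currency = Literal["NADPH", "ATP"]

_RESIDUAL_TOL = 1e-9


class DegenerateSystemError(ValueError):
    """The matching equation does not depend on the unknown(s)."""


class NonConvergenceError(RuntimeError):
    """The self-consistency loop failed to reach its tolerance."""


@dataclass(frozen=True)
class MatchResult:
    """Solved matching unknowns with feasibility diagnosis."""

    gamma_nadph: float | None = None
    gamma_atp: float | None = None
    eta: float | None = None
    eta1: float | None = None
    eta2: float | None = None
    rho_MDH: float | None = None
    iterations: int = 1
    converged: bool = True
    feasible: bool = True
    diagnosis: str = ""
    production_drift: float = 0.0

    def as_record(self) -> dict[str, object]:
        return {
            "gamma_nadph": self.gamma_nadph,
            "gamma_atp": self.gamma_atp,
            "eta": self.eta,
            "eta1": self.eta1,
            "eta2": self.eta2,
            "rho_MDH": self.rho_MDH,
            "iterations": self.iterations,
            "converged": self.converged,
            "feasible": self.feasible,
            "diagnosis": self.diagnosis,
        }


def _residual(scenario: DemandScenario, currency: Currency, fraction: float) -> float:
    """BS requirement minus fraction × total requirement (affine in γ, η)."""
    req = cell_requirements(scenario)
    if currency == "NADPH":
        return req.nadph_BS - fraction * req.nadph_total
    return req.atp_BS - fraction * req.atp_total


def solve_gamma(
    subtype: Subtype,
    scenario: DemandScenario,
    production: CellTypeSolution,
    currency: Currency,
) -> tuple[float, bool]:
    """Solve the affine equation requirement_ratio(γ) = production fraction.

    Returns ``(gamma, feasible)`` where ``feasible`` means γ in [0, 1].

    Raises
    ------
    DegenerateSystemError
        If the requirement ratio does not depend on γ.
    """
    fraction = production.f_nadph_BS if currency == "NADPH" else production.f_atp_BS
    base = replace(scenario, subtype=subtype)
    g0 = _residual(replace(base, gamma=0.0), currency, fraction)
    g1 = _residual(replace(base, gamma=1.0), currency, fraction)
    slope = g1 - g0
    if abs(slope) < 1e-12:
        raise DegenerateSystemError(
            f"{currency} requirement ratio of {subtype.value} does not depend on gamma"
        )
    gamma = -g0 / slope
    return gamma, 0.0 <= gamma <= 1.0


def solve_eta_double(
    mix_subtype: Subtype,
    scenario: DemandScenario,
    production: CellTypeSolution,
) -> MatchResult:
    """Solve γ and η for a double mixed decarboxylation type.

    The γ policy follows which requirement ratio is η-free:

    * NADP-ME + 'aspartate–malate': the ATP ratio is η-free, so γ comes
      from the ATP balance and η from the NADPH balance.
    * NAD-ME + PEP-CK: the NADPH ratio is η-free, so γ comes from the
      NADPH balance and η from the ATP balance.
    * NADP-ME + PEP-CK: both ratios depend on (γ, η); the 2×2 affine
      system is solved simultaneously.
    """
    if mix_subtype not in DOUBLE_MIXES:
        raise ValueError(f"{mix_subtype} is not a double mixed type")
    base = replace(scenario, subtype=mix_subtype, eta=0.0)

    if mix_subtype is Subtype.NADPME_PEPCK:
        gamma, eta = _solve_affine_2x2(
            base, production,
            set_unknowns=lambda sc, g, e: replace(sc, gamma=g, eta=e),
        )
        gamma_nadph = gamma_atp = gamma
    elif mix_subtype is Subtype.NADPME_ASPMAL:
        gamma, _ = solve_gamma(mix_subtype, base, production, "ATP")
        gamma_nadph = gamma_atp = gamma
        eta = _solve_eta_1d(replace(base, gamma=gamma), production, "NADPH")
    else:  # NADME_PEPCK
        gamma, _ = solve_gamma(mix_subtype, base, production, "NADPH")
        gamma_nadph = gamma_atp = gamma
        eta = _solve_eta_1d(replace(base, gamma=gamma), production, "ATP")

    feasible = 0.0 <= eta <= 1.0 and 0.0 <= gamma <= 1.0
    diagnosis = ""
    if eta > 1.0:
        diagnosis = "eta > 1: secondary decarboxylation route impossible for this species"
    elif eta < 0.0:
        diagnosis = "eta < 0: primary route alone already overshoots the balance"
    elif not 0.0 <= gamma <= 1.0:
        diagnosis = f"gamma = {gamma:.3f} outside [0, 1]"
    return MatchResult(
        gamma_nadph=gamma_nadph, gamma_atp=gamma_atp, eta=eta,
        feasible=feasible, diagnosis=diagnosis,
    )


def _solve_eta_1d(
    scenario: DemandScenario, production: CellTypeSolution, currency: Currency
) -> float:
    """Solve the affine η equation at fixed γ."""
    fraction = production.f_nadph_BS if currency == "NADPH" else production.f_atp_BS
    g0 = _residual(replace(scenario, eta=0.0), currency, fraction)
    g1 = _residual(replace(scenario, eta=1.0), currency, fraction)
    slope = g1 - g0
    if abs(slope) < 1e-12:
        raise DegenerateSystemError(
            f"{currency} requirement ratio does not depend on eta"
        )
    return -g0 / slope


def _solve_affine_2x2(scenario, production, set_unknowns):
    """Exact solve of the two affine balance residuals in two unknowns.

    The residuals are affine with no cross terms, so sampling them at
    (0,0), (1,0) and (0,1) determines the full linear system.
    """
    def residuals(g: float, e: float) -> np.ndarray:
        sc = set_unknowns(scenario, g, e)
        return np.array([
            _residual(sc, "NADPH", production.f_nadph_BS),
            _residual(sc, "ATP", production.f_atp_BS),
        ])

    r00 = residuals(0.0, 0.0)
    col_g = residuals(1.0, 0.0) - r00
    col_e = residuals(0.0, 1.0) - r00
    A = np.column_stack([col_g, col_e])
    if abs(np.linalg.det(A)) < 1e-12:
        raise DegenerateSystemError("matching system is singular for these parameters")
    g, e = np.linalg.solve(A, -r00)
    return float(g), float(e)


def solve_triple(
    scenario: DemandScenario,
    production: CellTypeSolution,
    rho_MDH: float = 0.39,
) -> MatchResult:
    """Solve (γ, η₁, η₂) for the triple decarboxylation pathway.

    The two balance equations cannot fix three unknowns, so the BS:M
    NADP-MDH abundance ratio is imposed as the constraint
    η₂ = rho_MDH · η₁, reducing the system to a 2×2 affine solve in
    (γ, η₁).  ``rho_MDH = 0`` recovers the NADP-ME + PEP-CK double mix.
    """
    if rho_MDH < 0.0:
        raise ValueError("rho_MDH must be non-negative")
    base = replace(scenario, subtype=Subtype.TRIPLE, eta1=0.0, eta2=0.0)
    gamma, eta1 = _solve_affine_2x2(
        base, production,
        set_unknowns=lambda sc, g, e1: replace(sc, gamma=g, eta1=e1, eta2=rho_MDH * e1),
    )
    eta2 = rho_MDH * eta1
    feasible = (
        0.0 <= gamma <= 1.0
        and eta1 >= 0.0
        and eta2 >= 0.0
        and eta1 + eta2 <= 1.0
    )
    diagnosis = "" if feasible else (
        f"triple solution gamma={gamma:.3f}, eta1={eta1:.3f}, eta2={eta2:.3f} "
        "violates 0 <= eta1 + eta2 <= 1 or gamma bounds"
    )
    return MatchResult(
        gamma_nadph=gamma, gamma_atp=gamma, eta1=eta1, eta2=eta2,
        rho_MDH=rho_MDH, feasible=feasible, diagnosis=diagnosis,
    )


def _production_for(preset: ParameterPreset, scenario: DemandScenario) -> CellTypeSolution:
    budget = scenario_budget(scenario, preset.efficiency)
    optics = absorption_cascade(preset.leaf)
    return solve_cell_fluxes(budget, optics, preset.photosystems, preset.efficiency)


def _match_once(
    mix_subtype: Subtype,
    scenario: DemandScenario,
    production: CellTypeSolution,
    rho_MDH: float | None,
) -> MatchResult:
    if mix_subtype is Subtype.TRIPLE:
        return solve_triple(scenario, production, rho_MDH if rho_MDH is not None else 0.39)
    if mix_subtype in DOUBLE_MIXES:
        return solve_eta_double(mix_subtype, scenario, production)
    # pure subtype: solve gamma for both currencies, no eta
    g_n, feas_n = solve_gamma(mix_subtype, scenario, production, "NADPH")
    g_a, feas_a = solve_gamma(mix_subtype, scenario, production, "ATP")
    diagnosis = ""
    if g_a < 0.0:
        diagnosis = "gamma for ATP negative: BS ATP requirement impossible to meet"
    return MatchResult(
        gamma_nadph=g_n, gamma_atp=g_a,
        feasible=feas_n and feas_a, diagnosis=diagnosis,
    )


def self_consistent_match(
    mix_subtype: Subtype,
    preset: ParameterPreset,
    scenario: DemandScenario | None = None,
    rho_MDH: float | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> MatchResult:
    """Iterate matching and production to a fixed point.

    A solved η changes the whole-leaf ATP requirement of a mixed type,
    which changes the electron budget, the cell-type solution, and hence
    the production fractions the matching used.  This loop re-solves
    until the production fractions stop moving (max |Δ| < tol).  In
    practice the production fractions barely move, which is why the
    default single-pass solvers are adequate; ``production_drift``
    reports the total movement between the first and final pass.

    Raises
    ------
    NonConvergenceError
        If the fixed point is not reached within ``max_iter`` passes.
    """
    if scenario is None:
        scenario = DemandScenario(subtype=mix_subtype)
    scenario = replace(scenario, subtype=mix_subtype)
    if mix_subtype in DOUBLE_MIXES and scenario.eta is None:
        scenario = replace(scenario, eta=1.0)
    if mix_subtype is Subtype.TRIPLE and scenario.eta1 is None:
        scenario = replace(scenario, eta1=1.0, eta2=0.0)

    first_fracs: tuple[float, float] | None = None

    for iteration in range(1, max_iter + 1):
        production = _production_for(preset, scenario)
        fracs = (production.f_nadph_BS, production.f_atp_BS)
        if first_fracs is None:
            first_fracs = fracs
        result = _match_once(mix_subtype, scenario, production, rho_MDH)
        # propagate solved unknowns into the scenario for the next pass
        updates: dict[str, float] = {}
        if result.gamma_nadph is not None:
            updates["gamma"] = result.gamma_nadph
        if result.eta is not None:
            updates["eta"] = result.eta
        if result.eta1 is not None:
            updates["eta1"] = result.eta1
            updates["eta2"] = result.eta2 if result.eta2 is not None else 0.0
        scenario = replace(scenario, **updates)
        nxt = _production_for(preset, scenario)
        delta = max(abs(nxt.f_nadph_BS - fracs[0]), abs(nxt.f_atp_BS - fracs[1]))
        if delta < tol:
            drift = max(
                abs(nxt.f_nadph_BS - first_fracs[0]),
                abs(nxt.f_atp_BS - first_fracs[1]),
            )
            return replace(
                result, iterations=iteration, converged=True, production_drift=drift,
            )
    raise NonConvergenceError(
        f"self-consistent matching did not converge within {max_iter} iterations"
    )
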