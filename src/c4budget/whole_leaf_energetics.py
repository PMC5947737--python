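"""Whole-leaf electron fluxes, photon cost and quantum yield.

Given the whole-leaf NADPH and ATP demand per CO₂, the leaf is assumed
to run exactly enough linear electron transport (LET) to supply the
NADPH (2 e⁻ per NADPH) and to top up the remaining ATP with cyclic
electron transport (CET) around PSI — the NADPH+ATP co-limitation
assumption.  ATP yields follow from the proton stoichiometries:
J·H/h ATP per J electrons.

The photon cost charges every LET electron with one PSII and one PSI
photon (1/Φ2LL + 1/Φ1LL) and every CET electron with one PSI photon
(1/Φ1LL).  The quantum yield Φ_CO2 is the reciprocal photon cost per
Rubisco carboxylation; no net-CO₂ correction for photorespiration or day
respiration is applied (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

from .core_params import EfficiencyStoichiometry
from .demand_stoichiometry import DemandScenario, whole_leaf_requirements

__all__ = ["WholeLeafBudget", "electron_budget", "scenario_budget"]


@dataclass(frozen=True)
class WholeLeafBudget:
    """Whole-leaf electron-transport budget per mol CO₂ carboxylated.

    ``atp_surplus`` flags demand combinations where LET alone would
    overproduce ATP (A_req < J_LET·H_LET/h); CET is then floored at zero
    and the ATP closure no longer holds exactly.
    """

    N_req: float
    A_req: float
    J_LET: float
    J_CET: float
    atp_from_LET: float
    f_CET: float
    photons: float
    Phi_CO2: float
    frac_atp_LET: float
    atp_surplus: bool = False

    @property
    def J_tot(self) -> float:
        return self.J_LET + self.J_CET

    def as_record(self) -> dict[str, float]:
        return {
            "N_req": self.N_req,
            "A_req": self.A_req,
            "J_LET": self.J_LET,
            "J_CET": self.J_CET,
            "atp_from_LET": self.atp_from_LET,
            "f_CET": self.f_CET,
            "photons": self.photons,
            "Phi_CO2": self.Phi_CO2,
            "frac_atp_LET": self.frac_atp_LET,
        }


def electron_budget(
    N_req: float, A_req: float, eff: EfficiencyStoichiometry
) -> WholeLeafBudget:
    """Partition electron flux between LET and CET for a given demand.

    LET is sized by the NADPH demand (J_LET = 2 N_req); CET covers the
    ATP deficit left after LET's proton pumping, at H_CET protons per
    electron.  Both productions then close on the demands exactly
    whenever the deficit is non-negative.
    """
    J_LET = 2.0 * N_req
    atp_from_LET = J_LET * eff.H_LET / eff.h
    deficit = A_req - atp_from_LET
    surplus = deficit < 0.0
    J_CET = max(0.0, deficit) * eff.h / eff.H_CET
    J_tot = J_LET + J_CET
    f_CET = J_CET / J_tot if J_tot > 0.0 else 0.0
    P2 = 1.0 / eff.Phi2LL
    P1 = 1.0 / eff.Phi1LL
    photons = J_LET * (P2 + P1) + J_CET * P1
    Phi_CO2 = 1.0 / photons if photons > 0.0 else float("inf")
    return WholeLeafBudget(
        N_req=N_req,
        A_req=A_req,
        J_LET=J_LET,
        J_CET=J_CET,
        atp_from_LET=atp_from_LET,
        f_CET=f_CET,
        photons=photons,
        Phi_CO2=Phi_CO2,
        frac_atp_LET=atp_from_LET / A_req if A_req > 0.0 else float("nan"),
        atp_surplus=surplus,
    )


def scenario_budget(
    scenario: DemandScenario, eff: EfficiencyStoichiometry
) -> WholeLeafBudget:
    """Electron budget for a demand scenario (requirements → fluxes)."""
    N_req, A_req = whole_leaf_requirements(scenario)
    return electron_budget(N_req, A_req, eff)
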