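"""Cell-type-specific NADPH and ATP demand per CO₂ assimilated.

Each decarboxylation type — the three classical subtypes (NADP-ME,
NAD-ME, standard PEP-CK), the 'aspartate–malate' variant, the
theoretical 'pure' PEP-CK type, and the double/triple mixed pathways —
has a fixed per-CO₂ stoichiometry of NADPH and ATP consumption in
mesophyll (M) and bundle-sheath (BS) cells.  The entries depend on:

* the leakiness ``phi_leak`` (ϕ), which inflates the C₄-cycle flux per
  net carboxylation by (1 + ϕ);
* ``gamma`` (γ), the fraction of the 3-PGA reduction phase of the Calvin
  cycle located in BS cells;
* ``eta`` (η) or (η₁, η₂), the fractions of oxaloacetate following the
  primary (and, for the triple pathway, the aspartate–malate) route;
* ``n_mito`` (n), the mitochondrial ATP:NADH yield, which sets the
  malate fraction a = 1/(1 + n) of the standard PEP-CK subtype;
* ``phi_extra`` (φ), the chloroplastic ATP per C₄ cycle for PEP
  regeneration (2 for pyruvate,Pi-dikinase);
* optional sink terms x₁–x₄ that add photorespiratory, nitrate-reduction
  and starch-synthesis costs.

Sinks carry an explicit on/off switch: the basic model corresponds to
all x terms equal to zero, including the starch term, not merely to
zero sink ratios.  Nitrate reduction is assigned to M cells, starch
synthesis and the non-reductive photorespiratory costs to BS cells;
these locations are fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

__all__ = [
    "Subtype",
    "SinkRatios",
    "DemandScenario",
    "CellRequirements",
    "sink_terms",
    "cell_requirements",
    "whole_leaf_requirements",
    "MissingParameterError",
]


class Subtype(str, Enum):
    """Decarboxylation type labels."""

    NADP_ME = "NADP_ME"
    NAD_ME = "NAD_ME"
    PEPCK_STANDARD = "PEPCK_STANDARD"
    ASP_MALATE = "ASP_MALATE"
    PURE_PEPCK = "PURE_PEPCK"
    NADPME_ASPMAL = "NADPME_ASPMAL"
    NADPME_PEPCK = "NADPME_PEPCK"
    NADME_PEPCK = "NADME_PEPCK"
    TRIPLE = "TRIPLE"


DOUBLE_MIXES = {Subtype.NADPME_ASPMAL, Subtype.NADPME_PEPCK, Subtype.NADME_PEPCK}


class MissingParameterError(ValueError):
    """A scenario field required by the chosen subtype is not set."""


@dataclass(frozen=True)
class SinkRatios:
    """Flux ratios of the alternative sinks to Rubisco carboxylation.

    nu_oc: oxygenation (photorespiration); nu_nc: nitrate reduction;
    nu_rc: day respiration.  All default to zero (basic model).
    """

    nu_oc: float = 0.0
    nu_nc: float = 0.0
    nu_rc: float = 0.0

    @classmethod
    def illustrative(cls) -> "SinkRatios":
        """The standard illustration: 1:20 oxygenation, 1:35 nitrate, 1:40 respiration."""
        return cls(nu_oc=1.0 / 20.0, nu_nc=1.0 / 35.0, nu_rc=1.0 / 40.0)


@dataclass(frozen=True)
class DemandScenario:
    """Subtype choice plus every stoichiometric parameter the entries use."""

    subtype: Subtype = Subtype.NADP_ME
    phi_leak: float = 0.16
    gamma: float = 0.5
    eta: float | None = None
    eta1: float | None = None
    eta2: float | None = None
    n_mito: float | None = None
    sinks: SinkRatios = field(default_factory=SinkRatios)
    sinks_enabled: bool = False
    phi_extra: float = 2.0

    @property
    def a_malate(self) -> float:
        """Malate fraction a = 1/(1 + n) of the standard PEP-CK subtype."""
        if self.n_mito is None:
            raise MissingParameterError("n_mito is required for the standard PEP-CK subtype")
        return 1.0 / (1.0 + self.n_mito)


@dataclass(frozen=True)
class CellRequirements:
    """Per-CO₂ NADPH and ATP demand in each cell type, with BS:total ratios.

    Ratios are always derived from the cell entries themselves.  Values
    outside [0, 1] are reported with ``feasible=False`` rather than
    clamped: the model uses such values diagnostically.
    """

    nadph_M: float
    nadph_BS: float
    atp_M: float
    atp_BS: float
    x1: float
    x2: float
    x3: float
    x4: float

    @property
    def nadph_total(self) -> float:
        return self.nadph_M + self.nadph_BS

    @property
    def atp_total(self) -> float:
        return self.atp_M + self.atp_BS

    @property
    def ratio_nadph_BS(self) -> float:
        return self.nadph_BS / self.nadph_total

    @property
    def ratio_atp_BS(self) -> float:
        return self.atp_BS / self.atp_total

    @property
    def feasible(self) -> bool:
        return 0.0 <= self.ratio_nadph_BS <= 1.0 and 0.0 <= self.ratio_atp_BS <= 1.0

    def as_record(self) -> dict[str, float]:
        return {
            "nadph_M": self.nadph_M,
            "nadph_BS": self.nadph_BS,
            "nadph_total": self.nadph_total,
            "atp_M": self.atp_M,
            "atp_BS": self.atp_BS,
            "atp_total": self.atp_total,
            "ratio_nadph_BS": self.ratio_nadph_BS,
            "ratio_atp_BS": self.ratio_atp_BS,
            "x1": self.x1,
            "x2": self.x2,
            "x3": self.x3,
            "x4": self.x4,
        }


def sink_terms(
    sinks: SinkRatios, gamma: float, enabled: bool = True
) -> tuple[float, float, float, float]:
    """The four sink cost terms (x1, x2, x3, x4).

    x1/x3 are NADPH/ATP costs landing in M cells, x2/x4 the costs landing
    in BS cells.  The 3-PGA-reduction share of the photorespiratory cost
    (1.5 ν_oc of each currency) is split between cells by γ; the
    remaining photorespiratory cost (0.5 ν_oc NADPH, 2 ν_oc ATP), and the
    starch-synthesis ATP 0.167·(1 − 0.5 ν_oc − ν_rc), are placed in BS.
    Nitrate reduction costs 5 ν_nc NADPH and ν_nc ATP in M cells.  When
    ``enabled`` is False all four terms are zero regardless of the ratios.
    """
    if not enabled:
        return (0.0, 0.0, 0.0, 0.0)
    nu_oc, nu_nc, nu_rc = sinks.nu_oc, sinks.nu_nc, sinks.nu_rc
    x1 = 1.5 * nu_oc * (1.0 - gamma) + 5.0 * nu_nc
    x2 = 1.5 * nu_oc * gamma + 0.5 * nu_oc
    x3 = 1.5 * nu_oc * (1.0 - gamma) + nu_nc
    x4 = 1.5 * nu_oc * gamma + 2.0 * nu_oc + 0.167 * (1.0 - 0.5 * nu_oc - nu_rc)
    return (x1, x2, x3, x4)


def _require(scenario: DemandScenario, *fields: str) -> None:
    for name in fields:
        if getattr(scenario, name) is None:
            raise MissingParameterError(
                f"scenario field {name!r} is required for subtype {scenario.subtype.value}"
            )


def cell_requirements(scenario: DemandScenario) -> CellRequirements:
    """Per-CO₂ NADPH and ATP requirements in M and BS cells.

    Mixed types are the η-weighted averages of the requirements of their
    constituent routes, so every mixed entry is continuous in η and
    reduces to the pure subtype at the boundary.
    """
    s = scenario
    L = 1.0 + s.phi_leak  # C4-cycle flux per net carboxylation
    g = s.gamma
    phi4 = s.phi_extra
    x1, x2, x3, x4 = sink_terms(s.sinks, g, s.sinks_enabled)

    # shared building blocks
    red_M = 2.0 * (1.0 - g)  # 3-PGA reduction in M, per currency
    red_BS = 2.0 * g
    atp_M_ME = phi4 * L + red_M + x3  # ME-family ATP in M (PEP regeneration + reduction)
    atp_BS_ME = 1.0 + red_BS + x4  # RuBP regeneration + reduction in BS

    t = s.subtype
    if t is Subtype.NADP_ME:
        nadph_M = L + red_M + x1
        nadph_BS = -L + red_BS + x2
        atp_M, atp_BS = atp_M_ME, atp_BS_ME
    elif t in (Subtype.NAD_ME, Subtype.ASP_MALATE):
        nadph_M = red_M + x1
        nadph_BS = red_BS + x2
        atp_M, atp_BS = atp_M_ME, atp_BS_ME
    elif t is Subtype.PEPCK_STANDARD:
        _require(s, "n_mito")
        a = s.a_malate
        nadph_M = a * L + red_M + x1
        nadph_BS = red_BS + x2
        atp_M = phi4 * a * L + red_M + x3  # PEP regeneration for the malate fraction only
        atp_BS = atp_BS_ME
    elif t is Subtype.PURE_PEPCK:
        nadph_M = red_M + x1
        nadph_BS = red_BS + x2
        atp_M = red_M + x3
        atp_BS = 1.0 + red_BS + L + x4
    elif t is Subtype.NADPME_ASPMAL:
        _require(s, "eta")
        nadph_M = s.eta * L + red_M + x1
        nadph_BS = -s.eta * L + red_BS + x2
        atp_M, atp_BS = atp_M_ME, atp_BS_ME
    elif t is Subtype.NADPME_PEPCK:
        _require(s, "eta")
        nadph_M = s.eta * L + red_M + x1
        nadph_BS = -s.eta * L + red_BS + x2
        atp_M = phi4 * s.eta * L + red_M + x3
        atp_BS = (1.0 - s.eta) * L + 1.0 + red_BS + x4
    elif t is Subtype.NADME_PEPCK:
        _require(s, "eta")
        nadph_M = red_M + x1
        nadph_BS = red_BS + x2
        atp_M = phi4 * s.eta * L + red_M + x3
        atp_BS = (1.0 - s.eta) * L + 1.0 + red_BS + x4
    elif t is Subtype.TRIPLE:
        _require(s, "eta1", "eta2")
        e1, e2 = s.eta1, s.eta2
        nadph_M = e1 * L + red_M + x1
        nadph_BS = -e1 * L + red_BS + x2
        atp_M = phi4 * (e1 + e2) * L + red_M + x3
        atp_BS = (1.0 - e1 - e2) * L + 1.0 + red_BS + x4
    else:  # pragma: no cover - exhaustive enum
        raise ValueError(f"unhandled subtype {t}")

    return CellRequirements(
        nadph_M=nadph_M, nadph_BS=nadph_BS, atp_M=atp_M, atp_BS=atp_BS,
        x1=x1, x2=x2, x3=x3, x4=x4,
    )


def whole_leaf_requirements(scenario: DemandScenario) -> tuple[float, float]:
    """Whole-leaf (NADPH, ATP) demand per CO₂ — the cell-entry totals.

    Both totals are invariant to γ (the reduction phase only moves
    between cells) and, for the basic NADP-ME/NAD-ME model, equal
    (2, 3 + φ(1 + ϕ)).
    """
    req = cell_requirements(scenario)
    return (req.nadph_total, req.atp_total)
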