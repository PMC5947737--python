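"""Light absorption by bundle-sheath and mesophyll compartments.

One unit of interveinal distance is divided into four sections: the
interveinal mesophyll column M1 (width fraction ``m``), and the vein
column (width fraction ``1 - m``), which is traversed top to bottom in
the order adaxial mesophyll M2, bundle sheath BS, abaxial mesophyll M3.
M2 and M3 each occupy half of the non-BS leaf depth, so their areas are
equal by construction.  Chlorophyll is partitioned to BS cells by
``f_bsCHL`` and among the three M sections in proportion to their areas.

Absorption is a single-pass, adaxial-only Beer–Lambert cascade.  Each
section absorbs the fraction ``1 - exp(-k C)`` of the light entering it,
where ``C`` is the section's chlorophyll expressed per unit leaf area;
the column widths enter only as the share of incident light each column
receives (``m`` or ``1 - m``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core_params import LeafStructure

__all__ = [
    "SectionAreas",
    "ChlorophyllPartition",
    "OpticsResult",
    "section_areas",
    "partition_chlorophyll",
    "absorption_cascade",
]


@dataclass(frozen=True)
class SectionAreas:
    """Relative areas of the four sections of one interveinal unit (sum = 1)."""

    A_M1: float
    A_M2: float
    A_M3: float
    A_BS: float

    @property
    def A_Mtot(self) -> float:
        return self.A_M1 + self.A_M2 + self.A_M3


@dataclass(frozen=True)
class ChlorophyllPartition:
    """Chlorophyll of each section, µmol per m² of leaf (sum = leaf CHL)."""

    C_M1: float
    C_M2: float
    C_M3: float
    C_BS: float

    @property
    def C_M(self) -> float:
        return self.C_M1 + self.C_M2 + self.C_M3


@dataclass(frozen=True)
class OpticsResult:
    """Fractions of incident light absorbed per section and their aggregates.

    ``ratio_BS_M`` is a_BS/a_M, the BS:M absorptance ratio; it is NaN with
    ``degenerate=True`` when nothing absorbs (k·CHL = 0).
    """

    a_M1: float
    a_M2: float
    a_M3: float
    a_BS: float
    a_M: float
    absorptance: float
    transmitted: float
    ratio_BS_M: float
    degenerate: bool = False

    def as_record(self) -> dict[str, float]:
        return {
            "a_M1": self.a_M1,
            "a_M2": self.a_M2,
            "a_M3": self.a_M3,
            "a_BS": self.a_BS,
            "a_M": self.a_M,
            "absorptance": self.absorptance,
            "transmitted": self.transmitted,
            "ratio_BS_M": self.ratio_BS_M,
        }


def section_areas(leaf: LeafStructure) -> SectionAreas:
    """Areas of M1, M2, M3 and BS from the two anatomical fractions."""
    m, n_BS = leaf.m, leaf.n_BS
    half = (1.0 - m) * (1.0 - n_BS) / 2.0
    return SectionAreas(A_M1=m, A_M2=half, A_M3=half, A_BS=(1.0 - m) * n_BS)


def partition_chlorophyll(
    leaf: LeafStructure, areas: SectionAreas | None = None
) -> ChlorophyllPartition:
    """Split leaf chlorophyll between BS and the three M sections.

    BS receives ``f_bsCHL·CHL``; the M remainder is divided among M1, M2
    and M3 in proportion to their areas.
    """
    if areas is None:
        areas = section_areas(leaf)
    C_BS = leaf.f_bsCHL * leaf.CHL
    C_M = (1.0 - leaf.f_bsCHL) * leaf.CHL
    tot = areas.A_Mtot
    return ChlorophyllPartition(
        C_M1=C_M * areas.A_M1 / tot,
        C_M2=C_M * areas.A_M2 / tot,
        C_M3=C_M * areas.A_M3 / tot,
        C_BS=C_BS,
    )


def absorption_cascade(leaf: LeafStructure) -> OpticsResult:
    """Serial Beer–Lambert absorption through the two-column leaf.

    The M1 column receives fraction ``m`` of incident light and absorbs
    in one step; the vein column receives ``1 - m`` and is traversed in
    the order M2 → BS → M3, each section absorbing from what the layers
    above transmitted.
    """
    m = leaf.m
    chl = partition_chlorophyll(leaf)

    def absorbed(C: float) -> float:
        return 1.0 - math.exp(-leaf.k * C)

    A_M1 = absorbed(chl.C_M1)
    A_M2 = absorbed(chl.C_M2)
    A_BS = absorbed(chl.C_BS)
    A_M3 = absorbed(chl.C_M3)

    a_M1 = m * A_M1
    a_M2 = (1.0 - m) * A_M2
    a_BS = (1.0 - m) * (1.0 - A_M2) * A_BS
    a_M3 = (1.0 - m) * (1.0 - A_M2) * (1.0 - A_BS) * A_M3
    a_M = a_M1 + a_M2 + a_M3
    absorptance = a_M + a_BS
    transmitted = m * (1.0 - A_M1) + (1.0 - m) * (1.0 - A_M2) * (1.0 - A_BS) * (1.0 - A_M3)

    degenerate = absorptance == 0.0
    ratio = math.nan if a_M == 0.0 else a_BS / a_M
    return OpticsResult(
        a_M1=a_M1,
        a_M2=a_M2,
        a_M3=a_M3,
        a_BS=a_BS,
        a_M=a_M,
        absorptance=absorptance,
        transmitted=transmitted,
        ratio_BS_M=ratio,
        degenerate=degenerate,
    )
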