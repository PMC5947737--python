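"""Partitioning of LET and CET between bundle-sheath and mesophyll cells.

The whole-leaf electron budget fixes the total LET flux ``J_LET`` and
CET flux ``J_CET``.  How much of each runs in the bundle sheath is set
by three simultaneous constraints:

1. *BS photon balance* — the photons absorbed by BS pigments must pay
   for the BS electron fluxes: ``x (P2 + P1) + y P1 = A_BS`` where
   ``x``/``y`` are BS LET/CET electron flux, ``P2 = 1/Φ2LL``,
   ``P1 = 1/Φ1LL``, and ``A_BS`` is the BS share of absorbed photons per
   CO₂.  The mesophyll balance then holds identically.
2. *PSII allocation* — the fraction of total PSII in BS, α, equals the
   BS share of PSII units.  PSII units are proportional to flux divided
   by the light absorbed per photosystem, so with ``r = k_BS : k_M`` the
   BS:M absorptance per photosystem: ``α = (x/r) / (x/r + J_LET − x)``.
3. *PSI allocation* — likewise for PSI with ``s = x + y`` the total BS
   PSI flux: ``f_bsPSI = (s/r) / (s/r + J_tot − s)``.

Substituting the photon balance into the two allocation constraints
yields a quadratic in ``x`` with exactly one admissible root on
realistic inputs; ``y``, ``r`` and all derived indicators follow in
closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_params import EfficiencyStoichiometry, PhotosystemDistribution
from .leaf_optics import OpticsResult
from .whole_leaf_energetics import WholeLeafBudget

__all__ = [
    "CellTypeSolution",
    "AlphaScanResult",
    "solve_cell_fluxes",
    "alpha_feasibility_scan",
    "NoAdmissibleRootError",
    "AmbiguousRootError",
]

_BALANCE_TOL = 1e-9


class NoAdmissibleRootError(ValueError):
    """The quadratic has no root with x in [0, J_LET] and r > 0."""


class AmbiguousRootError(ValueError):
    """Both quadratic roots are admissible (not observed on realistic inputs)."""


@dataclass(frozen=True)
class CellTypeSolution:
    """Bundle-sheath fluxes and every derived cell-type indicator.

    ``x``/``y`` are LET/CET electron flux in BS per CO₂; ``s = x + y``;
    ``r`` is the BS:M absorptance ratio per photosystem.  Ratios that
    divide by a zero flux (e.g. the BS PSI:PSII ratio when BS has no
    PSII) are reported as infinities with ``has_infinite_ratios`` set.
    """

    x: float
    y: float
    s: float
    r: float
    u: float
    v: float
    beta: float
    CxT: float
    psi_psii_leaf: float
    psi_psii_BS: float
    psi_psii_M: float
    photosys_BS_M: float
    f_CET_BS: float
    f_CET_M: float
    e_flux_BS_M: float
    cet_share_BS: float
    f_nadph_BS: float
    f_atp_BS: float
    atp_BS_from_CET: float
    A_BS: float
    A_M: float
    feasible: bool
    violations: tuple[str, ...] = ()
    has_infinite_ratios: bool = False

    def as_record(self) -> dict[str, float]:
        return {
            "J_LET_BS": self.x,
            "J_CET_BS": self.y,
            "k_BS_k_M": self.r,
            "u": self.u,
            "v": self.v,
            "beta": self.beta,
            "Cx_T": self.CxT,
            "psi_psii_leaf": self.psi_psii_leaf,
            "psi_psii_BS": self.psi_psii_BS,
            "psi_psii_M": self.psi_psii_M,
            "photosys_BS_M": self.photosys_BS_M,
            "f_CET_BS": self.f_CET_BS,
            "f_CET_M": self.f_CET_M,
            "e_flux_BS_M": self.e_flux_BS_M,
            "cet_share_BS": self.cet_share_BS,
            "f_nadph_BS": self.f_nadph_BS,
            "f_atp_BS": self.f_atp_BS,
            "atp_BS_from_CET": self.atp_BS_from_CET,
        }


def _solve_x(
    alpha: float,
    f_bsPSI: float,
    J_LET: float,
    J_tot: float,
    A_BS: float,
    c: float,
    d: float,
) -> float:
    """Admissible root of the matching quadratic in x (BS LET flux).

    ``c = Φ1LL·A_BS`` and ``d = Φ1LL/Φ2LL`` define the photon-balance
    line ``s(x) = c − d·x``.  Equating the r-expressions from the PSII
    and PSI allocation constraints and cross-multiplying gives
    ``(Ka − Kf) d x² + [Ka (J_tot − c) + Kf (c + d J_LET)] x − Kf c J_LET = 0``
    with ``Ka = (1−α)/α`` and ``Kf = (1−f_bsPSI)/f_bsPSI``.
    """
    Ka = (1.0 - alpha) / alpha
    Kf = (1.0 - f_bsPSI) / f_bsPSI
    c2 = (Ka - Kf) * d
    c1 = Ka * (J_tot - c) + Kf * (c + d * J_LET)
    c0 = -Kf * c * J_LET

    if abs(c2) < 1e-14:  # allocation symmetry alpha == f_bsPSI: linear equation
        roots = [-c0 / c1] if c1 != 0.0 else []
    else:
        disc = c1 * c1 - 4.0 * c2 * c0
        if disc < 0.0:
            roots = []
        else:
            sq = math.sqrt(disc)
            roots = [(-c1 + sq) / (2.0 * c2), (-c1 - sq) / (2.0 * c2)]

    admissible = []
    for x in roots:
        if -1e-12 <= x <= J_LET * (1.0 + 1e-12):
            x = min(max(x, 0.0), J_LET)
            r = _r_from_alpha(alpha, x, J_LET)
            if r > 0.0 and math.isfinite(r):
                admissible.append(x)
    if not admissible:
        raise NoAdmissibleRootError(
            f"no admissible root for alpha={alpha}, f_bsPSI={f_bsPSI}"
        )
    if len(admissible) > 1 and abs(admissible[0] - admissible[1]) > 1e-9:
        raise AmbiguousRootError(
            f"both quadratic roots admissible for alpha={alpha}, f_bsPSI={f_bsPSI}"
        )
    return admissible[0]


def _r_from_alpha(alpha: float, x: float, J_LET: float) -> float:
    if x >= J_LET:
        return math.inf
    return (1.0 - alpha) / alpha * x / (J_LET - x)


def _r_from_psi(f_bsPSI: float, s: float, J_tot: float) -> float:
    if s >= J_tot:
        return math.inf
    return (1.0 - f_bsPSI) / f_bsPSI * s / (J_tot - s)


def solve_cell_fluxes(
    budget: WholeLeafBudget,
    optics: OpticsResult,
    ps: PhotosystemDistribution,
    eff: EfficiencyStoichiometry,
) -> CellTypeSolution:
    """Solve the three-constraint system for the BS fluxes (x, y) and r.

    Degenerate photosystem distributions bypass the quadratic: α = 0
    forces x = 0 (no PSII in BS means no BS LET) with r determined from
    the PSI constraint alone; α = 1 forces x = J_LET symmetrically.

    The result always reports the full indicator set; out-of-range
    indicators (u, v outside [0, 1], y outside [0, J_CET]) set
    ``feasible=False`` with the violated bounds listed, never an error.
    """
    if budget.J_LET <= 0.0:
        raise ValueError("cell-type partitioning requires J_LET > 0")
    J_LET, J_CET, J_tot = budget.J_LET, budget.J_CET, budget.J_tot
    P2 = 1.0 / eff.Phi2LL
    P1 = 1.0 / eff.Phi1LL
    total_abs = optics.a_BS + optics.a_M
    if total_abs <= 0.0:
        raise ValueError("optics result absorbs no light; cannot partition photons")
    A_BS = budget.photons * optics.a_BS / total_abs
    A_M = budget.photons * optics.a_M / total_abs
    c = eff.Phi1LL * A_BS
    d = eff.Phi1LL / eff.Phi2LL

    alpha, f = ps.alpha, ps.f_bsPSI
    if alpha <= 0.0:
        x = 0.0
    elif alpha >= 1.0:
        x = J_LET
    elif f <= 0.0:
        # no PSI in BS: s = 0 hence x = c/d and y = -x; typically infeasible
        x = c / d
    elif f >= 1.0:
        # all PSI in BS: s = J_tot
        x = (c - J_tot) / d
    else:
        x = _solve_x(alpha, f, J_LET, J_tot, A_BS, c, d)

    s = c - d * x
    y = s - x

    # r from whichever allocation constraint is non-degenerate
    if 0.0 < alpha < 1.0 and 0.0 < x < J_LET:
        r = _r_from_alpha(alpha, x, J_LET)
    elif 0.0 < f < 1.0 and 0.0 < s < J_tot:
        r = _r_from_psi(f, s, J_tot)
    elif alpha >= 1.0:
        r = math.inf
    else:
        r = math.nan

    u = (J_LET - x) * (P2 + P1) / A_M if A_M > 0.0 else math.nan
    v = x * (P2 + P1) / A_BS if A_BS > 0.0 else 0.0

    def ratio(num: float, den: float) -> float:
        if den == 0.0:
            return math.inf if num > 0.0 else math.nan
        return num / den

    eff21 = eff.Phi2LL / eff.Phi1LL
    psii_BS = x / r if math.isfinite(r) and r > 0.0 else 0.0
    psii_M = J_LET - x
    psi_BS = s / r if math.isfinite(r) and r > 0.0 else 0.0
    psi_M = J_tot - s

    cet_psi_BS = y / r if math.isfinite(r) and r > 0.0 else 0.0
    beta = ratio(y, y + r * (J_CET - y)) if math.isfinite(r) else ratio(y, y)
    CxT = eff21 * ratio(cet_psi_BS + (J_CET - y), psii_BS + psii_M)
    psi_psii_leaf = eff21 * ratio(psi_BS + psi_M, psii_BS + psii_M)
    psi_psii_BS = eff21 * ratio(s, x)
    psi_psii_M = eff21 * ratio(J_tot - s, J_LET - x)
    photosys_BS_M = (optics.a_BS / optics.a_M) / r if math.isfinite(r) and r > 0.0 else 0.0
    f_CET_BS = ratio(y, s)
    f_CET_M = ratio(J_CET - y, J_tot - s)
    e_flux_BS_M = ratio(s, J_tot - s)
    cet_share_BS = ratio(y, J_CET) if J_CET > 0.0 else 0.0
    f_nadph_BS = x / J_LET
    atp_BS = (x * eff.H_LET + y * eff.H_CET) / eff.h
    f_atp_BS = atp_BS / budget.A_req if budget.A_req > 0.0 else math.nan
    atp_BS_from_CET = ratio(y * eff.H_CET / eff.h, atp_BS)

    violations: list[str] = []
    tol = 1e-9
    if not -tol <= x <= J_LET + tol:
        violations.append(f"x = {x:.4g} outside [0, J_LET]")
    if not -tol <= y <= J_CET + tol:
        violations.append(f"y = {y:.4g} outside [0, J_CET]")
    if not (math.isfinite(u) and -tol <= u <= 1.0 + tol):
        violations.append(f"u = {u:.4g} outside [0, 1]")
    if not -tol <= v <= 1.0 + tol:
        violations.append(f"v = {v:.4g} outside [0, 1]")
    if not (math.isfinite(r) and r > 0.0):
        violations.append(f"r = {r} not positive and finite")

    has_inf = any(
        not math.isfinite(q)
        for q in (psi_psii_BS, psi_psii_M, beta, CxT, psi_psii_leaf, r)
    )

    return CellTypeSolution(
        x=x, y=y, s=s, r=r, u=u, v=v, beta=beta, CxT=CxT,
        psi_psii_leaf=psi_psii_leaf, psi_psii_BS=psi_psii_BS, psi_psii_M=psi_psii_M,
        photosys_BS_M=photosys_BS_M, f_CET_BS=f_CET_BS, f_CET_M=f_CET_M,
        e_flux_BS_M=e_flux_BS_M, cet_share_BS=cet_share_BS,
        f_nadph_BS=f_nadph_BS, f_atp_BS=f_atp_BS, atp_BS_from_CET=atp_BS_from_CET,
        A_BS=A_BS, A_M=A_M,
        feasible=not violations, violations=tuple(violations),
        has_infinite_ratios=has_inf,
    )


@dataclass(frozen=True)
class AlphaScanResult:
    """Feasible α interval plus the full per-α scan table.

    ``interval`` holds the endpoints of the contiguous feasible run at
    grid resolution (None when no grid point is feasible).  The analytic
    boundaries locate where v → 1 (equivalently the BS CET flux y → 0)
    and where u → 1 (y → J_CET); they bracket the grid interval.
    """

    table: pd.DataFrame
    interval: tuple[float, float] | None
    alpha_v1: float | None
    alpha_u1: float | None


def alpha_feasibility_scan(
    budget: WholeLeafBudget,
    optics: OpticsResult,
    f_bsPSI: float,
    eff: EfficiencyStoichiometry,
    grid_step: float = 0.005,
) -> AlphaScanResult:
    """Scan α over [0, 1] and report the physiologically feasible interval.

    A grid point is feasible when a solution exists with u, v in [0, 1],
    y in [0, J_CET] and r > 0 (closed bounds; boundary points count).
    """
    if grid_step <= 0.0:
        raise ValueError("grid_step must be positive")
    n = int(round(1.0 / grid_step))
    alphas = np.linspace(0.0, 1.0, n + 1)
    rows = []
    for a in alphas:
        ps = PhotosystemDistribution(alpha=float(a), f_bsPSI=f_bsPSI)
        try:
            sol = solve_cell_fluxes(budget, optics, ps, eff)
            rows.append({"alpha": float(a), "feasible": sol.feasible, **sol.as_record()})
        except (NoAdmissibleRootError, AmbiguousRootError):
            rows.append({"alpha": float(a), "feasible": False})
    table = pd.DataFrame(rows)

    feas = table.loc[table["feasible"].fillna(False).astype(bool), "alpha"]
    interval: tuple[float, float] | None = None
    if len(feas):
        # contiguous run containing the first feasible point
        idx = table.index[table["feasible"].fillna(False).astype(bool)].to_numpy()
        breaks = np.where(np.diff(idx) > 1)[0]
        stop = idx[breaks[0]] if len(breaks) else idx[-1]
        interval = (float(table.loc[idx[0], "alpha"]), float(table.loc[stop, "alpha"]))

    # analytic boundaries from the photon balance
    P2 = 1.0 / eff.Phi2LL
    P1 = 1.0 / eff.Phi1LL
    total_abs = optics.a_BS + optics.a_M
    A_BS = budget.photons * optics.a_BS / total_abs
    A_M = budget.photons * optics.a_M / total_abs
    J_LET, J_tot = budget.J_LET, budget.J_tot

    def alpha_at(x: float) -> float | None:
        if not 0.0 < x < J_LET:
            return None
        s = eff.Phi1LL * A_BS - (eff.Phi1LL / eff.Phi2LL) * x
        if not 0.0 < s < J_tot:
            return None
        r = _r_from_psi(f_bsPSI, s, J_tot)
        return x / (x + r * (J_LET - x))

    alpha_v1 = alpha_at(A_BS / (P1 + P2))  # v = 1 hence y = 0
    alpha_u1 = alpha_at(J_LET - A_M / (P1 + P2))  # u = 1 hence y = J_CET

    return AlphaScanResult(table=table, interval=interval, alpha_v1=alpha_v1, alpha_u1=alpha_u1)
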