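"""Model inputs, validation and packaged parameter presets.

All quantities use the conventional units of the C4 bioenergetics
literature: chlorophyll content in µmol Chl m⁻² leaf, the extinction
coefficient k in m² (µmol Chl)⁻¹, electron/proton/ATP stoichiometries as
dimensionless mol:mol ratios.  The PSI photochemical efficiency under
limiting light (Phi1LL) is never stored: it is always derived from the
PSII efficiency and the PSII:PSI efficiency ratio, which is the quantity
actually reported by fluorescence studies.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Any

import yaml
from scipy.optimize import brentq

__all__ = [
    "LeafStructure",
    "PhotosystemDistribution",
    "EfficiencyStoichiometry",
    "ParameterPreset",
    "available_presets",
    "load_preset",
    "preset_from_dict",
    "preset_to_dict",
    "read_config",
    "validate_parameters",
    "fit_k",
    "UnknownPresetError",
    "NoRootError",
]


class UnknownPresetError(KeyError):
    """Raised when a preset label is not among the packaged presets."""


class NoRootError(ValueError):
    """Raised when a target absorptance cannot be reached by any k in the bracket."""


@dataclass(frozen=True)
class LeafStructure:
    """Interveinal leaf anatomy and pigment content.

    Parameters
    ----------
    m : float
        Fraction of one unit interveinal distance occupied by the M1
        (interveinal mesophyll) column, open interval (0, 1).
    n_BS : float
        Fraction of leaf depth occupied by the bundle-sheath section of
        the vein column, open interval (0, 1).
    CHL : float
        Leaf chlorophyll content, µmol Chl m⁻².
    f_bsCHL : float
        Fraction of leaf chlorophyll located in bundle-sheath cells.
    k : float
        Light extinction coefficient, m² (µmol Chl)⁻¹.
    """

    m: float = 0.55
    n_BS: float = 0.6
    CHL: float = 475.0
    f_bsCHL: float = 0.33
    k: float = 0.005


@dataclass(frozen=True)
class PhotosystemDistribution:
    """Fractions of the two photosystems residing in bundle-sheath cells."""

    alpha: float = 0.1
    f_bsPSI: float = 0.35


@dataclass(frozen=True)
class EfficiencyStoichiometry:
    """Photochemical efficiencies and proton/ATP coupling ratios.

    ``Phi2LL`` is the PSII electron transport efficiency under strictly
    limiting light (mol e⁻ per mol photon absorbed by PSII antennae);
    ``ratio21`` is Phi2LL/Phi1LL.  ``H_LET`` and ``H_CET`` are protons
    translocated per electron by linear and cyclic electron transport and
    ``h`` is the protons consumed per ATP by the ATP synthase.  The
    defaults assume full Q-cycle operation (H_LET=3, H_CET=2) and h=4,
    for which LET alone delivers ATP:NADPH = 1.5.
    """

    Phi2LL: float = 0.8
    ratio21: float = 0.85
    H_LET: float = 3.0
    H_CET: float = 2.0
    h: float = 4.0

    @property
    def Phi1LL(self) -> float:
        """PSI electron transport efficiency under limiting light (derived)."""
        return self.Phi2LL / self.ratio21


@dataclass(frozen=True)
class ParameterPreset:
    """A complete, named set of structural and photochemical inputs."""

    name: str
    leaf: LeafStructure = field(default_factory=LeafStructure)
    photosystems: PhotosystemDistribution = field(default_factory=PhotosystemDistribution)
    efficiency: EfficiencyStoichiometry = field(default_factory=EfficiencyStoichiometry)


_PRESET_PACKAGE = "c4budget.presets"

# keys understood in flat preset/config dictionaries, mapped to (section, attr)
_FLAT_KEYS = {
    "m": ("leaf", "m"),
    "n_BS": ("leaf", "n_BS"),
    "CHL": ("leaf", "CHL"),
    "f_bsCHL": ("leaf", "f_bsCHL"),
    "k": ("leaf", "k"),
    "alpha": ("photosystems", "alpha"),
    "f_bsPSI": ("photosystems", "f_bsPSI"),
    "Phi2LL": ("efficiency", "Phi2LL"),
    "ratio21": ("efficiency", "ratio21"),
    "H_LET": ("efficiency", "H_LET"),
    "H_CET": ("efficiency", "H_CET"),
    "h": ("efficiency", "h"),
}


def available_presets() -> list[str]:
    """Labels of the presets shipped inside the package."""
    files = resources.files(_PRESET_PACKAGE)
    return sorted(p.name[:-5] for p in files.iterdir() if p.name.endswith(".json"))


def load_preset(name: str) -> ParameterPreset:
    """Load a packaged preset by label.

    Raises
    ------
    UnknownPresetError
        If ``name`` is not a packaged label; the message lists the
        available labels.
    """
    files = resources.files(_PRESET_PACKAGE)
    candidate = files / f"{name}.json"
    if not candidate.is_file():
        raise UnknownPresetError(
            f"unknown preset {name!r}; available: {', '.join(available_presets())}"
        )
    data = json.loads(candidate.read_text())
    return preset_from_dict(data, name=name)


def preset_from_dict(data: dict[str, Any], name: str | None = None) -> ParameterPreset:
    """Build a preset from a flat mapping keyed by the symbol names."""
    sections: dict[str, dict[str, float]] = {"leaf": {}, "photosystems": {}, "efficiency": {}}
    for key, value in data.items():
        if key == "name":
            continue
        if key not in _FLAT_KEYS:
            raise KeyError(f"unknown parameter key {key!r}")
        section, attr = _FLAT_KEYS[key]
        sections[section][attr] = float(value)
    return ParameterPreset(
        name=name or data.get("name", "custom"),
        leaf=LeafStructure(**sections["leaf"]),
        photosystems=PhotosystemDistribution(**sections["photosystems"]),
        efficiency=EfficiencyStoichiometry(**sections["efficiency"]),
    )


def preset_to_dict(preset: ParameterPreset) -> dict[str, Any]:
    """Flatten a preset to the symbol-named key set (inverse of preset_from_dict)."""
    out: dict[str, Any] = {"name": preset.name}
    for key, (section, attr) in _FLAT_KEYS.items():
        out[key] = getattr(getattr(preset, section), attr)
    return out


def read_config(path: str | Path) -> dict[str, Any]:
    """Read a JSON or YAML configuration file into a plain dictionary.

    JSON is valid YAML, so a single YAML parse handles both dialects.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping at top level")
    return data


def validate_parameters(preset: ParameterPreset) -> list[str]:
    """Return the list of violated invariants (empty when the preset is valid).

    This is a report-style contract: it never raises for invalid values,
    so callers can surface every problem at once.
    """
    violations: list[str] = []
    leaf, ps, eff = preset.leaf, preset.photosystems, preset.efficiency
    if not 0.0 < leaf.m < 1.0:
        violations.append(f"m = {leaf.m}: section fraction must lie in the open interval (0, 1)")
    if not 0.0 < leaf.n_BS < 1.0:
        violations.append(f"n_BS = {leaf.n_BS}: depth fraction must lie in the open interval (0, 1)")
    if not leaf.CHL > 0.0:
        violations.append(f"CHL = {leaf.CHL}: chlorophyll content must be positive")
    if not 0.0 <= leaf.f_bsCHL <= 1.0:
        violations.append(f"f_bsCHL = {leaf.f_bsCHL}: fraction out of [0, 1]")
    if not leaf.k >= 0.0:
        violations.append(f"k = {leaf.k}: extinction coefficient must be non-negative")
    if not 0.0 <= ps.alpha <= 1.0:
        violations.append(f"alpha = {ps.alpha}: fraction out of [0, 1]")
    if not 0.0 <= ps.f_bsPSI <= 1.0:
        violations.append(f"f_bsPSI = {ps.f_bsPSI}: fraction out of [0, 1]")
    if not 0.0 < eff.Phi2LL <= 1.0:
        violations.append(f"Phi2LL = {eff.Phi2LL}: efficiency must lie in (0, 1]")
    if not 0.0 < eff.ratio21 <= 1.0:
        violations.append(f"ratio21 = {eff.ratio21}: efficiency ratio must lie in (0, 1]")
    elif eff.Phi2LL > 0 and eff.Phi1LL > 1.0:
        violations.append(
            f"Phi1LL = Phi2LL/ratio21 = {eff.Phi1LL:.4f} > 1: derived PSI efficiency unphysical"
        )
    for attr in ("H_LET", "H_CET", "h"):
        if not getattr(eff, attr) > 0.0:
            violations.append(f"{attr} = {getattr(eff, attr)}: stoichiometric ratio must be positive")
    return violations


def fit_k(
    target_absorptance: float,
    leaf: LeafStructure,
    bracket: tuple[float, float] = (1e-9, 0.02),
    xtol: float = 1e-12,
) -> float:
    """Solve for the extinction coefficient giving a target whole-leaf absorptance.

    The whole-leaf absorptance is a strictly increasing function of k that
    saturates below 1, so a bracketed scalar root solve is exact.  The
    default bracket spans the physically plausible range of k — measured
    broadband values sit near 0.005 m² (µmol Chl)⁻¹, and 0.02 already
    corresponds to near-total absorption at typical chlorophyll contents
    — so unphysical targets (e.g. 0.9999) fail fast instead of returning
    an extinction coefficient no leaf exhibits.

    Raises
    ------
    NoRootError
        If the target is not attainable for k within ``bracket``.
    """
    from .leaf_optics import absorption_cascade  # local import avoids a cycle

    if not 0.0 < target_absorptance < 1.0:
        raise ValueError("target absorptance must lie strictly between 0 and 1")

    def residual(k: float) -> float:
        return absorption_cascade(replace(leaf, k=k)).absorptance - target_absorptance

    lo, hi = bracket
    if residual(lo) > 0.0 or residual(hi) < 0.0:
        raise NoRootError(
            f"absorptance {target_absorptance} not reachable for k in [{lo}, {hi}]"
        )
    return float(brentq(residual, lo, hi, xtol=xtol))
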