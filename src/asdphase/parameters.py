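"""Physical parameter store: pure-component constants and binary interactions.

All quantities are normalized to canonical internal units on load:
kelvin, pascal, joule, mole, kilogram, ångström.  Parameter files (JSON, or a
YAML dialect of the same schema) carry explicit unit strings because published
tables mix kJ and J.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "PureComponent",
    "BinaryInteraction",
    "ParameterSet",
    "ParameterError",
    "UnitError",
    "load_parameters",
    "save_parameters",
    "builtin_fixture",
    "sigma_water",
    "DEFAULT_FIXTURE",
]

#: Name of the packaged parameter fixture (naproxen + venetoclax + PVPVA64 + water).
DEFAULT_FIXTURE = "naproxen_venetoclax_pvpva64"


class ParameterError(ValueError):
    """Schema or referential-integrity violation in a parameter file."""


class UnitError(ParameterError):
    """Unrecognized unit string in a parameter file."""


# --- unit normalization -----------------------------------------------------

_UNIT_FACTORS = {
    # canonical target -> accepted unit strings and multiplicative factors
    "K": {"K": 1.0, "k": 1.0},
    "g/mol": {"g/mol": 1.0, "kg/mol": 1000.0},
    "mol/g": {"mol/g": 1.0, "mol/kg": 1e-3},
    "angstrom": {"angstrom": 1.0, "A": 1.0, "Å": 1.0, "nm": 10.0},
    "J/mol": {"J/mol": 1.0, "kJ/mol": 1000.0},
    "J/mol/K": {"J/mol/K": 1.0, "kJ/mol/K": 1000.0, "J/(mol K)": 1.0},
    "kg/m^3": {"kg/m^3": 1.0, "kg/m3": 1.0, "g/cm^3": 1000.0, "g/cm3": 1000.0},
    "1/K": {"1/K": 1.0, "K^-1": 1.0},
    "dimensionless": {"dimensionless": 1.0, "": 1.0},
}


def _quantity(raw, target_unit: str, fieldname: str):
    """Normalize a ``{"value":..,"unit":..}`` mapping (or bare number) to the
    canonical unit.  Temperature offsets (°C) are handled explicitly."""
    if raw is None:
        return None
    if isinstance(raw, (int, float)):
        return float(raw)
    if not isinstance(raw, Mapping) or "value" not in raw:
        raise ParameterError(f"field {fieldname!r}: expected number or value/unit mapping, got {raw!r}")
    value = float(raw["value"])
    unit = str(raw.get("unit", ""))
    if target_unit == "K" and unit in ("C", "degC", "°C"):
        return value + 273.15
    try:
        factor = _UNIT_FACTORS[target_unit][unit]
    except KeyError:
        raise UnitError(f"field {fieldname!r}: unit {unit!r} not recognized (expected {target_unit})") from None
    return value * factor


# --- water segment diameter -------------------------------------------------

#: Coefficients of the temperature-dependent water segment diameter,
#: σ(T) = c0 + c1·exp(c2·T) + c3·exp(c4·T) with T in kelvin, σ in Å.
WATER_SIGMA_COEFFS = (2.7927, 10.11, -0.01755, -1.417, -0.01146)


def sigma_water(T: float, coefficients: Sequence[float] = WATER_SIGMA_COEFFS) -> float:
    """Temperature-dependent segment diameter of water in Å (T in kelvin)."""
    if T <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    c0, c1, c2, c3, c4 = coefficients
    return c0 + c1 * math.exp(c2 * T) + c3 * math.exp(c4 * T)


# --- domain types -----------------------------------------------------------

@dataclass(frozen=True)
class PureComponent:
    """All per-substance constants: PC-SAFT parameters, melting properties,
    true density and glass-transition temperature.

    ``segment_diameter`` is either a fixed value in Å or ``None`` when the
    component uses the temperature-dependent water expression (then
    ``sigma_coefficients`` holds the exponential coefficients).
    ``melting_T``/``melting_enthalpy`` must be present together; ``delta_cp``
    may be absent alone (its term is then dropped from the solubility
    equation).
    """

    name: str
    molar_mass: float            # g/mol
    segment_ratio: float         # mol/g  (segments per gram, m_seg/M)
    segment_diameter: float | None  # Å; None => temperature-dependent
    dispersion_energy: float     # K  (u/kB)
    assoc_energy: float = 0.0    # K  (eps_AB/kB)
    assoc_volume: float = 0.0    # dimensionless (kappa_AB)
    assoc_sites: tuple[int, int] = (0, 0)  # (donor, acceptor) counts
    melting_T: float | None = None         # K
    melting_enthalpy: float | None = None  # J/mol
    delta_cp: float | None = None          # J/mol/K
    density: float | None = None           # kg/m^3
    glass_T: float | None = None           # K
    sigma_coefficients: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.molar_mass <= 0:
            raise ParameterError(f"{self.name}: molar_mass must be > 0")
        if self.segment_ratio <= 0:
            raise ParameterError(f"{self.name}: segment_ratio must be > 0")
        if self.segment_diameter is not None and self.segment_diameter <= 0:
            raise ParameterError(f"{self.name}: segment_diameter must be > 0")
        if self.segment_diameter is None and self.sigma_coefficients is None:
            raise ParameterError(f"{self.name}: segment_diameter missing and no formula given")
        if self.dispersion_energy <= 0:
            raise ParameterError(f"{self.name}: dispersion_energy must be > 0")
        if min(self.assoc_sites) < 0:
            raise ParameterError(f"{self.name}: assoc_sites counts must be >= 0")
        if (self.melting_T is None) != (self.melting_enthalpy is None):
            raise ParameterError(
                f"{self.name}: melting_T and melting_enthalpy must be present together")

    @property
    def segments(self) -> float:
        """Number of PC-SAFT segments m_i = (m/M)·M."""
        return self.segment_ratio * self.molar_mass

    @property
    def associating(self) -> bool:
        return min(self.assoc_sites) > 0 or max(self.assoc_sites) > 0

    def sigma(self, T: float) -> float:
        """Segment diameter in Å at temperature T (kelvin)."""
        if self.segment_diameter is not None:
            return self.segment_diameter
        return sigma_water(T, self.sigma_coefficients)


def _norm_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class BinaryInteraction:
    """Temperature-dependent binary dispersion correction
    k_ij(T) = kij_m · T + kij_b for one unordered component pair."""

    pair: tuple[str, str]
    kij_m: float  # 1/K
    kij_b: float  # dimensionless

    def __post_init__(self):
        object.__setattr__(self, "pair", _norm_pair(*self.pair))

    def kij(self, T: float) -> float:
        if T <= 0:
            raise ValueError("temperature must be positive (kelvin)")
        if self.pair[0] == self.pair[1]:
            return 0.0
        return self.kij_m * T + self.kij_b


def kij(interaction: BinaryInteraction, T: float) -> float:
    """Evaluate k_ij(T) = kij_m·T + kij_b (self-pairs are identically zero)."""
    return interaction.kij(T)


@dataclass
class ParameterSet:
    """A registry of pure components plus their pairwise interactions.

    Looking up a pair that was never registered raises ``ParameterError``
    rather than silently assuming k_ij = 0.
    """

    components: dict[str, PureComponent] = field(default_factory=dict)
    interactions: dict[tuple[str, str], BinaryInteraction] = field(default_factory=dict)
    provenance: str = ""

    def add_component(self, comp: PureComponent) -> None:
        self.components[comp.name] = comp

    def add_interaction(self, inter: BinaryInteraction) -> None:
        for name in inter.pair:
            if name not in self.components:
                raise ParameterError(
                    f"interaction {inter.pair} references unknown component {name!r}")
        self.interactions[inter.pair] = inter

    def component(self, name: str) -> PureComponent:
        try:
            return self.components[name]
        except KeyError:
            raise ParameterError(f"component {name!r} not registered") from None

    def interaction(self, a: str, b: str) -> BinaryInteraction:
        if a == b:
            return BinaryInteraction((a, b), 0.0, 0.0)
        key = _norm_pair(a, b)
        try:
            return self.interactions[key]
        except KeyError:
            raise ParameterError(f"no interaction registered for pair {key}") from None

    def kij(self, a: str, b: str, T: float) -> float:
        return self.interaction(a, b).kij(T)


# --- load / save ------------------------------------------------------------

def _component_from_raw(raw: Mapping) -> PureComponent:
    name = raw.get("name")
    if not name:
        raise ParameterError("component without a name")
    sd_raw = raw.get("segment_diameter")
    sigma_coeffs = None
    if isinstance(sd_raw, Mapping) and "formula" in sd_raw:
        if sd_raw["formula"] != "water_exponential":
            raise ParameterError(f"{name}: unknown segment-diameter formula {sd_raw['formula']!r}")
        sigma_coeffs = tuple(float(c) for c in sd_raw.get("coefficients", WATER_SIGMA_COEFFS))
        segment_diameter = None
    else:
        segment_diameter = _quantity(sd_raw, "angstrom", f"{name}.segment_diameter")
    sites_raw = raw.get("assoc_sites") or [0, 0]
    if isinstance(sites_raw, str):  # "2/2" shorthand
        sites_raw = sites_raw.split("/")
    sites = tuple(int(s) for s in sites_raw)
    if len(sites) != 2:
        raise ParameterError(f"{name}: assoc_sites must be a (donor, acceptor) pair")
    kappa = raw.get("assoc_volume")
    eps = _quantity(raw.get("assoc_energy"), "K", f"{name}.assoc_energy") or 0.0
    return PureComponent(
        name=name,
        molar_mass=_quantity(raw.get("molar_mass"), "g/mol", f"{name}.molar_mass"),
        segment_ratio=_quantity(raw.get("segment_ratio"), "mol/g", f"{name}.segment_ratio"),
        segment_diameter=segment_diameter,
        dispersion_energy=_quantity(raw.get("dispersion_energy"), "K", f"{name}.dispersion_energy"),
        assoc_energy=eps,
        assoc_volume=0.0 if kappa is None else float(kappa),
        assoc_sites=sites,
        melting_T=_quantity(raw.get("melting_T"), "K", f"{name}.melting_T"),
        melting_enthalpy=_quantity(raw.get("melting_enthalpy"), "J/mol", f"{name}.melting_enthalpy"),
        delta_cp=_quantity(raw.get("delta_cp"), "J/mol/K", f"{name}.delta_cp"),
        density=_quantity(raw.get("density"), "kg/m^3", f"{name}.density"),
        glass_T=_quantity(raw.get("glass_T"), "K", f"{name}.glass_T"),
        sigma_coefficients=sigma_coeffs,
    )


def _parse(raw: Mapping) -> ParameterSet:
    if "components" not in raw:
        raise ParameterError("parameter file lacks a 'components' list")
    pset = ParameterSet(provenance=str(raw.get("provenance", "")))
    for comp_raw in raw["components"]:
        pset.add_component(_component_from_raw(comp_raw))
    for inter_raw in raw.get("interactions", []):
        pair = inter_raw.get("pair")
        if not pair or len(pair) != 2:
            raise ParameterError(f"interaction needs a two-element 'pair', got {pair!r}")
        pset.add_interaction(BinaryInteraction(
            pair=tuple(pair),
            kij_m=_quantity(inter_raw.get("kij_m", 0.0), "1/K", f"{pair}.kij_m") or 0.0,
            kij_b=float(inter_raw.get("kij_b", 0.0)),
        ))
    return pset


def load_parameters(path: str | Path) -> ParameterSet:
    """Load a parameter set from a JSON (or YAML) file, or by fixture name."""
    p = Path(path)
    if not p.exists():
        # allow bare fixture names
        try:
            return builtin_fixture(str(path))
        except KeyError:
            raise FileNotFoundError(f"no such parameter file or fixture: {path}") from None
    text = p.read_text()
    if p.suffix.lower() in (".yaml", ".yml"):
        import yaml
        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    return _parse(raw)


def builtin_fixture(name: str = DEFAULT_FIXTURE) -> ParameterSet:
    """Resolve a packaged parameter fixture by name, without any path."""
    ref = resources.files("asdphase").joinpath(f"data/{name}.json")
    if not ref.is_file():
        raise KeyError(f"no packaged fixture named {name!r}")
    return _parse(json.loads(ref.read_text()))


def _component_to_raw(c: PureComponent) -> dict:
    if c.segment_diameter is None:
        sd = {"formula": "water_exponential", "coefficients": list(c.sigma_coefficients),
              "unit": "angstrom"}
    else:
        sd = {"value": c.segment_diameter, "unit": "angstrom"}
    def q(v, u):
        return None if v is None else {"value": v, "unit": u}
    return {
        "name": c.name,
        "molar_mass": q(c.molar_mass, "g/mol"),
        "segment_ratio": q(c.segment_ratio, "mol/g"),
        "segment_diameter": sd,
        "dispersion_energy": q(c.dispersion_energy, "K"),
        "assoc_energy": q(c.assoc_energy, "K"),
        "assoc_volume": c.assoc_volume,
        "assoc_sites": list(c.assoc_sites),
        "melting_T": q(c.melting_T, "K"),
        "melting_enthalpy": q(c.melting_enthalpy, "J/mol"),
        "delta_cp": q(c.delta_cp, "J/mol/K"),
        "density": q(c.density, "kg/m^3"),
        "glass_T": q(c.glass_T, "K"),
    }


def save_parameters(pset: ParameterSet, path: str | Path) -> None:
    """Write a parameter set back out in the canonical JSON schema."""
    raw = {
        "provenance": pset.provenance,
        "components": [_component_to_raw(c) for c in pset.components.values()],
        "interactions": [
            {"pair": list(i.pair), "kij_m": {"value": i.kij_m, "unit": "1/K"}, "kij_b": i.kij_b}
            for i in pset.interactions.values()
        ],
    }
    Path(path).write_text(json.dumps(raw, indent=2) + "\n")
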