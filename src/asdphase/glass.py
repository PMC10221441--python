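"""Gordon–Taylor glass-transition of API/polymer/water mixtures and the
escape-glass-transition (eGT) locus.

The mixture glass transition is the mass-fraction-weighted mean

    Tg = Σ K_i w_i Tg_i / Σ K_i w_i

with the Simha–Boyer coefficients K_i = (ρ_ref · Tg_ref)/(ρ_i · Tg_i),
referenced to the polymer (so K_polymer = 1; the equation is invariant under
uniform rescaling of all K, making the reference choice presentational).
Temperatures inside the mixing rule are kelvin.

The eGT composition on a hydration path is the water content at which the
mixture Tg equals the dissolution-medium temperature: below it the surface
layer is glassy (a gel layer); beyond it the layer escapes into solution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .parameters import PureComponent

__all__ = [
    "GlassState", "simha_boyer_K", "gordon_taylor_tg",
    "egt_water_content", "egt_locus",
]


@dataclass
class GlassState:
    """Mixture glass transition with the coefficients that produced it."""
    mass_fractions: np.ndarray
    Tg_mix: float                 # K
    K_coefficients: np.ndarray    # dimensionless, reference component K = 1


def simha_boyer_K(component: PureComponent, reference: PureComponent) -> float:
    """K_i = (ρ_ref Tg_ref)/(ρ_i Tg_i), temperatures in kelvin."""
    for c in (component, reference):
        if not c.density or c.density <= 0 or not c.glass_T or c.glass_T <= 0:
            raise ValueError(f"{c.name}: positive density and glass_T required")
    return (reference.density * reference.glass_T) / (component.density * component.glass_T)


def gordon_taylor_tg(mass_fractions, components: Sequence[PureComponent],
                     reference: PureComponent | None = None) -> float:
    """Mixture glass-transition temperature in kelvin.

    ``reference`` defaults to the component named PVPVA64 if present, else the
    first component; the choice only rescales all K uniformly and cancels.
    """
    w = np.asarray(mass_fractions, dtype=float)
    if w.min() < -1e-12 or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("mass fractions must be a valid simplex point")
    if reference is None:
        reference = next((c for c in components if c.name == "PVPVA64"),
                         components[0])
    K = np.array([simha_boyer_K(c, reference) for c in components])
    Tg = np.array([c.glass_T for c in components])
    return float(np.sum(K * w * Tg) / np.sum(K * w))


def glass_state(mass_fractions, components: Sequence[PureComponent],
                reference: PureComponent | None = None) -> GlassState:
    if reference is None:
        reference = next((c for c in components if c.name == "PVPVA64"),
                         components[0])
    K = np.array([simha_boyer_K(c, reference) for c in components])
    return GlassState(mass_fractions=np.asarray(mass_fractions, dtype=float),
                      Tg_mix=gordon_taylor_tg(mass_fractions, components, reference),
                      K_coefficients=K)


def egt_water_content(drug_load: float, T_medium: float,
                      components: Sequence[PureComponent],
                      tol: float = 1e-10):
    """Water mass fraction w* at which the fixed-drug-load hydration line
    reaches Tg = T_medium.

    ``components`` is the ordered (API, polymer, water) triple; ``drug_load``
    is the API mass fraction on the water-free basis.  Returns ``(w*, True)``
    or ``(0.0, False)`` when the dry blend is already at or below the medium
    temperature (no glassy gel layer forms).
    """
    if not 0.0 <= drug_load < 1.0:
        raise ValueError("drug load must be in [0, 1)")

    def tg_at(w_water):
        w = np.array([drug_load * (1 - w_water), (1 - drug_load) * (1 - w_water),
                      w_water])
        return gordon_taylor_tg(w, components)

    if tg_at(0.0) <= T_medium:
        return 0.0, False
    lo, hi = 0.0, 0.999
    if tg_at(hi) > T_medium:
        return hi, False
    # Tg decreases monotonically toward pure water: plain bisection
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if tg_at(mid) > T_medium:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi), True


def egt_locus(T_medium: float, components: Sequence[PureComponent],
              drug_loads) -> list:
    """One (mass-fraction composition, Tg) pair per drug load where the
    mixture Tg equals the medium temperature."""
    out = []
    for dl in np.atleast_1d(np.asarray(drug_loads, dtype=float)):
        w_star, ok = egt_water_content(float(dl), T_medium, components)
        w = np.array([dl * (1 - w_star), (1 - dl) * (1 - w_star), w_star])
        out.append((w, gordon_taylor_tg(w, components)))
    return out
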