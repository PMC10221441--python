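"""Solid-liquid and liquid-liquid equilibria for API/polymer/water systems.

Conventions
-----------
* All equilibrium equations are solved in mole-fraction space, where the
  saturation and isoactivity relations are stated; results are reported in
  mass fractions.  Because the polymer is a 65 kg/mol pseudo-component its
  mole fractions are O(1e-5), so solvers work in log-mole-fraction variables
  and each phase eliminates its *largest* component to avoid cancellation in
  the small ones.
* Saturation: x_API·γ_API = exp(-Δh/(RT)·(1-T/Tm) - Δcp/R·(ln(Tm/T)-Tm/T+1)),
  the Δcp term being dropped exactly when Δcp is not tabulated.
* Coexistence: x_i·γ_i equal across phases for every component, verified a
  posteriori by a tangent-plane stability test.
* Pressure is fixed by the caller (0.1 MPa for all reported results).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .parameters import ParameterSet, PureComponent
from .pcsaft import Mixture, NumericalError

__all__ = [
    "R_GAS", "TernarySystem", "SolubilityPoint", "TieLine", "TernaryDiagram",
    "ideal_solubility", "ln_saturation_activity", "sle_solubility",
    "path_solubility_crossing", "stability_test", "lle_flash", "binary_lle",
    "path_binodal_crossing", "trace_binodal", "spinodal_locus",
    "compute_diagram", "round_half_up",
]

R_GAS = 8.314462618  # J/(mol K)

API, POLY, WATER = 0, 1, 2  # canonical component order


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention of the reported tables)."""
    factor = 10.0 ** decimals
    return math.floor(abs(value) * factor + 0.5) / factor * (1 if value >= 0 else -1)


@dataclass
class TernarySystem:
    """Ordered (API, polymer, water) triple with its pair interactions."""

    pset: ParameterSet
    api: str
    polymer: str
    water: str = "water"

    def __post_init__(self):
        self.names = (self.api, self.polymer, self.water)
        self.mixture = Mixture(self.pset, self.names)
        self.api_component: PureComponent = self.pset.component(self.api)

    def mass_to_mole(self, w):
        return self.mixture.mass_to_mole(w)

    def mole_to_mass(self, x):
        return self.mixture.mole_to_mass(x)

    def path_mass(self, drug_load: float, w_water: float) -> np.ndarray:
        """Mass-fraction composition on the straight hydration path."""
        return np.array([drug_load * (1.0 - w_water),
                         (1.0 - drug_load) * (1.0 - w_water), w_water])


@dataclass
class SolubilityPoint:
    T: float
    w: np.ndarray          # mass fractions (API, polymer, water)
    x: np.ndarray          # mole fractions
    residual: float        # saturation-equation residual (ln units)


@dataclass
class TieLine:
    w1: np.ndarray  # polymer-rich / first phase, mass fractions
    w2: np.ndarray  # API-rich / second phase, mass fractions
    x1: np.ndarray
    x2: np.ndarray
    isoactivity_residual: float


@dataclass
class TernaryDiagram:
    """Computed loci of one system at fixed T, P (mass fractions)."""
    system: TernarySystem
    T: float
    P: float
    solubility_locus: list = field(default_factory=list)   # SolubilityPoint
    binodal_locus: list = field(default_factory=list)      # np.ndarray rows
    tie_lines: list = field(default_factory=list)          # TieLine
    spinodal_locus: list = field(default_factory=list)     # np.ndarray rows
    egt_locus: list = field(default_factory=list)          # (w, Tg) rows

    def to_frame(self):
        import pandas as pd
        rows = []
        for p in self.solubility_locus:
            rows.append(("solubility", *p.w, "", ""))
        for i, t in enumerate(self.tie_lines):
            rows.append(("binodal", *t.w1, "", i))
            rows.append(("binodal", *t.w2, "", i))
        for w in self.binodal_locus:
            rows.append(("binodal_locus", *w, "", ""))
        for w in self.spinodal_locus:
            rows.append(("spinodal", *w, "", ""))
        for w, tg in self.egt_locus:
            rows.append(("egt", *w, round_half_up(tg - 273.15, 1), ""))
        return pd.DataFrame(rows, columns=[
            "locus_type", "w_api", "w_polymer", "w_water", "Tg_celsius", "tie_id"])

    def to_json(self) -> str:
        return json.dumps({
            "T_kelvin": self.T, "P_pascal": self.P,
            "components": list(self.system.names),
            "solubility": [list(map(float, p.w)) for p in self.solubility_locus],
            "binodal": [list(map(float, w)) for w in self.binodal_locus],
            "tie_lines": [{"phase_polymer_rich": list(map(float, t.w1)),
                           "phase_api_rich": list(map(float, t.w2))}
                          for t in self.tie_lines],
            "spinodal": [list(map(float, w)) for w in self.spinodal_locus],
            "egt": [{"w": list(map(float, w)), "Tg_K": float(tg)}
                    for w, tg in self.egt_locus],
        }, indent=1)


# --- solid-liquid equilibrium ----------------------------------------------

def ln_saturation_activity(component: PureComponent, T: float) -> float:
    """ln(x·γ) of the saturated liquid against the pure crystal."""
    if component.melting_T is None:
        raise ValueError(f"{component.name}: melting properties absent")
    tm, dh = component.melting_T, component.melting_enthalpy
    val = -dh / (R_GAS * T) * (1.0 - T / tm)
    if component.delta_cp is not None:
        val -= component.delta_cp / R_GAS * (math.log(tm / T) - tm / T + 1.0)
    return val


def ideal_solubility(component: PureComponent, T: float) -> float:
    """Mole-fraction solubility with γ = 1 (Δcp term only when tabulated)."""
    return math.exp(ln_saturation_activity(component, T))


class _Phase:
    """Warm-started activity evaluations for one persistent phase."""

    def __init__(self, mixture: Mixture, T: float, P: float):
        self.mixture, self.T, self.P = mixture, T, P
        self.rho = None

    def lngamma(self, x):
        lg, rho = self.mixture.lngamma(self.T, self.P, x, rho0=self.rho)
        self.rho = rho
        return lg


def sle_solubility(system: TernarySystem, T: float, P: float,
                   solvent_ratio: float = math.inf) -> SolubilityPoint:
    """Saturated API content in a polymer/water solvent of fixed mass ratio.

    ``solvent_ratio`` is the polymer:water mass ratio of the API-free solvent
    (``inf`` = dry polymer, ``0`` = pure water).
    """
    ln_asat = ln_saturation_activity(system.api_component, T)
    if math.isinf(solvent_ratio):
        fp, fw = 1.0, 0.0
    else:
        fp = solvent_ratio / (1.0 + solvent_ratio)
        fw = 1.0 - fp
    ph = _Phase(system.mixture, T, P)

    def resid(w_api):
        w = np.array([w_api, (1 - w_api) * fp, (1 - w_api) * fw])
        x = system.mass_to_mole(w)
        lg = ph.lngamma(x)
        return math.log(x[API]) + lg[API] - ln_asat

    lo, hi = 1e-10, 1.0 - 1e-10
    flo, fhi = resid(lo), resid(hi)
    if flo > 0 or fhi < 0:
        raise NumericalError("saturation equation has no bracketed root")
    w_api = brentq(resid, lo, hi, xtol=1e-12, rtol=1e-12)
    w = np.array([w_api, (1 - w_api) * fp, (1 - w_api) * fw])
    return SolubilityPoint(T=T, w=w, x=system.mass_to_mole(w),
                           residual=resid(w_api))


def path_solubility_crossing(system: TernarySystem, T: float, P: float,
                             drug_load: float):
    """First water content at which the hydration path reaches saturation.

    Returns ``(w_water, SolubilityPoint)`` or ``("supersaturated", None)``
    when the dry ASD already exceeds the solubility, or ``(None, None)`` when
    the path never saturates.
    """
    ln_asat = ln_saturation_activity(system.api_component, T)
    ph = _Phase(system.mixture, T, P)

    def margin(a):
        w = system.path_mass(drug_load, a)
        x = system.mass_to_mole(w)
        lg = ph.lngamma(x)
        return math.log(x[API]) + lg[API] - ln_asat

    if margin(0.0) > 0:
        return "supersaturated", None
    grid = np.linspace(0.0, 0.99, 45)
    prev = margin(grid[0])
    for a0, a1 in zip(grid[:-1], grid[1:]):
        cur = margin(a1)
        if prev <= 0 < cur or (prev < 0 <= cur):
            a = brentq(margin, a0, a1, xtol=1e-11)
            w = system.path_mass(drug_load, a)
            pt = SolubilityPoint(T=T, w=w, x=system.mass_to_mole(w),
                                 residual=margin(a))
            return a, pt
        prev = cur
    return None, None


def solubility_locus(system: TernarySystem, T: float, P: float,
                     n: int = 40) -> list:
    """Solubility line from the dry polymer edge toward the water corner,
    parameterized by the water fraction of the API-free solvent."""
    pts = []
    for s in np.linspace(0.0, 1.0, n):
        ratio = math.inf if s == 0 else (1.0 - s) / s
        try:
            pts.append(sle_solubility(system, T, P, solvent_ratio=ratio))
        except NumericalError:
            continue
    return pts


# --- stability (tangent-plane distance) -------------------------------------

def stability_test(system: TernarySystem, T: float, P: float, x,
                   n_iter: int = 120, seeds: Sequence | None = None):
    """Michelsen-style tangent-plane stability analysis.

    Returns ``(stable: bool, trial_x or None, tpd)``; the trial composition of
    an unstable feed can seed a flash.
    """
    mix = system.mixture
    x = np.clip(np.asarray(x, dtype=float), 1e-16, None)
    x = x / x.sum()
    ph_feed = _Phase(mix, T, P)
    d = np.log(x) + ph_feed.lngamma(x)
    if seeds is None:
        seeds = []
        for k in range(3):
            s = np.full(3, 0.02)
            s[k] = 0.96
            seeds.append(s)
        seeds.append(np.array([0.98, 1e-6, 0.02 - 1e-6]))  # API-rich, polymer-free
        seeds.append(np.array([0.02, 1e-6, 0.98]))         # water-rich, polymer-free
    best = (True, None, 0.0)
    for s in seeds:
        W = np.clip(np.asarray(s, dtype=float), 1e-250, None)
        ph = _Phase(mix, T, P)
        failed = False
        for _ in range(n_iter):
            y = np.clip(W / W.sum(), 1e-250, None)
            try:
                lg = ph.lngamma(y)
            except NumericalError:
                failed = True
                break
            lnW_new = np.clip(d - lg, -500.0, 500.0)
            W_new = np.exp(lnW_new)
            if not np.all(np.isfinite(W_new)):
                failed = True
                break
            if np.max(np.abs(lnW_new - np.log(W))) < 1e-10:
                W = W_new
                break
            W = W_new
            if _ > 6:
                tm_est = 1.0 + float(np.sum(W * (lnW_new + lg - d - 1.0)))
                if tm_est < -1e-3:
                    break   # clearly unstable; stop polishing
        if failed:
            continue
        y = np.clip(W / W.sum(), 1e-250, None)
        try:
            lg = ph.lngamma(y)
        except NumericalError:
            continue
        tm = 1.0 + float(np.sum(W * (np.log(W) + lg - d - 1.0)))
        if tm < best[2] - 1e-12:
            best = (False, y, tm)
    stable = best[2] > -1e-7
    return (stable, None if stable else best[1], best[2])


# --- liquid-liquid equilibrium ----------------------------------------------

def _phase_vars(x, free_idx):
    return np.log(np.clip(x[list(free_idx)], 1e-300, None))


def _phase_from_vars(v, free_idx):
    x = np.zeros(3)
    x[list(free_idx)] = np.exp(v)
    dep = ({0, 1, 2} - set(free_idx)).pop()
    x[dep] = 1.0 - x[list(free_idx)].sum()
    return x, dep


def _choose_free(x):
    """Free variables are the two smallest mole fractions (log-space)."""
    order = np.argsort(x)
    return tuple(sorted(order[:2]))


def _isoactivity_residual(mix, T, P, x1, x2, ph1, ph2):
    lg1 = ph1.lngamma(x1)
    lg2 = ph2.lngamma(x2)
    return (np.log(np.clip(x1, 1e-300, None)) + lg1
            - np.log(np.clip(x2, 1e-300, None)) - lg2)


def lle_flash(system: TernarySystem, T: float, P: float, feed,
              guess: tuple | None = None, max_iter: int = 80) -> TieLine:
    """Two-phase isoactivity split of an unstable feed (mole fractions).

    Solves the four-unknown system (two log-mole-fraction coordinates per
    phase) for the three isoactivity equations plus collinearity of the feed
    with the phase compositions; converged phases are checked against the
    trivial root and for a physical lever fraction.
    """
    mix = system.mixture
    feed = np.asarray(feed, dtype=float)
    if guess is None:
        stable, trial, tpd = stability_test(system, T, P, feed)
        if stable:
            raise NumericalError("feed is single-phase (stability test)")
        x2 = trial
        x1 = np.clip(feed + 0.3 * (feed - trial * feed.sum()), 1e-12, None)
        x1 = x1 / x1.sum()
        guess = (x1, x2)
    x1, x2 = (np.asarray(g, dtype=float) for g in guess)
    f1, f2 = _choose_free(x1), _choose_free(x2)
    ph1, ph2 = _Phase(mix, T, P), _Phase(mix, T, P)
    u = np.concatenate([_phase_vars(x1, f1), _phase_vars(x2, f2)])

    def residual(u):
        y1, _ = _phase_from_vars(u[:2], f1)
        y2, _ = _phase_from_vars(u[2:], f2)
        if y1.min() < 0 or y2.min() < 0:
            return None, None, None
        iso = _isoactivity_residual(mix, T, P, y1, y2, ph1, ph2)
        # collinearity of feed with the tie line in the (x_API, x_water) plane
        v1, v2 = y1 - feed, y2 - feed
        col = v1[API] * v2[WATER] - v1[WATER] * v2[API]
        return np.concatenate([iso, [col * 50.0]]), y1, y2

    F, y1, y2 = residual(u)
    if F is None:
        raise NumericalError("flash guess outside the simplex")
    for it in range(max_iter):
        if np.max(np.abs(F)) < 1e-10:
            break
        J = np.zeros((4, 4))
        for k in range(4):
            du = np.zeros(4)
            du[k] = 1e-6
            Fp, _, _ = residual(u + du)
            if Fp is None:
                Fp, _, _ = residual(u - du)
                J[:, k] = (F - Fp) / 1e-6
            else:
                J[:, k] = (Fp - F) / 1e-6
        try:
            step = np.linalg.solve(J, F)
        except np.linalg.LinAlgError:
            raise NumericalError("singular Jacobian in flash")
        lam = 1.0
        for _ in range(8):
            Fn, y1n, y2n = residual(u - lam * step)
            if Fn is not None and np.max(np.abs(Fn)) < np.max(np.abs(F)) * (1 - 1e-4 * lam) + 1e-14:
                u = u - lam * step
                F, y1, y2 = Fn, y1n, y2n
                break
            lam *= 0.5
        else:
            u = u - 0.1 * step
            F, y1, y2 = residual(u)
            if F is None:
                raise NumericalError("flash line search failed")
    else:
        raise NumericalError("flash did not converge")
    w1, w2 = system.mole_to_mass(y1), system.mole_to_mass(y2)
    if np.max(np.abs(w1 - w2)) < 1e-4:
        raise NumericalError("flash converged to the trivial root")
    iso = _isoactivity_residual(mix, T, P, y1, y2, ph1, ph2)
    res = float(np.max(np.abs(np.exp(np.log(np.clip(y1, 1e-300, None))
                                     + ph1.lngamma(y1))
                              - np.exp(np.log(np.clip(y2, 1e-300, None))
                                       + ph2.lngamma(y2)))))
    # order phases: polymer-rich first
    if w1[POLY] < w2[POLY]:
        y1, y2, w1, w2 = y2, y1, w2, w1
    return TieLine(w1=w1, w2=w2, x1=y1, x2=y2, isoactivity_residual=res)


def binary_lle(system: TernarySystem, T: float, P: float,
               absent: int = WATER, n_grid: int = 120):
    """LLE of one binary face of the triangle (``absent`` component at zero).

    A Gibbs-energy grid with a convex-hull double-tangent construction seeds a
    Newton solve of the two isoactivity equations.  Returns a TieLine (with a
    zero entry for the absent component) or ``None`` if the face is miscible.
    """
    mix = system.mixture
    pres = [i for i in range(3) if i != absent]
    ph = _Phase(mix, T, P)

    def comp(xa):
        x = np.zeros(3)
        x[pres[0]] = xa
        x[pres[1]] = 1.0 - xa
        return x

    xs = np.linspace(1e-6, 1 - 1e-6, n_grid)
    # log-spaced refinement near both ends (polymer dilution is extreme)
    xs = np.unique(np.concatenate([xs, np.geomspace(1e-10, 0.02, 25),
                                   1 - np.geomspace(1e-10, 0.02, 25)]))
    g = np.empty(len(xs))
    for i, xa in enumerate(xs):
        x = comp(xa)
        lg = ph.lngamma(x)
        g[i] = (xa * (math.log(xa) + lg[pres[0]])
                + (1 - xa) * (math.log(1 - xa) + lg[pres[1]]))
    # lower convex envelope in (x, g) by monotone chain
    lower_sorted: list[int] = []
    for i in range(len(xs)):
        while len(lower_sorted) >= 2:
            i0, i1 = lower_sorted[-2], lower_sorted[-1]
            cross = ((xs[i1] - xs[i0]) * (g[i] - g[i0])
                     - (g[i1] - g[i0]) * (xs[i] - xs[i0]))
            if cross <= 0:   # middle point is not below the chord
                lower_sorted.pop()
            else:
                break
        lower_sorted.append(i)
    gaps = []
    for i0, i1 in zip(lower_sorted[:-1], lower_sorted[1:]):
        mid = 0.5 * (xs[i0] + xs[i1])
        # only count as a miscibility gap if interior grid points lie above the chord
        interior = (xs > xs[i0] + 1e-12) & (xs < xs[i1] - 1e-12)
        if not interior.any():
            continue
        chord = g[i0] + (g[i1] - g[i0]) * (xs[interior] - xs[i0]) / (xs[i1] - xs[i0])
        if np.max(g[interior] - chord) > 1e-9:
            gaps.append((xs[i1] - xs[i0], xs[i0], xs[i1]))
    if not gaps:
        return None
    _, xa1, xa2 = max(gaps)

    # Each phase is parameterized by the log mole fraction of its *minor*
    # component: the conjugate of a polymer-rich phase can hold polymer at
    # mole fractions far below 1e-16, unreachable in a logit of the major one.
    minor1 = pres[1] if xa1 > 0.5 else pres[0]
    minor2 = pres[1] if xa2 > 0.5 else pres[0]

    def comp_minor(minor, ln_xm):
        x = np.zeros(3)
        xm = math.exp(min(ln_xm, -1e-12))
        x[minor] = xm
        other = pres[0] if minor == pres[1] else pres[1]
        x[other] = 1.0 - xm
        return x

    ph1, ph2 = _Phase(mix, T, P), _Phase(mix, T, P)

    def residual(v):
        y1 = comp_minor(minor1, v[0])
        y2 = comp_minor(minor2, v[1])
        iso = _isoactivity_residual(mix, T, P, y1, y2, ph1, ph2)
        return np.array([iso[pres[0]], iso[pres[1]]]), y1, y2

    v = np.array([
        math.log((1 - xa1) if minor1 == pres[1] else xa1),
        math.log((1 - xa2) if minor2 == pres[1] else xa2)])
    F, y1, y2 = residual(v)
    for it in range(80):
        if np.max(np.abs(F)) < 1e-10:
            break
        J = np.zeros((2, 2))
        for k in range(2):
            dv = np.zeros(2)
            dv[k] = 1e-6
            Fp, _, _ = residual(v + dv)
            J[:, k] = (Fp - F) / 1e-6
        try:
            step = np.linalg.solve(J, F)
        except np.linalg.LinAlgError:
            raise NumericalError("singular Jacobian in binary LLE")
        step = np.clip(step, -20.0, 20.0)
        lam = 1.0
        while lam > 1e-4:
            Fn, y1n, y2n = residual(v - lam * step)
            if np.max(np.abs(Fn)) < np.max(np.abs(F)) + 1e-14:
                v, F, y1, y2 = v - lam * step, Fn, y1n, y2n
                break
            lam *= 0.5
        else:
            break
    else:
        raise NumericalError("binary LLE Newton did not converge")
    if np.max(np.abs(F)) > 1e-8:
        raise NumericalError("binary LLE Newton did not converge")
    if abs(y1[pres[0]] - y2[pres[0]]) < 1e-6:
        return None
    w1, w2 = system.mole_to_mass(y1), system.mole_to_mass(y2)
    res = float(np.max(np.abs(F)))
    if w1[POLY] < w2[POLY]:
        y1, y2, w1, w2 = y2, y1, w2, w1
    return TieLine(w1=w1, w2=w2, x1=y1, x2=y2, isoactivity_residual=res)


def path_binodal_crossing(system: TernarySystem, T: float, P: float,
                          drug_load: float, guess=None,
                          tie_lines: list | None = None,
                          a_bracket=(1e-4, 0.95)) -> tuple | None:
    """Tie line whose polymer-rich endpoint lies exactly on the hydration path.

    The returned tuple is ``(w_water_at_crossing, TieLine)``; ``None`` when
    the path never enters the two-phase region.  The three unknowns are the
    water coordinate of the on-path phase and two log-mole-fraction
    coordinates of the conjugate phase.  A previously traced tie-line list
    seeds the solve cheaply; otherwise a stability scan along the path
    brackets the boundary.
    """
    mix = system.mixture

    if guess is None and tie_lines:
        # locate where the water-free API ratio of the traced polymer-rich
        # branch passes through the drug load
        def ratio(tl):
            s = tl.w1[API] + tl.w1[POLY]
            return tl.w1[API] / s if s > 0 else 0.0
        best_pair = None
        for t0, t1 in zip(tie_lines[:-1], tie_lines[1:]):
            r0, r1 = ratio(t0), ratio(t1)
            if (r0 - drug_load) * (r1 - drug_load) <= 0 and abs(r1 - r0) > 0:
                lam = (drug_load - r0) / (r1 - r0)
                best_pair = (t0, t1, min(max(lam, 0.0), 1.0))
                break
        if best_pair is not None:
            t0, t1, lam = best_pair
            a0 = float((1 - lam) * t0.w1[WATER] + lam * t1.w1[WATER])
            x2g = np.exp((1 - lam) * np.log(np.clip(t0.x2, 1e-250, None))
                         + lam * np.log(np.clip(t1.x2, 1e-250, None)))
            x2g = x2g / x2g.sum()
            guess = (a0, x2g)

    if guess is None:
        # bracket the binodal by a stability scan along the path
        lo, hi = a_bracket
        n_scan = 14
        a_in, trial = None, None
        prev_a, prev_stable = lo, None
        for a in np.linspace(lo, hi, n_scan):
            stable, tr, tpd = stability_test(system, T, P,
                                             system.mass_to_mole(system.path_mass(drug_load, a)))
            if prev_stable is None:
                prev_stable = stable
                if not stable:
                    a_in, trial = a, tr
                    break
            if stable != prev_stable:
                # bisect the flip
                a0, a1 = prev_a, a
                for _ in range(18):
                    am = 0.5 * (a0 + a1)
                    s_m, tr_m, _ = stability_test(
                        system, T, P,
                        system.mass_to_mole(system.path_mass(drug_load, am)))
                    if s_m == prev_stable:
                        a0 = am
                    else:
                        a1, trial = am, tr_m
                a_in = a1
                break
            prev_a, prev_stable = a, stable
        if a_in is None:
            return None
        # conjugate-phase guess: flash slightly inside the gap
        a_seed = min(a_in + 0.01, hi)
        feed = system.mass_to_mole(system.path_mass(drug_load, a_seed))
        try:
            tl = lle_flash(system, T, P, feed)
            x2_guess = tl.x2 if np.argmax(np.abs(tl.x1 - feed)) >= 0 and \
                np.max(np.abs(tl.x1 - feed)) < np.max(np.abs(tl.x2 - feed)) else tl.x1
        except NumericalError:
            x2_guess = trial if trial is not None else np.array([0.9, 1e-8, 0.1])
        guess = (a_in, x2_guess)

    a0, x2 = guess
    x2 = np.clip(np.asarray(x2, dtype=float), 1e-300, None)
    x2 = x2 / x2.sum()
    f2 = _choose_free(x2)
    ph1, ph2 = _Phase(mix, T, P), _Phase(mix, T, P)
    u = np.concatenate([[a0], _phase_vars(x2, f2)])

    def residual(u):
        a = min(max(u[0], 1e-6), 0.999)
        y1 = system.mass_to_mole(system.path_mass(drug_load, a))
        y2, _ = _phase_from_vars(u[1:], f2)
        if y2.min() < 0:
            return None, None, None
        iso = _isoactivity_residual(mix, T, P, y1, y2, ph1, ph2)
        return iso, y1, y2

    F, y1, y2 = residual(u)
    for it in range(60):
        if F is not None and np.max(np.abs(F)) < 1e-10:
            break
        J = np.zeros((3, 3))
        for k in range(3):
            du = np.zeros(3)
            du[k] = 1e-7 if k == 0 else 1e-6
            Fp, _, _ = residual(u + du)
            if Fp is None:
                Fp, _, _ = residual(u - du)
                J[:, k] = (F - Fp) / du[k]
            else:
                J[:, k] = (Fp - F) / du[k]
        step = np.linalg.solve(J, F)
        lam = 1.0
        while lam > 1e-4:
            un = u - lam * step
            Fn, y1n, y2n = residual(un)
            if Fn is not None and np.max(np.abs(Fn)) < np.max(np.abs(F)) + 1e-14:
                u, F, y1, y2 = un, Fn, y1n, y2n
                break
            lam *= 0.5
        else:
            raise NumericalError("path-binodal Newton stalled")
    else:
        raise NumericalError("path-binodal crossing did not converge")
    a = min(max(u[0], 1e-6), 0.999)
    w1, w2 = system.mole_to_mass(y1), system.mole_to_mass(y2)
    if np.max(np.abs(w1 - w2)) < 1e-4:
        raise NumericalError("path-binodal crossing found the trivial root")
    res = float(np.max(np.abs(np.exp(np.log(y1) + ph1.lngamma(y1))
                              - np.exp(np.log(np.clip(y2, 1e-300, None))
                                       + ph2.lngamma(y2)))))
    return a, TieLine(w1=w1, w2=w2, x1=y1, x2=y2, isoactivity_residual=res)


def _lift_from_binary(system: TernarySystem, T: float, P: float,
                      start: TieLine, eps: float):
    """Resolve a tie line just off a binary face: the absent component is
    fixed at mole fraction ``eps`` in phase 1 and the remaining three
    coordinates are solved, seeded by one isoactivity substitution step."""
    mix = system.mixture
    absent = int(np.argmin(np.maximum(start.x1, start.x2)))
    ph1, ph2 = _Phase(mix, T, P), _Phase(mix, T, P)
    lg1 = ph1.lngamma(start.x1)
    lg2 = ph2.lngamma(start.x2)
    ln_x_abs2 = math.log(eps) + lg1[absent] - lg2[absent]
    ln_x_abs2 = min(max(ln_x_abs2, math.log(1e-250)), math.log(0.5))
    others = [i for i in range(3) if i != absent]

    def build(xa, base):
        x = np.zeros(3)
        x[absent] = xa
        rest = np.clip(base[others], 1e-250, None)
        x[others] = (1.0 - xa) * rest / rest.sum()
        return x

    x1 = build(eps, start.x1)
    x2 = build(math.exp(ln_x_abs2), start.x2)
    # unknowns: minor 'other' coordinate of each phase + absent coord of phase 2
    minor1 = others[0] if x1[others[0]] < x1[others[1]] else others[1]
    minor2 = others[0] if x2[others[0]] < x2[others[1]] else others[1]
    maj1 = others[1] if minor1 == others[0] else others[0]
    maj2 = others[1] if minor2 == others[0] else others[0]

    def residual(v):
        y1 = np.zeros(3)
        y1[absent] = eps
        y1[minor1] = math.exp(min(v[0], -1e-15))
        y1[maj1] = 1.0 - eps - y1[minor1]
        y2 = np.zeros(3)
        y2[absent] = math.exp(min(v[1], -1e-15))
        y2[minor2] = math.exp(min(v[2], -1e-15))
        y2[maj2] = 1.0 - y2[absent] - y2[minor2]
        if y1.min() < 0 or y2.min() < 0:
            return None, None, None
        return _isoactivity_residual(mix, T, P, y1, y2, ph1, ph2), y1, y2

    v = np.array([math.log(max(x1[minor1], 1e-250)), ln_x_abs2,
                  math.log(max(x2[minor2], 1e-250))])
    F, y1, y2 = residual(v)
    for _ in range(60):
        if F is not None and np.max(np.abs(F)) < 1e-9:
            break
        J = np.zeros((3, 3))
        for k in range(3):
            dv = np.zeros(3)
            dv[k] = 1e-6
            Fp, _, _ = residual(v + dv)
            if Fp is None:
                Fp, _, _ = residual(v - dv)
                J[:, k] = (F - Fp) / 1e-6
            else:
                J[:, k] = (Fp - F) / 1e-6
        try:
            step = np.clip(np.linalg.solve(J, F), -3.0, 3.0)
        except np.linalg.LinAlgError:
            raise NumericalError("singular Jacobian while lifting off the binary face")
        lam = 1.0
        while lam > 1e-3:
            Fn, y1n, y2n = residual(v - lam * step)
            if Fn is not None and np.max(np.abs(Fn)) <= np.max(np.abs(F)) + 1e-14:
                v, F, y1, y2 = v - lam * step, Fn, y1n, y2n
                break
            lam *= 0.5
        else:
            raise NumericalError("lift line search failed")
    else:
        raise NumericalError("lift off the binary face did not converge")
    w1, w2 = system.mole_to_mass(y1), system.mole_to_mass(y2)
    return TieLine(w1=w1, w2=w2, x1=y1, x2=y2,
                   isoactivity_residual=float(np.max(np.abs(F))))


def trace_binodal(system: TernarySystem, T: float, P: float,
                  step_wt: float = 0.005, max_points: int = 400,
                  start: TieLine | None = None):
    """Continuation of the coexistence curve with matched tie lines.

    Starts from a binary-edge tie line (dry API/polymer face first, then the
    API/water face) and marches the four-unknown isoactivity system with a
    secant predictor, fixing the fastest-moving coordinate each step;
    steps halve on failure down to 0.0001 in mass fraction.  Returns
    ``(binodal_locus, tie_lines)``; both empty when no split exists.
    """
    mix = system.mixture
    if start is None:
        for absent in (WATER, POLY):
            try:
                start = binary_lle(system, T, P, absent=absent)
            except NumericalError:
                start = None
            if start is not None:
                break
    if start is None:
        return [], []

    # lift off the binary face twice to get a finite continuation direction
    try:
        lift1 = _lift_from_binary(system, T, P, start, eps=3e-5)
        lift2 = _lift_from_binary(system, T, P, start, eps=1e-4)
    except NumericalError:
        return [start.w1, start.w2], [start]

    tie_lines = [start, lift1, lift2]
    f1 = _choose_free(np.clip(lift2.x1, 1e-250, None))
    f2 = _choose_free(np.clip(lift2.x2, 1e-250, None))
    ph1, ph2 = _Phase(mix, T, P), _Phase(mix, T, P)

    def pack(tl):
        return np.concatenate([
            np.log(np.clip(tl.x1[list(f1)], 1e-250, None)),
            np.log(np.clip(tl.x2[list(f2)], 1e-250, None))])

    def unpack(u):
        y1, _ = _phase_from_vars(u[:2], f1)
        y2, _ = _phase_from_vars(u[2:], f2)
        return y1, y2

    def residual3(u, fix_k, fix_val):
        y1, y2 = unpack(u)
        if y1.min() < -1e-15 or y2.min() < -1e-15:
            return None
        y1, y2 = np.clip(y1, 1e-300, None), np.clip(y2, 1e-300, None)
        iso = _isoactivity_residual(mix, T, P, y1, y2, ph1, ph2)
        return np.concatenate([iso, [u[fix_k] - fix_val]])

    u = pack(lift2)
    du_prev = pack(lift2) - pack(lift1)
    step_scale = 1.0
    for _ in range(max_points):
        direction = du_prev / (np.linalg.norm(du_prev) + 1e-300)
        fix_k = int(np.argmax(np.abs(direction)))
        # scale the predictor so the mass-fraction move is about step_wt
        y1_cur, y2_cur = unpack(u)
        w_cur = system.mole_to_mass(y1_cur)
        u_pred = u + direction * step_scale
        ok = False
        for attempt in range(8):
            fix_val = u_pred[fix_k]
            v = u_pred.copy()
            F = residual3(v, fix_k, fix_val)
            if F is not None:
                for it in range(40):
                    if np.max(np.abs(F)) < 1e-9:
                        ok = True
                        break
                    J = np.zeros((4, 4))
                    for k in range(4):
                        dv = np.zeros(4)
                        dv[k] = 1e-6
                        Fp = residual3(v + dv, fix_k, fix_val)
                        if Fp is None:
                            Fp = residual3(v - dv, fix_k, fix_val)
                            J[:, k] = (F - Fp) / 1e-6
                        else:
                            J[:, k] = (Fp - F) / 1e-6
                    try:
                        stp = np.linalg.solve(J, F)
                    except np.linalg.LinAlgError:
                        break
                    v = v - np.clip(stp, -1.5, 1.5)
                    F = residual3(v, fix_k, fix_val)
                    if F is None:
                        break
                if ok:
                    break
            step_scale *= 0.5
            u_pred = u + direction * step_scale
            if step_scale < 1e-4:
                break
        if not ok:
            break
        y1, y2 = unpack(v)
        w1, w2 = system.mole_to_mass(y1), system.mole_to_mass(y2)
        if np.max(np.abs(w1 - w2)) < 2e-3:   # plait point reached
            break
        tie_lines.append(TieLine(w1=w1, w2=w2, x1=y1, x2=y2,
                                 isoactivity_residual=float(np.max(np.abs(F[:3])))))
        du_prev = v - u
        u = v
        # adapt the step toward ~step_wt mass-fraction moves of phase 1
        move = np.max(np.abs(w1 - w_cur))
        if move > 0:
            step_scale = min(step_scale * min(max(step_wt / move, 0.3), 2.0), 4.0)
        if w1[WATER] > 0.995 or w2[WATER] > 0.995:
            break
        if min(y1.min(), y2.min()) < 1e-250:
            break
    binodal = [tl.w1 for tl in tie_lines] + [tl.w2 for tl in reversed(tie_lines)]
    return binodal, tie_lines


# --- spinodal ----------------------------------------------------------------

def _gibbs_hessian_det(system: TernarySystem, T: float, P: float, x,
                       ph: _Phase | None = None):
    """Determinant of d²(g_mix/RT)/dx² in two independent mole fractions.

    The largest component is eliminated (its mole fraction is the dependent
    coordinate); the zero locus of the determinant is invariant under that
    choice.  Finite-difference steps are kept inside the simplex."""
    mix = system.mixture
    if ph is None:
        ph = _Phase(mix, T, P)
    x = np.asarray(x, dtype=float)
    dep = int(np.argmax(x))
    free = [i for i in range(3) if i != dep]

    def mu_hat(v1, v2):
        y = np.empty(3)
        y[free[0]], y[free[1]] = v1, v2
        y[dep] = 1.0 - v1 - v2
        if y.min() <= 0:
            return None
        lg = ph.lngamma(y)
        act = np.log(y) + lg
        return np.array([act[free[0]] - act[dep], act[free[1]] - act[dep]])

    margin = 0.25 * x[dep]
    h1 = min(max(1e-9, 1e-4 * x[free[0]]), 0.5 * x[free[0]], margin)
    h2 = min(max(1e-9, 1e-4 * x[free[1]]), 0.5 * x[free[1]], margin)
    if h1 <= 0 or h2 <= 0:
        return None
    m_p1 = mu_hat(x[free[0]] + h1, x[free[1]])
    m_m1 = mu_hat(x[free[0]] - h1, x[free[1]])
    m_p2 = mu_hat(x[free[0]], x[free[1]] + h2)
    m_m2 = mu_hat(x[free[0]], x[free[1]] - h2)
    if any(v is None for v in (m_p1, m_m1, m_p2, m_m2)):
        return None
    H = np.empty((2, 2))
    H[:, 0] = (m_p1 - m_m1) / (2 * h1)
    H[:, 1] = (m_p2 - m_m2) / (2 * h2)
    H = 0.5 * (H + H.T)
    return float(np.linalg.det(H))


def spinodal_locus(system: TernarySystem, T: float, P: float,
                   n_water: int = 25, w_water_max: float = 0.9) -> list:
    """Locus where the Gibbs-curvature determinant vanishes, scanned along
    fixed water levels in mass-fraction space.  Empty list when no
    instability exists."""
    pts = []
    levels = np.linspace(0.0, w_water_max, n_water)
    levels[levels < 1e-6] = 1e-6   # the dry face is sampled just inside
    for w_w in levels:
        ph = _Phase(system.mixture, T, P)

        def det_at(w_api):
            w = np.array([w_api, 1.0 - w_w - w_api, w_w])
            if w.min() < 0:
                return None
            return _gibbs_hessian_det(system, T, P, system.mass_to_mole(w), ph)

        grid = np.linspace(1e-4, 1.0 - w_w - 1e-4, 30)
        vals = []
        for wa in grid:
            dv = det_at(wa)
            vals.append(dv if dv is not None else np.nan)
        vals = np.array(vals)
        for i in range(len(grid) - 1):
            if np.isnan(vals[i]) or np.isnan(vals[i + 1]):
                continue
            if np.sign(vals[i]) * np.sign(vals[i + 1]) < 0:
                try:
                    wa = brentq(lambda w: det_at(w), grid[i], grid[i + 1],
                                xtol=1e-10)
                except (ValueError, TypeError):
                    continue
                pts.append(np.array([wa, 1.0 - w_w - wa, w_w]))
    return pts


# --- diagram assembly ---------------------------------------------------------

def compute_diagram(system: TernarySystem, T: float, P: float,
                    n_solubility: int = 30, with_spinodal: bool = True,
                    with_binodal: bool = True, binodal_step: float = 0.01,
                    egt_locus_points=None) -> TernaryDiagram:
    """Compute all requested loci of the ternary diagram at fixed T, P."""
    diagram = TernaryDiagram(system=system, T=T, P=P)
    try:
        diagram.solubility_locus = solubility_locus(system, T, P, n=n_solubility)
    except ValueError:
        diagram.solubility_locus = []   # API without melting properties
    if with_binodal:
        binodal, ties = trace_binodal(system, T, P, step_wt=binodal_step)
        diagram.binodal_locus = binodal
        diagram.tie_lines = ties
    if with_spinodal:
        diagram.spinodal_locus = spinodal_locus(system, T, P)
    if egt_locus_points is not None:
        diagram.egt_locus = egt_locus_points
    return diagram
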