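"""Hydration pathways, locus crossings, lever-rule fractions and the
loss-of-release (LoR) classification.

The hydration pathway is the straight mass-fraction line from the dry ASD
composition (DL, 1-DL, 0) toward the pure-water vertex; the API:polymer mass
ratio is constant along it.  Ordered crossings of the escape-glass-transition
(eGT) line, the solubility line and the binodal decide the interfacial fate:

* LoR Type I — a fast crystallizer whose path reaches saturation at a water
  content not beyond the eGT water content crystallizes inside the glassy gel
  layer; API and polymer release collapse together (congruent loss).
* LoR Type II — a slow crystallizer whose path meets the binodal at or before
  eGT phase-separates in the gel layer; the immobile API-rich phase passivates
  the surface while the polymer-rich phase keeps releasing (incongruent,
  polymer-only release).

Crossings within a narrow water-content band around eGT are reported as
sitting at the gel-layer boundary; crossings within a wider proximity band
are annotated as borderline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .equilibria import (API, POLY, WATER, TernarySystem, TernaryDiagram,
                         TieLine, path_solubility_crossing,
                         path_binodal_crossing, round_half_up)
from .glass import gordon_taylor_tg, egt_water_content
from .pcsaft import NumericalError

__all__ = [
    "HydrationPath", "CrossingEvent", "LoRClassification", "HydrationReport",
    "build_path", "find_crossings", "classify_lor", "lor_threshold_dl",
    "lever_fractions", "hydration_report", "dose_strength",
    "GEL_BOUNDARY_BAND", "BORDERLINE_BAND",
]

#: water-content tolerance (mass fraction) for "at the gel-layer boundary"
GEL_BOUNDARY_BAND = 5e-4
#: proximity band (mass fraction water) for borderline annotations
BORDERLINE_BAND = 0.05


@dataclass(frozen=True)
class HydrationPath:
    """Straight hydration line at fixed water-free drug load."""
    drug_load: float

    def __post_init__(self):
        if not 0.0 < self.drug_load < 1.0:
            raise ValueError("drug load must lie strictly between 0 and 1")

    def composition(self, w_water: float) -> np.ndarray:
        """Mass fractions (API, polymer, water) at a given water content."""
        if not 0.0 <= w_water <= 1.0:
            raise ValueError("water content must lie in [0, 1]")
        return np.array([self.drug_load * (1.0 - w_water),
                         (1.0 - self.drug_load) * (1.0 - w_water), w_water])


def build_path(drug_load: float) -> HydrationPath:
    return HydrationPath(drug_load=drug_load)


@dataclass
class CrossingEvent:
    locus: Literal["egt", "solubility", "binodal"]
    water_content: float          # mass fraction water on the path
    composition: np.ndarray       # full mass fractions on the path
    Tg_celsius: float
    flag: str = ""                # e.g. "supersaturated in the dry state"
    tie_line: TieLine | None = None   # conjugate phase for binodal events


@dataclass
class LoRClassification:
    lor_type: Literal["none", "Type I", "Type II", "mixed"]
    rationale: str
    release_expectation: Literal[
        "congruent release", "congruent loss (API+polymer)",
        "incongruent (polymer-only) release"]
    borderline: bool = False


@dataclass
class HydrationReport:
    system: str
    T: float
    P: float
    T_medium: float
    blocks: list = field(default_factory=list)  # (drug_load, rows, classification)

    def to_frame(self):
        import pandas as pd
        rows = []
        for dl, block, cls in self.blocks:
            for label, w, tg, flag in block:
                if w is None:
                    rows.append((100 * dl, label, "", "", "", "", flag))
                else:
                    rows.append((100 * dl, label,
                                 round_half_up(100 * w[WATER], 1),
                                 round_half_up(100 * w[API], 1),
                                 round_half_up(100 * w[POLY], 1),
                                 "" if tg is None else round_half_up(tg, 1),
                                 flag))
        return pd.DataFrame(rows, columns=[
            "drug_load_wt", "row", "water_wt", "api_wt", "polymer_wt",
            "Tg_celsius", "note"])


def _components(system: TernarySystem):
    return [system.pset.component(n) for n in system.names]


def _tg_c(system: TernarySystem, w) -> float:
    return gordon_taylor_tg(w, _components(system)) - 273.15


def find_crossings(system: TernarySystem, T: float, P: float,
                   path: HydrationPath, T_medium: float | None = None,
                   diagram: TernaryDiagram | None = None,
                   tie_lines: Sequence[TieLine] | None = None,
                   with_binodal: bool = True) -> list[CrossingEvent]:
    """Ordered crossing events (eGT, solubility, binodal) of one path.

    ``diagram``/``tie_lines`` supply a previously traced binodal so the
    binodal crossing can be polished cheaply; without one, a stability scan
    along the path brackets it.
    """
    if T_medium is None:
        T_medium = T
    if tie_lines is None and diagram is not None:
        tie_lines = diagram.tie_lines
    comps = _components(system)
    events: list[CrossingEvent] = []

    w_egt, reached = egt_water_content(path.drug_load, T_medium, comps)
    if reached:
        w = path.composition(w_egt)
        events.append(CrossingEvent("egt", w_egt, w, _tg_c(system, w)))

    if system.api_component.melting_T is not None:
        out, pt = path_solubility_crossing(system, T, P, path.drug_load)
        if out == "supersaturated":
            w = path.composition(0.0)
            events.append(CrossingEvent(
                "solubility", 0.0, w, _tg_c(system, w),
                flag="supersaturated in the dry state"))
        elif out is not None:
            w = path.composition(out)
            events.append(CrossingEvent("solubility", out, w, _tg_c(system, w)))

    res = None
    if with_binodal:
        try:
            res = path_binodal_crossing(system, T, P, path.drug_load,
                                        tie_lines=tie_lines)
        except NumericalError:
            res = None
    if res is not None:
        a, tl = res
        w = path.composition(a)
        events.append(CrossingEvent("binodal", a, w, _tg_c(system, w),
                                    tie_line=tl))
    events.sort(key=lambda e: e.water_content)
    return events


def classify_lor(crossings: Sequence[CrossingEvent],
                 crystallization_propensity: Literal["fast", "slow"]) -> LoRClassification:
    """LoR classification from ordered crossing events.

    A crossing "at or before eGT" is decided on the water-content axis with a
    0.05 wt% band (crossings inside the band sit at the gel-layer boundary);
    crossings within 5 wt% water of eGT on either side are flagged borderline.
    """
    if crystallization_propensity not in ("fast", "slow"):
        raise ValueError("crystallization_propensity must be 'fast' or 'slow'")
    by_locus = {e.locus: e for e in crossings}
    egt = by_locus.get("egt")
    w_egt = egt.water_content if egt is not None else 0.0

    def before(e):
        return e is not None and e.water_content <= w_egt + GEL_BOUNDARY_BAND

    def near(e):
        return e is not None and abs(e.water_content - w_egt) <= BORDERLINE_BAND

    sol, bino = by_locus.get("solubility"), by_locus.get("binodal")
    fast = crystallization_propensity == "fast"
    type1 = fast and egt is not None and before(sol)
    type2 = (not fast) and egt is not None and before(bino)
    mixed = fast and egt is not None and before(sol) and before(bino)

    parts = []
    if egt is None:
        parts.append("no glassy gel layer (dry Tg at or below the medium temperature)")
    else:
        parts.append(f"eGT at {100 * w_egt:.1f} wt% water")
    for name, e in (("solubility", sol), ("binodal", bino)):
        if e is None:
            continue
        if e.flag:
            parts.append(f"{name}: {e.flag}")
        else:
            rel = "before" if before(e) else "beyond"
            parts.append(f"{name} crossing at {100 * e.water_content:.1f} wt% water "
                         f"({rel} eGT)")
    rationale = "; ".join(parts)

    if mixed:
        kind = "mixed"
        release = "congruent loss (API+polymer)"
    elif type1:
        kind = "Type I"
        release = "congruent loss (API+polymer)"
    elif type2:
        kind = "Type II"
        release = "incongruent (polymer-only) release"
    else:
        kind = "none"
        release = "congruent release"
    borderline = near(sol) if fast else near(bino)
    return LoRClassification(lor_type=kind, rationale=rationale,
                             release_expectation=release, borderline=borderline)


def lor_threshold_dl(system: TernarySystem, T: float, P: float,
                     crystallization_propensity: Literal["fast", "slow"],
                     T_medium: float | None = None,
                     tie_lines: Sequence[TieLine] | None = None,
                     dl_bracket=(0.002, 0.95), tol: float = 1e-3):
    """Smallest drug load classified as LoR, by bisection on the signed
    water-content gap between the decisive crossing and eGT (0.1 wt% in DL).

    Returns the threshold drug load (mass fraction) or ``None`` if no drug
    load in the bracket triggers LoR.
    """
    if T_medium is None:
        T_medium = T
    comps = _components(system)
    fast = crystallization_propensity == "fast"

    def gap(dl):
        w_egt, reached = egt_water_content(dl, T_medium, comps)
        if not reached:
            return 1.0
        if fast:
            out, _ = path_solubility_crossing(system, T, P, dl)
            if out == "supersaturated":
                return -w_egt
            if out is None:
                return 1.0
            return out - w_egt
        res = path_binodal_crossing(system, T, P, dl, tie_lines=tie_lines)
        if res is None:
            return 1.0
        return res[0] - w_egt

    lo, hi = dl_bracket
    if gap(lo) <= 0:
        return lo
    # the gap is not monotone over the whole range (at very high drug loads
    # the dry blend is no longer glassy), so bracket the first sign change
    grid = np.linspace(lo, hi, 16)
    prev = lo
    hit = None
    for dl in grid[1:]:
        if gap(dl) <= 0:
            hit = (prev, dl)
            break
        prev = dl
    if hit is None:
        return None
    lo, hi = hit
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if gap(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def lever_fractions(feed, tie: TieLine, tol: float = 1e-6):
    """Mass fractions of the two phases of a tie line for a collinear feed.

    Mass-fraction compositions and the lever rule: feed = f1·w1 + f2·w2.
    Raises ``ValueError`` when the feed is not on the tie segment within
    ``tol`` (mass-fraction distance).
    """
    feed = np.asarray(feed, dtype=float)
    seg = tie.w2 - tie.w1
    denom = float(seg @ seg)
    if denom <= 0:
        raise ValueError("degenerate tie line")
    t = float((feed - tie.w1) @ seg) / denom
    proj = tie.w1 + t * seg
    if np.max(np.abs(proj - feed)) > tol:
        raise ValueError("feed is not collinear with the tie line")
    if not -tol <= t <= 1 + tol:
        raise ValueError("feed lies outside the tie segment")
    t = min(max(t, 0.0), 1.0)
    return (1.0 - t, t)   # fractions of (phase 1, phase 2)


def hydration_report(system: TernarySystem, T: float, P: float,
                     drug_loads: Sequence[float],
                     crystallization_propensity: Literal["fast", "slow"],
                     T_medium: float | None = None,
                     tie_lines: Sequence[TieLine] | None = None,
                     with_binodal: bool = True) -> HydrationReport:
    """Per-drug-load table of compositions along the hydration pathway with
    their Gordon–Taylor Tg, plus the LoR classification."""
    if T_medium is None:
        T_medium = T
    report = HydrationReport(system=system.api, T=T, P=P, T_medium=T_medium)
    for dl in drug_loads:
        path = build_path(dl)
        rows = []
        w_dry = path.composition(0.0)
        rows.append(("ASD (dry)", w_dry, _tg_c(system, w_dry), ""))
        crossings = find_crossings(system, T, P, path, T_medium=T_medium,
                                   tie_lines=tie_lines,
                                   with_binodal=with_binodal)
        by_locus = {e.locus: e for e in crossings}
        egt = by_locus.get("egt")
        bino = by_locus.get("binodal")
        if egt is not None:
            note = ""
            if bino is not None and bino.water_content <= egt.water_content:
                note = "LLPS occurs before eGT"
            rows.append(("eGT", egt.composition, egt.Tg_celsius, note))
        else:
            rows.append(("eGT", None, None,
                         "dry Tg at or below the medium temperature"))
        sol = by_locus.get("solubility")
        if sol is None:
            if system.api_component.melting_T is not None:
                rows.append(("Solubility limit", None, None,
                             "path never reaches saturation"))
        elif sol.flag:
            rows.append(("Solubility limit", None, None, sol.flag))
        else:
            rows.append(("Solubility limit", sol.composition, sol.Tg_celsius, ""))
        if bino is not None and bino.tie_line is not None:
            tl = bino.tie_line
            rows.append(("Polymer-rich phase at binodal line", tl.w1,
                         _tg_c(system, tl.w1), ""))
            rows.append(("API-rich phase at binodal line", tl.w2,
                         _tg_c(system, tl.w2), ""))
        cls = classify_lor(crossings, crystallization_propensity)
        report.blocks.append((dl, rows, cls))
    return report


def dose_strength(aqueous_solubility: float, volume: float,
                  supersaturation_factor: float = 1.0) -> int:
    """Dose in mg from an aqueous solubility (g/L), a medium volume (L) and a
    target concentration multiple (the saturation dose has factor 1)."""
    if aqueous_solubility <= 0 or volume <= 0 or supersaturation_factor <= 0:
        raise ValueError("all arguments must be positive")
    return int(round_half_up(
        aqueous_solubility * volume * supersaturation_factor * 1000.0, 0))
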