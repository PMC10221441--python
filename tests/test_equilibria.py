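"""Solid-liquid and liquid-liquid equilibria: saturation closed forms,
isoactivity splits, stability analysis, spinodal, basis conversions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from asdphase.equilibria import (API, POLY, WATER, R_GAS, TernarySystem,
                                 binary_lle, ideal_solubility, lle_flash,
                                 ln_saturation_activity,
                                 path_binodal_crossing,
                                 path_solubility_crossing, round_half_up,
                                 sle_solubility, spinodal_locus,
                                 stability_test, _gibbs_hessian_det)
from asdphase.parameters import (BinaryInteraction, ParameterSet,
                                 PureComponent)
from asdphase.pcsaft import NumericalError

from conftest import T37, P_ATM


# --- solid-liquid ------------------------------------------------------------

def test_ideal_solubility_venetoclax_closed_form(pset):
    """Delta-cp absent: the saturation activity is the enthalpy term alone."""
    ven = pset.component("venetoclax")
    expected = math.exp(-(59900 / (R_GAS * T37)) * (1 - T37 / 418.15))
    assert ideal_solubility(ven, T37) == pytest.approx(expected, rel=1e-12)
    assert ideal_solubility(ven, T37) == pytest.approx(2.48e-3, rel=0.01)


def test_ideal_solubility_naproxen_with_delta_cp(pset):
    nap = pset.component("naproxen")
    enth = -(31500 / (R_GAS * T37)) * (1 - T37 / 429.47)
    cp = -(87.0 / R_GAS) * (math.log(429.47 / T37) - 429.47 / T37 + 1.0)
    assert ln_saturation_activity(nap, T37) == pytest.approx(enth + cp, rel=1e-12)
    # the Delta-cp correction raises the subcooled-liquid solubility
    assert cp > 0


def test_melting_point_identity(pset):
    nap = pset.component("naproxen")
    assert ideal_solubility(nap, 429.47) == pytest.approx(1.0, rel=1e-12)


def test_missing_melting_properties(pset):
    with pytest.raises(ValueError):
        ideal_solubility(pset.component("PVPVA64"), T37)


def test_sle_reduces_to_ideal_when_gamma_is_one():
    """An API identical to its solvent has gamma = 1, so the saturated mole
    fraction equals the ideal closed form."""
    base = dict(molar_mass=230.26, segment_ratio=0.0352, segment_diameter=2.939,
                dispersion_energy=229.45, density=1250.0, glass_T=265.15)
    api = PureComponent(name="api", melting_T=429.47, melting_enthalpy=31500.0,
                        delta_cp=87.0, **base)
    solvent = PureComponent(name="solvent", **base)
    other = PureComponent(name="other", **base)
    ps = ParameterSet()
    for c in (api, solvent, other):
        ps.add_component(c)
    for pair in (("api", "solvent"), ("api", "other"), ("solvent", "other")):
        ps.add_interaction(BinaryInteraction(pair, 0.0, 0.0))
    system = TernarySystem(ps, "api", "solvent", "other")
    pt = sle_solubility(system, T37, P_ATM, solvent_ratio=math.inf)
    assert pt.x[API] == pytest.approx(ideal_solubility(api, T37), rel=1e-6)


def test_sle_satisfies_saturation_residual(nap_sys):
    pt = sle_solubility(nap_sys, T37, P_ATM, solvent_ratio=math.inf)
    assert abs(pt.residual) < 1e-8
    assert pt.w.sum() == pytest.approx(1.0, abs=1e-10)


def test_solubility_rises_with_temperature(nap_sys):
    w37 = sle_solubility(nap_sys, T37, P_ATM, math.inf).w[API]
    w50 = sle_solubility(nap_sys, 323.15, P_ATM, math.inf).w[API]
    assert w50 > w37


def test_supersaturated_dry_state_flagged(nap_sys):
    out, _ = path_solubility_crossing(nap_sys, T37, P_ATM, 0.30)
    assert out == "supersaturated"


def test_solubility_crossing_decreases_with_drug_load(nap_sys):
    a10, _ = path_solubility_crossing(nap_sys, T37, P_ATM, 0.10)
    a20, _ = path_solubility_crossing(nap_sys, T37, P_ATM, 0.20)
    assert a20 < a10


# --- basis conversion --------------------------------------------------------

@given(st.lists(st.floats(1e-6, 1.0), min_size=3, max_size=3))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_mass_mole_round_trip(nap_sys, raw):
    w = np.asarray(raw)
    w = w / w.sum()
    x = nap_sys.mass_to_mole(w)
    w2 = nap_sys.mole_to_mass(x)
    assert np.max(np.abs(w2 - w)) < 1e-12
    assert x.sum() == pytest.approx(1.0, abs=1e-12)


def test_round_half_up():
    assert round_half_up(0.25, 1) == 0.3
    assert round_half_up(0.24999, 1) == 0.2
    assert round_half_up(-0.25, 1) == -0.3


# --- liquid-liquid -----------------------------------------------------------

def _toy_symmetric_system(kij_b=0.02):
    """Two identical non-associating species with an unfavorable kij, plus a
    passive third component: symmetric miscibility gap on the a/b face."""
    base = dict(molar_mass=868.44, segment_ratio=0.03938, segment_diameter=2.546,
                dispersion_energy=233.70, density=1340.0, glass_T=393.15)
    ps = ParameterSet()
    for n in ("a", "b", "c"):
        ps.add_component(PureComponent(name=n, **base))
    ps.add_interaction(BinaryInteraction(("a", "b"), 0.0, kij_b))
    ps.add_interaction(BinaryInteraction(("a", "c"), 0.0, 0.0))
    ps.add_interaction(BinaryInteraction(("b", "c"), 0.0, 0.0))
    return TernarySystem(ps, "a", "b", "c")


def test_symmetric_toy_split_is_symmetric():
    system = _toy_symmetric_system()
    tl = binary_lle(system, T37, P_ATM, absent=WATER)
    assert tl is not None
    assert tl.x1[API] == pytest.approx(tl.x2[POLY], rel=1e-6)
    assert tl.x1[POLY] == pytest.approx(tl.x2[API], rel=1e-6)
    assert tl.isoactivity_residual < 1e-8


def test_toy_face_miscible_without_kij():
    system = _toy_symmetric_system(kij_b=0.0)
    assert binary_lle(system, T37, P_ATM, absent=WATER) is None


def test_venetoclax_dry_binary_tie_line(ven_sys):
    tl = binary_lle(ven_sys, T37, P_ATM, absent=WATER)
    assert tl is not None
    # polymer-rich boundary in the mid-single-digit wt% range; conjugate is
    # essentially pure amorphous API
    assert 0.03 < tl.w1[API] < 0.09
    assert tl.w2[API] > 0.995
    assert tl.isoactivity_residual < 1e-8


def test_venetoclax_gap_shrinks_at_50C(ven_sys):
    tl37 = binary_lle(ven_sys, T37, P_ATM, absent=WATER)
    tl50 = binary_lle(ven_sys, 323.15, P_ATM, absent=WATER)
    assert tl50.w1[API] > tl37.w1[API]     # polymer-rich side moves inward


def test_flash_tie_line_properties(ven_sys, ven_ties37):
    """Interior feed: isoactivity, phase distinctness, lever collinearity and
    endpoint stability."""
    res = path_binodal_crossing(ven_sys, T37, P_ATM, 0.025,
                                tie_lines=ven_ties37)
    assert res is not None
    a, tl = res
    feed_w = ven_sys.path_mass(0.025, a + 0.02)
    feed_x = ven_sys.mass_to_mole(feed_w)
    flash = lle_flash(ven_sys, T37, P_ATM, feed_x,
                      guess=(tl.x1, tl.x2))
    assert flash.isoactivity_residual < 1e-8
    assert np.max(np.abs(flash.w1 - flash.w2)) > 1e-4
    # mass balance: feed on the segment between the phases (mole basis)
    v1, v2 = flash.x1 - feed_x, flash.x2 - feed_x
    cross = v1[API] * v2[WATER] - v1[WATER] * v2[API]
    assert abs(cross) < 1e-8
    # midpoint of the tie line is unstable, endpoints are not deeper-unstable
    mid = ven_sys.mole_to_mass(0.5 * (flash.x1 + flash.x2))
    stable, trial, tpd = stability_test(ven_sys, T37, P_ATM,
                                        ven_sys.mass_to_mole(mid))
    assert not stable and tpd < 0


def test_stability_of_pure_water(ven_sys):
    stable, trial, tpd = stability_test(ven_sys, T37, P_ATM,
                                        [1e-12, 1e-12, 1.0])
    assert stable


def test_flash_rejects_stable_feed(ven_sys):
    x = ven_sys.mass_to_mole([1e-4, 0.999 - 1e-4, 1e-3])
    with pytest.raises(NumericalError):
        lle_flash(ven_sys, T37, P_ATM, x)


# --- binodal and spinodal ----------------------------------------------------

def test_traced_tie_lines_satisfy_isoactivity(ven_ties37):
    for tl in ven_ties37[:: max(1, len(ven_ties37) // 10)]:
        assert tl.isoactivity_residual < 1e-8


def test_tie_lines_do_not_cross(ven_ties37):
    """Successive tie lines are nested: both endpoints move monotonically
    along their branches."""
    w1_water = [tl.w1[WATER] for tl in ven_ties37[1:]]
    assert all(b >= a - 1e-9 for a, b in zip(w1_water, w1_water[1:]))


def test_path_crossing_on_path(ven_sys, ven_ties37):
    a, tl = path_binodal_crossing(ven_sys, T37, P_ATM, 0.01,
                                  tie_lines=ven_ties37)
    r = tl.w1[API] / (tl.w1[API] + tl.w1[POLY])
    assert r == pytest.approx(0.01, abs=1e-6)
    assert tl.w1[WATER] == pytest.approx(a, abs=1e-9)


def test_spinodal_points_have_zero_curvature(ven_sys):
    pts = spinodal_locus(ven_sys, T37, P_ATM, n_water=4, w_water_max=0.3)
    assert len(pts) >= 2
    for w in pts[:4]:
        # the determinant changes sign across the locus point along the scan
        # direction (API axis at fixed water)
        dets = []
        for s in (-0.02, 0.0, +0.02):
            w_off = np.array([w[API] + s, w[POLY] - s, w[WATER]])
            if w_off.min() < 0:
                continue
            d = _gibbs_hessian_det(ven_sys, T37, P_ATM,
                                   ven_sys.mass_to_mole(w_off))
            if d is not None:
                dets.append((s, d))
        d0 = dict(dets)[0.0]
        outer = [d for s, d in dets if s != 0.0]
        assert len(outer) >= 1
        scale = max(abs(d) for d in outer)
        crosses = len(outer) == 2 and outer[0] * outer[1] < 0
        assert crosses or abs(d0) < 1e-5 * scale


def test_spinodal_inside_binodal(ven_sys, ven_ties37):
    """On the dry face the spinodal pair lies strictly inside the binodal."""
    pts = spinodal_locus(ven_sys, T37, P_ATM, n_water=1, w_water_max=0.0)
    assert len(pts) >= 2
    lo = min(p[API] for p in pts)
    hi = max(p[API] for p in pts)
    tl = ven_ties37[0]   # dry binary tie line
    assert tl.w1[API] < lo and hi < tl.w2[API]
    # and spinodal compositions are tangent-plane unstable
    mid = 0.5 * (lo + hi)
    stable, _, _ = stability_test(ven_sys, T37, P_ATM,
                                  ven_sys.mass_to_mole([mid, 1 - mid, 0.0]))
    assert not stable


def test_binary_spinodal_matches_1d_oracle(ven_sys):
    """Ternary spinodal code on the dry face vs a 1-D d2g/dx2 bisection."""
    from asdphase.equilibria import _Phase
    pts = spinodal_locus(ven_sys, T37, P_ATM, n_water=1, w_water_max=0.0)
    lo = min(p[API] for p in pts)
    ph = _Phase(ven_sys.mixture, T37, P_ATM)

    def d2g(w_api):
        h = 1e-4

        def dg(w):
            x = ven_sys.mass_to_mole([w, 1 - w, 0.0])
            x = np.clip(x, 1e-300, None)
            lg = ph.lngamma(x)
            act = np.log(x) + lg
            return act[API] - act[POLY]

        # derivative of dg wrt mole fraction of API via the chain rule is not
        # needed for a sign change: bisection on dg'(w) sign via differences
        return (dg(w_api + h) - dg(w_api - h)) / (2 * h)

    a, b = 0.02, 0.30
    assert d2g(a) > 0 and d2g(b) < 0
    for _ in range(40):
        m = 0.5 * (a + b)
        if d2g(m) > 0:
            a = m
        else:
            b = m
    assert lo == pytest.approx(0.5 * (a + b), abs=0.01)
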