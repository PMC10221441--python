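"""PC-SAFT core: combining rules, Helmholtz breakdown, association, density
roots and activity coefficients, checked against independent oracles
(successive substitution, finite differences, dense pressure scans)."""

import math

import numpy as np
import pytest

from asdphase.parameters import (BinaryInteraction, ParameterSet,
                                 PureComponent, builtin_fixture)
from asdphase.pcsaft import Mixture, NA, cross_parameters
from asdphase.verification import ss_site_fractions

from conftest import T37, P_ATM


@pytest.fixture(scope="module")
def mix3(pset):
    return Mixture(pset, ["naproxen", "PVPVA64", "water"])


# --- combining rules ---------------------------------------------------------

def test_cross_parameters_examples(pset):
    nap, pol, wat = (pset.component(n) for n in ("naproxen", "PVPVA64", "water"))
    cp = cross_parameters(nap, pol, T37, kij=0.0)
    assert cp.sigma_ij == pytest.approx(0.5 * (2.939 + 2.947), abs=1e-12)
    cp = cross_parameters(wat, pol, T37)
    assert cp.eps_ij == pytest.approx(0.5 * (2425.7 + 0.0), abs=1e-9)
    # diagonal case: pure values recovered
    cp = cross_parameters(nap, nap, T37)
    assert cp.sigma_ij == 2.939
    assert cp.u_ij == pytest.approx(229.45)
    assert cp.eps_ij == pytest.approx(934.2)
    assert cp.kappa_ij == pytest.approx(0.02)


def test_cross_dispersion_uses_kij(pset):
    nap, wat = pset.component("naproxen"), pset.component("water")
    k = pset.kij("naproxen", "water", T37)
    cp = cross_parameters(nap, wat, T37, kij=k)
    assert cp.u_ij == pytest.approx(
        math.sqrt(229.45 * 353.95) * (1 - k), rel=1e-12)


# --- Helmholtz breakdown -----------------------------------------------------

def test_breakdown_additivity_and_no_association(pset):
    mix = Mixture(pset, ["venetoclax"])
    state = mix.resolve(T37, P_ATM, [1.0])
    bd = mix.helmholtz_breakdown(state)
    assert bd.a_assoc == 0.0                      # no sites on venetoclax
    assert bd.a_res == pytest.approx(bd.a_hc + bd.a_disp + bd.a_assoc,
                                     abs=1e-14)


def test_binary_pure_limit_matches_pure_component(mix3):
    """a_res of a binary at x1 -> 1 approaches the pure-component value."""
    pure = Mixture(builtin_fixture(), ["water"])
    rho = pure.solve_liquid_density(T37, P_ATM, [1.0])
    a_pure = float(np.real(pure.a_res(T37, rho, np.array([1.0]))))
    a_lim = float(np.real(mix3.a_res(T37, rho, np.array([1e-12, 0.0, 1.0 - 1e-12]))))
    assert a_lim == pytest.approx(a_pure, rel=1e-6)


# --- association -------------------------------------------------------------

def test_site_fractions_match_successive_substitution(pset, mix3):
    """Newton-accelerated site fractions agree with the plain damped
    successive-substitution oracle to 1e-8 (pure water, liquid density)."""
    state = mix3.resolve(T37, P_ATM, [0.0, 0.0, 1.0])
    fr = mix3.solve_site_fractions(state)
    xa, xb = fr["water"]
    assert xa == pytest.approx(xb, abs=1e-10)     # symmetric donor/acceptor
    # oracle with the same inputs
    rho = state.molar_density * NA * 1e-30
    idx = mix3._assoc_idx
    sig, d, sig_ij, u_ij, eps_ij, kap_ij, pref = mix3._geometry(T37)
    x = np.array([0.0, 0.0, 1.0])
    z2 = (np.pi / 6) * rho * np.sum(x * mix3.m * d ** 2)
    z3 = (np.pi / 6) * rho * np.sum(x * mix3.m * d ** 3)
    dd = d[:, None] * d[None, :] / (d[:, None] + d[None, :])
    g = (1 / (1 - z3) + dd * 3 * z2 / (1 - z3) ** 2
         + dd ** 2 * 2 * z2 ** 2 / (1 - z3) ** 3)
    delta = (pref * g)[np.ix_(idx, idx)]
    xa_o, xb_o = ss_site_fractions(rho, x[idx], mix3.n_don[idx],
                                   mix3.n_acc[idx], delta)
    k = list(idx).index(2)
    assert xa == pytest.approx(xa_o[k], abs=1e-8)
    assert 0 < xa <= 1.0


def test_site_fractions_approach_one_without_bonding(pset):
    """Scaling the association energy to zero drives X -> 1."""
    weak = PureComponent(
        name="weakwater", molar_mass=18.015, segment_ratio=0.0669,
        segment_diameter=2.7927, dispersion_energy=353.95,
        assoc_energy=1e-6, assoc_volume=1e-10, assoc_sites=(1, 1),
        density=1000.0, glass_T=138.0)
    ps = ParameterSet()
    ps.add_component(weak)
    mix = Mixture(ps, ["weakwater"])
    state = mix.resolve(T37, P_ATM, [1.0])
    xa, xb = mix.solve_site_fractions(state)["weakwater"]
    assert xa == pytest.approx(1.0, abs=1e-6)
    assert mix.helmholtz_breakdown(state).a_assoc == pytest.approx(0.0, abs=1e-8)


# --- density -----------------------------------------------------------------

def test_pure_water_density_is_physical(mix3):
    rho_mass = mix3.mass_density(T37, P_ATM, [0.0, 0.0, 1.0])
    assert rho_mass == pytest.approx(1000.0, rel=0.05)


def test_pressure_consistency_and_monotonicity(mix3):
    x = np.array([0.05, 0.001, 0.949])
    rho = mix3.solve_liquid_density(T37, P_ATM, x)
    assert mix3.pressure(T37, rho, x) == pytest.approx(P_ATM, rel=1e-6)
    rhos = [mix3.solve_liquid_density(T37, p, x)
            for p in (0.5e5, 1e5, 1.5e5, 2e5)]
    assert all(b >= a for a, b in zip(rhos, rhos[1:]))


def test_liquid_root_matches_dense_scan(mix3):
    """Warm-started Newton density equals the dense grid-scan root."""
    x = np.array([0.2, 0.0005, 0.7995])
    rho_scan = mix3._density_scan(T37, P_ATM, x)
    rho_newton = mix3.solve_liquid_density(T37, P_ATM, x, rho0=rho_scan * 1.07)
    assert rho_newton == pytest.approx(rho_scan, rel=1e-9)


# --- fugacity/activity -------------------------------------------------------

def test_pure_component_activity_is_unity(mix3):
    for k, x in enumerate(np.eye(3)):
        lg, _ = mix3.lngamma(T37, P_ATM, x)
        assert lg[k] == pytest.approx(0.0, abs=1e-8)


def test_composition_derivatives_match_finite_differences(mix3):
    """Complex-step dA/dx agrees with central finite differences (the test
    oracle) to relative 1e-5."""
    x = np.array([0.15, 0.002, 0.848])
    rho = mix3.solve_liquid_density(T37, P_ATM, x)
    h_im = 1e-30
    for k in range(3):
        xc = x.astype(complex)
        xc[k] += 1j * h_im
        exact = np.imag(mix3.a_res(T37, rho, xc)) / h_im
        h = 1e-6
        xp, xm = x.copy(), x.copy()
        xp[k] += h
        xm[k] -= h
        fd = (np.real(mix3.a_res(T37, rho, xp))
              - np.real(mix3.a_res(T37, rho, xm))) / (2 * h)
        assert exact == pytest.approx(fd, rel=1e-5, abs=1e-9)


def test_gibbs_duhem_residual(mix3):
    """Binary naproxen/water slice: sum_i x_i dln(gamma_i)/dx1 vanishes."""
    h = 1e-5
    for x1 in (0.02, 0.3, 0.7):
        def lg(v):
            out, _ = mix3.lngamma(T37, P_ATM, np.array([v, 0.0, 1.0 - v]))
            return out
        d = (lg(x1 + h) - lg(x1 - h)) / (2 * h)
        x = np.array([x1, 0.0, 1.0 - x1])
        assert abs(float(np.sum(x * d))) < 1e-4


def test_identical_species_are_ideal():
    """Two components with identical parameters and kij = 0 cannot be told
    apart: gamma = 1 at every composition."""
    base = dict(molar_mass=230.26, segment_ratio=0.0352, segment_diameter=2.939,
                dispersion_energy=229.45, assoc_energy=934.2, assoc_volume=0.02,
                assoc_sites=(2, 2), density=1250.0, glass_T=265.15)
    ps = ParameterSet()
    ps.add_component(PureComponent(name="a", **base))
    ps.add_component(PureComponent(name="b", **base))
    ps.add_interaction(BinaryInteraction(("a", "b"), 0.0, 0.0))
    mix = Mixture(ps, ["a", "b"])
    for x1 in (0.1, 0.5, 0.9):
        lg, _ = mix.lngamma(T37, P_ATM, np.array([x1, 1 - x1]))
        assert np.max(np.abs(lg)) < 1e-6


def test_polymer_dilution_is_stable(mix3):
    """O(1e-5) polymer mole fractions stay numerically well-behaved."""
    x = np.array([0.01, 2e-5, 0.98998])
    lg, rho = mix3.lngamma(T37, P_ATM, x)
    assert np.all(np.isfinite(lg)) and rho > 0


def test_water_sigma_used_in_cross_terms(pset):
    """Cross diameters with water move with temperature."""
    wat, pol = pset.component("water"), pset.component("PVPVA64")
    c1 = cross_parameters(wat, pol, 290.0)
    c2 = cross_parameters(wat, pol, 350.0)
    assert c1.sigma_ij != c2.sigma_ij
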