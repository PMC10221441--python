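"""PC-SAFT residual Helmholtz energy, liquid density and activity coefficients.

The equation of state is built from three residual contributions,
a_res = a_hc + a_disp + a_assoc (all reduced, per mole of molecules):

* hard-chain reference (Mansoori hard-sphere mixture + chain connectivity),
* second-order perturbation dispersion with the universal model constants,
* association from donor/acceptor site fractions (mass-action equations with
  Lorentz/Berthelot and Wolbach–Sandler combining rules for the cross terms).

Site scheme: the ``N/N`` association entries are read as N donor sites of one
type and N acceptor sites of a second type per molecule; only donor–acceptor
bonding contributes.  The polymer carries a nonzero association volume with
zero self-association energy, so it bonds only in cross-association with
water/API (induced association).

Composition derivatives (fugacity coefficients) are computed by complex-step
differentiation of the Helmholtz function, which is exact to machine precision
for this analytic model; central finite differences serve only as a test
oracle.  Densities are reported as number densities in Å⁻³ internally and
converted to molar densities (mol·m⁻³) at the interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .parameters import ParameterSet, PureComponent

__all__ = [
    "KB", "NA",
    "MixtureState", "HelmholtzBreakdown", "CrossParameters",
    "cross_parameters", "Mixture", "NumericalError",
]

KB = 1.380649e-23   # J/K
NA = 6.02214076e23  # 1/mol

# Maximum packing fraction of the hard-sphere reference.
ETA_MAX = 0.7405

# Universal dispersion-integral constants (rows: powers of eta, cols: 0th/1st/2nd
# order in the chain-length composition).
_A = np.array([
    [0.9105631445, -0.3084016918, -0.0906148351],
    [0.6361281449, 0.1860531159, 0.4527842806],
    [2.6861347891, -2.5030047259, 0.5962700728],
    [-26.547362491, 21.419793629, -1.7241829131],
    [97.759208784, -65.255885330, -4.1302112531],
    [-159.59154087, 83.318680481, 13.776631870],
    [91.297774084, -33.746922930, -8.6728470368],
])
_B = np.array([
    [0.7240946941, -0.5755498075, 0.0976883116],
    [2.2382791861, 0.6995095521, -0.2557574982],
    [-4.0025849485, 3.8925673390, -9.1558561530],
    [-21.003576815, -17.215471648, 20.642075974],
    [26.855641363, 192.67226447, -38.804430052],
    [206.55133841, -161.82646165, 93.626774077],
    [-355.60235612, -165.20769346, -29.666905585],
])


class NumericalError(RuntimeError):
    """Raised when a density or association solve fails to converge."""


@dataclass
class HelmholtzBreakdown:
    """Reduced residual Helmholtz energy and its three contributions."""
    a_hc: float
    a_disp: float
    a_assoc: float

    @property
    def a_res(self) -> float:
        return self.a_hc + self.a_disp + self.a_assoc


@dataclass
class MixtureState:
    """A resolved liquid state: T, P, composition and the solved density."""
    T: float                 # K
    P: float                 # Pa
    mole_fractions: np.ndarray
    molar_density: float     # mol/m^3

    def __post_init__(self):
        x = np.asarray(self.mole_fractions, dtype=float)
        if np.any(x < -1e-15) or abs(x.sum() - 1.0) > 1e-12:
            raise ValueError("mole fractions must be >= 0 and sum to 1 within 1e-12")
        self.mole_fractions = np.clip(x, 0.0, None)


@dataclass(frozen=True)
class CrossParameters:
    """Unlike-pair segment diameter, dispersion energy and association
    parameters from the combining rules."""
    sigma_ij: float  # Å
    u_ij: float      # K
    eps_ij: float    # K
    kappa_ij: float  # dimensionless


def cross_parameters(i: PureComponent, j: PureComponent, T: float,
                     kij: float = 0.0) -> CrossParameters:
    """Combining rules for one pair: arithmetic-mean diameter, geometric-mean
    dispersion energy corrected by k_ij, and Wolbach–Sandler association."""
    si, sj = i.sigma(T), j.sigma(T)
    sig = 0.5 * (si + sj)
    u = math.sqrt(i.dispersion_energy * j.dispersion_energy) * (1.0 - kij)
    eps = 0.5 * (i.assoc_energy + j.assoc_energy)
    kap = math.sqrt(i.assoc_volume * j.assoc_volume) * (math.sqrt(si * sj) / sig) ** 3
    return CrossParameters(sigma_ij=sig, u_ij=u, eps_ij=eps, kappa_ij=kap)


class Mixture:
    """PC-SAFT evaluator for a fixed, ordered list of registered components.

    Parameters are pulled from a :class:`~asdphase.parameters.ParameterSet`;
    every pair of distinct components must have a registered interaction.
    """

    def __init__(self, pset: ParameterSet, names: Sequence[str]):
        self.names = list(names)
        self.components = [pset.component(n) for n in self.names]
        n = len(self.names)
        self.m = np.array([c.segments for c in self.components])
        self.M = np.array([c.molar_mass for c in self.components])
        self.u = np.array([c.dispersion_energy for c in self.components])
        self.eps = np.array([c.assoc_energy for c in self.components])
        self.kappa = np.array([c.assoc_volume for c in self.components])
        self.n_don = np.array([c.assoc_sites[0] for c in self.components], dtype=float)
        self.n_acc = np.array([c.assoc_sites[1] for c in self.components], dtype=float)
        self.kij_m = np.zeros((n, n))
        self.kij_b = np.zeros((n, n))
        for a in range(n):
            for b in range(a + 1, n):
                inter = pset.interaction(self.names[a], self.names[b])
                self.kij_m[a, b] = self.kij_m[b, a] = inter.kij_m
                self.kij_b[a, b] = self.kij_b[b, a] = inter.kij_b
        self._assoc_idx = np.where((self.n_don + self.n_acc) > 0)[0]
        self._geom_cache: dict[float, tuple] = {}
        self._pure_lnphi_cache: dict[tuple, float] = {}

    @property
    def n(self) -> int:
        return len(self.names)

    # -- temperature-dependent geometry (real quantities, cached per T) ------

    def _geometry(self, T: float):
        key = round(float(T), 9)
        hit = self._geom_cache.get(key)
        if hit is not None:
            return hit
        sig = np.array([c.sigma(T) for c in self.components])
        d = sig * (1.0 - 0.12 * np.exp(-3.0 * self.u / T))
        sig_ij = 0.5 * (sig[:, None] + sig[None, :])
        kij = self.kij_m * T + self.kij_b
        u_ij = np.sqrt(self.u[:, None] * self.u[None, :]) * (1.0 - kij)
        eps_ij = 0.5 * (self.eps[:, None] + self.eps[None, :])
        kap_ij = (np.sqrt(self.kappa[:, None] * self.kappa[None, :])
                  * (np.sqrt(sig[:, None] * sig[None, :]) / sig_ij) ** 3)
        # association prefactor sigma_ij^3 * kappa_ij * (exp(eps/T)-1)
        assoc_pref = sig_ij ** 3 * kap_ij * np.expm1(eps_ij / T)
        out = (sig, d, sig_ij, u_ij, eps_ij, kap_ij, assoc_pref)
        self._geom_cache[key] = out
        if len(self._geom_cache) > 256:
            self._geom_cache.clear()
            self._geom_cache[key] = out
        return out

    # -- residual Helmholtz energy ------------------------------------------

    def a_res_parts(self, T: float, rho, x):
        """Reduced residual Helmholtz contributions (a_hc, a_disp, a_assoc).

        ``rho`` is the total number density in Å⁻³; ``rho`` and ``x`` may be
        complex for complex-step differentiation.
        """
        x = np.asarray(x)
        sig, d, sig_ij, u_ij, eps_ij, kap_ij, assoc_pref = self._geometry(T)

        zeta = [(np.pi / 6.0) * rho * np.sum(x * self.m * d ** k) for k in range(4)]
        z0, z1, z2, z3 = zeta
        one_m = 1.0 - z3
        mbar = np.sum(x * self.m)

        # hard-sphere + chain
        a_hs = (1.0 / z0) * (3.0 * z1 * z2 / one_m
                             + z2 ** 3 / (z3 * one_m ** 2)
                             + (z2 ** 3 / z3 ** 2 - z0) * np.log(one_m))
        dd = d[:, None] * d[None, :] / (d[:, None] + d[None, :])
        g_ij = (1.0 / one_m + dd * 3.0 * z2 / one_m ** 2
                + dd ** 2 * 2.0 * z2 ** 2 / one_m ** 3)
        a_hc = mbar * a_hs - np.sum(x * (self.m - 1.0) * np.log(np.diagonal(g_ij)))

        # dispersion
        eta = z3
        mfrac = (mbar - 1.0) / mbar
        mfrac2 = mfrac * (mbar - 2.0) / mbar
        a_coef = _A[:, 0] + mfrac * _A[:, 1] + mfrac2 * _A[:, 2]
        b_coef = _B[:, 0] + mfrac * _B[:, 1] + mfrac2 * _B[:, 2]
        powers = eta ** np.arange(7)
        I1 = np.sum(a_coef * powers)
        I2 = np.sum(b_coef * powers)
        xm = x * self.m
        o1 = np.sum((xm[:, None] * xm[None, :]) * (u_ij / T) * sig_ij ** 3)
        o2 = np.sum((xm[:, None] * xm[None, :]) * (u_ij / T) ** 2 * sig_ij ** 3)
        C1 = 1.0 / (1.0 + mbar * (8.0 * eta - 2.0 * eta ** 2) / one_m ** 4
                    + (1.0 - mbar) * (20.0 * eta - 27.0 * eta ** 2
                                      + 12.0 * eta ** 3 - 2.0 * eta ** 4)
                    / (one_m * (2.0 - eta)) ** 2)
        a_disp = -2.0 * np.pi * rho * I1 * o1 - np.pi * rho * mbar * C1 * I2 * o2

        # association
        idx = self._assoc_idx
        if idx.size == 0:
            a_assoc = 0.0 * a_hc
        else:
            delta = assoc_pref[np.ix_(idx, idx)] * g_ij[np.ix_(idx, idx)]
            xa, xb = self._solve_sites(rho, x[idx], self.n_don[idx],
                                       self.n_acc[idx], delta)
            a_assoc = np.sum(x[idx] * (
                self.n_don[idx] * (np.log(xa) - 0.5 * xa + 0.5)
                + self.n_acc[idx] * (np.log(xb) - 0.5 * xb + 0.5)))
        return a_hc, a_disp, a_assoc

    def a_res(self, T: float, rho, x):
        a_hc, a_disp, a_assoc = self.a_res_parts(T, rho, x)
        return a_hc + a_disp + a_assoc

    def helmholtz_breakdown(self, state: MixtureState) -> HelmholtzBreakdown:
        rho = state.molar_density * NA * 1e-30
        a_hc, a_disp, a_assoc = self.a_res_parts(state.T, rho, state.mole_fractions)
        return HelmholtzBreakdown(float(np.real(a_hc)), float(np.real(a_disp)),
                                  float(np.real(a_assoc)))

    # -- association ----------------------------------------------------------

    @staticmethod
    def _solve_sites(rho, x, n_don, n_acc, delta, tol: float = 1e-12,
                     max_iter: int = 10000):
        """Fraction of unbonded donor (X_A) and acceptor (X_B) sites.

        Mass action:  X_Ai = 1 / (1 + rho Σ_j x_j N_acc,j X_Bj Δ_ij)  and the
        mirrored relation for acceptors.  A short damped successive-substitution
        warmup is followed by Newton iterations on the coupled system; complex
        inputs propagate complex-step derivatives exactly.
        """
        k = len(x)
        dtype = np.result_type(rho, x, float)
        ca = rho * x * n_acc  # multiplies X_B in the donor equation
        cb = rho * x * n_don
        xa = np.full(k, 0.2, dtype=dtype)
        xb = np.full(k, 0.2, dtype=dtype)
        # damped successive substitution warmup
        for _ in range(8):
            xa_new = 1.0 / (1.0 + (delta * (ca * xb)[None, :]).sum(axis=1))
            xb_new = 1.0 / (1.0 + (delta * (cb * xa)[None, :]).sum(axis=1))
            xa = 0.5 * xa + 0.5 * xa_new
            xb = 0.5 * xb + 0.5 * xb_new
        # Newton on F = [Xa*(1+Sa)-1, Xb*(1+Sb)-1]
        eye = np.eye(k)
        converged = False
        for it in range(200):
            sa = (delta * (ca * xb)[None, :]).sum(axis=1)
            sb = (delta * (cb * xa)[None, :]).sum(axis=1)
            fa = xa * (1.0 + sa) - 1.0
            fb = xb * (1.0 + sb) - 1.0
            res = max(np.max(np.abs(fa.real)), np.max(np.abs(fb.real)))
            if not np.isfinite(res):
                break
            jaa = eye * (1.0 + sa)[:, None]
            jab = xa[:, None] * delta * ca[None, :]
            jba = xb[:, None] * delta * cb[None, :]
            jbb = eye * (1.0 + sb)[:, None]
            jac = np.block([[jaa, jab], [jba, jbb]])
            try:
                step = np.linalg.solve(jac, np.concatenate([fa, fb]))
            except np.linalg.LinAlgError:
                break
            xa = xa - step[:k]
            xb = xb - step[k:]
            # keep iterates physical
            xa = np.where(xa.real <= 0, 1e-12 + 0j if np.iscomplexobj(xa) else 1e-12, xa)
            xb = np.where(xb.real <= 0, 1e-12 + 0j if np.iscomplexobj(xb) else 1e-12, xb)
            if converged:
                return xa, xb
            if res < tol:
                converged = True  # one polishing step for the complex part
        # fallback: plain damped successive substitution (0.5 damping)
        xa = np.full(k, 0.5, dtype=dtype)
        xb = np.full(k, 0.5, dtype=dtype)
        for it in range(max_iter):
            xa_new = 1.0 / (1.0 + (delta * (ca * xb)[None, :]).sum(axis=1))
            xb_new = 1.0 / (1.0 + (delta * (cb * xa)[None, :]).sum(axis=1))
            ra = np.max(np.abs(xa_new - xa))
            rb = np.max(np.abs(xb_new - xb))
            xa = 0.5 * xa + 0.5 * xa_new
            xb = 0.5 * xb + 0.5 * xb_new
            if max(ra, rb) < tol:
                return xa, xb
        raise NumericalError("association site-fraction solve did not converge")

    def solve_site_fractions(self, state: MixtureState):
        """Unbonded-site fractions (donor, acceptor) per associating component
        at a resolved state, as a dict name -> (X_A, X_B)."""
        idx = self._assoc_idx
        if idx.size == 0:
            raise ValueError("no component carries association sites")
        rho = state.molar_density * NA * 1e-30
        sig, d, sig_ij, u_ij, eps_ij, kap_ij, assoc_pref = self._geometry(state.T)
        x = np.asarray(state.mole_fractions, dtype=float)
        z2 = (np.pi / 6.0) * rho * np.sum(x * self.m * d ** 2)
        z3 = (np.pi / 6.0) * rho * np.sum(x * self.m * d ** 3)
        one_m = 1.0 - z3
        dd = d[:, None] * d[None, :] / (d[:, None] + d[None, :])
        g_ij = (1.0 / one_m + dd * 3.0 * z2 / one_m ** 2
                + dd ** 2 * 2.0 * z2 ** 2 / one_m ** 3)
        delta = assoc_pref[np.ix_(idx, idx)] * g_ij[np.ix_(idx, idx)]
        xa, xb = self._solve_sites(rho, x[idx], self.n_don[idx], self.n_acc[idx], delta)
        return {self.names[i]: (float(xa[a].real), float(xb[a].real))
                for a, i in enumerate(idx)}

    # -- pressure and density --------------------------------------------------

    def _eta_to_rho(self, T: float, x, eta):
        _, d, *_ = self._geometry(T)
        return eta / ((np.pi / 6.0) * np.sum(np.asarray(x) * self.m * d ** 3))

    def compressibility(self, T: float, rho, x):
        """Z = 1 + rho * d(a_res)/d(rho) via complex step."""
        h = 1e-30
        a = self.a_res(T, rho * (1.0 + 1j * h), np.asarray(x, dtype=complex))
        return 1.0 + np.imag(a) / h

    def pressure(self, T: float, rho, x):
        """Pressure in Pa at number density rho (Å⁻³)."""
        return self.compressibility(T, rho, x) * rho * 1e30 * KB * T

    def solve_liquid_density(self, T: float, P: float, x, rho0: float | None = None):
        """Number density (Å⁻³) of the liquid root of P(ρ) = P.

        With ``rho0`` a warm-started Newton iteration is tried first; the
        fallback scans packing fractions up to the close-packing limit, refines
        every bracketed root and keeps the mechanically stable root with the
        lowest Gibbs energy (ties broken toward the denser, liquid-like root).
        """
        x = np.asarray(x, dtype=float)
        if P <= 0:
            raise ValueError("pressure must be positive")
        if rho0 is not None:
            _, d, *_ = self._geometry(T)
            vseg = (np.pi / 6.0) * float(np.sum(x * self.m * d ** 3))
            rho_hi = (ETA_MAX - 1e-3) / vseg
            rho = min(rho0, rho_hi)
            ok = False
            try:
                for _ in range(30):
                    h = 1e-30
                    z_c = self.a_res(T, rho * (1.0 + 1j * h), x.astype(complex))
                    # P and dP/drho from one complex evaluation pair
                    Z = 1.0 + np.imag(z_c) / h
                    f = Z * rho * 1e30 * KB * T - P
                    drho = rho * 1e-6
                    f2 = self.pressure(T, rho + drho, x) - P
                    dfdr = (f2 - f) / drho
                    if dfdr == 0 or not np.isfinite(dfdr):
                        break
                    step = f / dfdr
                    rho_new = rho - step
                    if not (0 < rho_new < rho_hi):
                        rho_new = min(max(rho * 0.5, 0.5 * (rho + rho_hi)
                                          if rho_new >= rho_hi else rho * 0.5),
                                      rho_hi)
                    if abs(rho_new - rho) < 1e-14 * rho:
                        rho = rho_new
                        ok = True
                        break
                    rho = rho_new
            except (NumericalError, FloatingPointError):
                ok = False
            if ok:
                eta = float((np.pi / 6.0) * np.sum(x * self.m *
                                                   self._geometry(T)[1] ** 3) * rho)
                if 0 < eta < ETA_MAX and abs(self.pressure(T, rho, x) - P) < 1e-6 * P:
                    drho = rho * 1e-6
                    if self.pressure(T, rho + drho, x) > self.pressure(T, rho - drho, x):
                        return float(rho)
        return self._density_scan(T, P, x)

    def _density_scan(self, T: float, P: float, x):
        etas = np.concatenate([np.geomspace(1e-12, 0.05, 25),
                               np.linspace(0.06, ETA_MAX - 1e-4, 90)])
        pr = np.array([self.pressure(T, self._eta_to_rho(T, x, e), x) - P
                       for e in etas])
        roots = []
        for i in range(len(etas) - 1):
            if np.sign(pr[i]) * np.sign(pr[i + 1]) < 0:
                try:
                    e = brentq(lambda ee: self.pressure(
                        T, self._eta_to_rho(T, x, ee), x) - P,
                        etas[i], etas[i + 1], xtol=1e-14, rtol=1e-14)
                except ValueError:
                    continue
                roots.append(e)
        stable = []
        for e in roots:
            rho = self._eta_to_rho(T, x, e)
            drho = rho * 1e-6
            if self.pressure(T, rho + drho, x) > self.pressure(T, rho - drho, x):
                stable.append((e, rho))
        if not stable:
            raise NumericalError(
                f"no mechanically stable density root at T={T} K, P={P} Pa")
        best = None
        for e, rho in stable:
            a = float(np.real(self.a_res(T, rho, x)))
            Z = float(np.real(self.compressibility(T, rho, x)))
            g = a + (Z - 1.0) - math.log(Z)  # ln(phi): fixed-T,P Gibbs ranking
            if best is None or g < best[0] - 1e-12 or (
                    abs(g - best[0]) <= 1e-12 and rho > best[1]):
                best = (g, rho)
        return float(best[1])

    def molar_density(self, T: float, P: float, x) -> float:
        """Liquid molar density in mol/m^3."""
        return self.solve_liquid_density(T, P, x) * 1e30 / NA

    def mass_density(self, T: float, P: float, x) -> float:
        """Liquid mass density in kg/m^3."""
        x = np.asarray(x, dtype=float)
        return self.molar_density(T, P, x) * np.sum(x * self.M) * 1e-3

    def resolve(self, T: float, P: float, x) -> MixtureState:
        return MixtureState(T=T, P=P, mole_fractions=np.asarray(x, dtype=float),
                            molar_density=self.molar_density(T, P, x))

    # -- fugacity and activity coefficients ------------------------------------

    def lnphi(self, T: float, P: float, x, rho0: float | None = None):
        """ln fugacity coefficients; returns (lnphi array, number density)."""
        x = np.asarray(x, dtype=float)
        rho = self.solve_liquid_density(T, P, x, rho0=rho0)
        h = 1e-30
        xc = x.astype(complex)
        a0 = self.a_res(T, rho, x)
        Z = self.compressibility(T, rho, x)
        dadx = np.empty(self.n)
        for k in range(self.n):
            xp = xc.copy()
            xp[k] += 1j * h
            dadx[k] = np.imag(self.a_res(T, rho, xp)) / h
        a0 = float(np.real(a0))
        Z = float(np.real(Z))
        mu = a0 + (Z - 1.0) + dadx - float(np.sum(x * dadx))
        return mu - math.log(Z), rho

    def _pure_lnphi(self, T: float, P: float, k: int) -> float:
        key = (k, round(float(T), 9), round(float(P), 3))
        hit = self._pure_lnphi_cache.get(key)
        if hit is None:
            x = np.zeros(self.n)
            x[k] = 1.0
            try:
                lp, _ = self.lnphi(T, P, x)
            except NumericalError as exc:
                raise NumericalError(
                    f"pure-component density failed for {self.names[k]}: {exc}")
            hit = float(lp[k])
            self._pure_lnphi_cache[key] = hit
        return hit

    def lngamma(self, T: float, P: float, x, rho0: float | None = None):
        """ln activity coefficients (pure-liquid reference at the same T, P);
        returns (lngamma array, number density of the mixture)."""
        lp, rho = self.lnphi(T, P, x, rho0=rho0)
        ref = np.array([self._pure_lnphi(T, P, k) for k in range(self.n)])
        return lp - ref, rho

    def activity_coefficients(self, T: float, P: float, x):
        """Activity coefficients γ_i (γ_i → 1 as x_i → 1)."""
        lg, _ = self.lngamma(T, P, x)
        return np.exp(lg)

    # -- composition bases ------------------------------------------------------

    def mass_to_mole(self, w):
        w = np.asarray(w, dtype=float)
        n = w / self.M
        return n / n.sum()

    def mole_to_mass(self, x):
        x = np.asarray(x, dtype=float)
        g = x * self.M
        return g / g.sum()
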