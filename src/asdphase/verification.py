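"""Verification oracles: a closed-form toy mixture, brute-force tangent-plane
grid scans, a successive-substitution association oracle and the packaged
regression table of published hydration-pathway values.

Everything here is deliberately independent of the production solvers: the
grid oracles evaluate the Gibbs energy of mixing exhaustively and use
convex-envelope / tangent-plane constructions, so they can serve as ground
truth for the continuation and Newton machinery on small instances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .equilibria import API, POLY, WATER, TernarySystem, _Phase

__all__ = [
    "ToyBinaryModel", "oracle_binary_boundaries", "oracle_grid_stability",
    "oracle_path_entry", "ss_site_fractions", "regression_tables",
    "regression_lookup",
]


# --- toy activity model -------------------------------------------------------

@dataclass(frozen=True)
class ToyBinaryModel:
    """Symmetric regular-solution binary: g/RT = Σ x ln x + chi·x1·x2.

    Closed forms: spinodal at x(1-x) = 1/(2·chi); critical point chi = 2 at
    x = 1/2; the binodal compositions solve ln(x/(1-x)) = chi·(2x-1) and are
    symmetric about 1/2.
    """
    chi: float

    def g_mix(self, x1):
        x1 = np.asarray(x1, dtype=float)
        x2 = 1.0 - x1
        with np.errstate(divide="ignore", invalid="ignore"):
            ideal = np.where(x1 > 0, x1 * np.log(x1), 0.0) + \
                np.where(x2 > 0, x2 * np.log(x2), 0.0)
        return ideal + self.chi * x1 * x2

    def lngamma(self, x1):
        x1 = np.asarray(x1, dtype=float)
        return self.chi * (1.0 - x1) ** 2, self.chi * x1 ** 2

    def spinodal(self):
        """Closed-form spinodal pair, or None below the critical point."""
        if self.chi <= 2.0:
            return None
        disc = math.sqrt(0.25 - 1.0 / (2.0 * self.chi))
        return (0.5 - disc, 0.5 + disc)

    def binodal(self, tol: float = 1e-14):
        """Symmetric coexistence pair from bisection on the isoactivity
        condition ln(x/(1-x)) + chi·(1-2x) = 0 (non-trivial root)."""
        if self.chi <= 2.0:
            return None

        def f(x):
            return math.log(x / (1.0 - x)) + self.chi * (1.0 - 2.0 * x)

        lo, hi = 1e-15, 0.5 - 1e-12
        if f(lo) >= 0:
            return None
        # f(lo) < 0; f -> 0- at 1/2: find the interior sign change via the
        # maximum of f (f has a single hump for chi > 2)
        xs = np.linspace(1e-6, 0.5 - 1e-6, 4000)
        vals = np.array([f(x) for x in xs])
        k = int(np.argmax(vals))
        if vals[k] <= 0:
            return None
        a, b = lo, xs[k]
        while b - a > tol:
            m = 0.5 * (a + b)
            if f(m) < 0:
                a = m
            else:
                b = m
        x_low = 0.5 * (a + b)
        return (x_low, 1.0 - x_low)


# --- brute-force oracles ------------------------------------------------------

def oracle_binary_boundaries(g_values, xs):
    """Binodal and spinodal estimates from an exhaustive g(x) grid.

    The binodal estimate is the widest chord of the lower convex envelope with
    interior points above it; the spinodal estimate brackets the sign changes
    of the second difference.  Returns ``(binodal pair or None, spinodal pair
    or None)`` at grid resolution.
    """
    xs = np.asarray(xs, dtype=float)
    g = np.asarray(g_values, dtype=float)
    lower: list[int] = []
    for i in range(len(xs)):
        while len(lower) >= 2:
            i0, i1 = lower[-2], lower[-1]
            cross = ((xs[i1] - xs[i0]) * (g[i] - g[i0])
                     - (g[i1] - g[i0]) * (xs[i] - xs[i0]))
            if cross <= 0:
                lower.pop()
            else:
                break
        lower.append(i)
    binodal = None
    width = 0.0
    for i0, i1 in zip(lower[:-1], lower[1:]):
        interior = (xs > xs[i0]) & (xs < xs[i1])
        if not interior.any():
            continue
        chord = g[i0] + (g[i1] - g[i0]) * (xs[interior] - xs[i0]) / (xs[i1] - xs[i0])
        if np.max(g[interior] - chord) > 1e-10 and xs[i1] - xs[i0] > width:
            width = xs[i1] - xs[i0]
            binodal = (xs[i0], xs[i1])
    d2 = np.gradient(np.gradient(g, xs), xs)
    spin = None
    signs = np.sign(d2[2:-2])
    idx = np.where(np.diff(signs) != 0)[0]
    if len(idx) >= 2:
        spin = (xs[2 + idx[0]], xs[2 + idx[-1] + 1])
    return binodal, spin


def oracle_grid_stability(system: TernarySystem, T: float, P: float,
                          grid_n: int = 40, w_cap: float = 1.0):
    """Exhaustive tangent-plane stability map on a mole-fraction simplex grid.

    Returns ``(points, g, lnact, unstable_mask)`` where ``points`` are mole
    fractions, ``g`` the mixing Gibbs energy per RT, ``lnact`` the ln
    activities and ``unstable_mask`` flags feeds whose tangent-plane distance
    over the whole grid is negative.
    """
    mix = system.mixture
    pts = []
    for i in range(grid_n + 1):
        for j in range(grid_n + 1 - i):
            x = np.array([i, j, grid_n - i - j], dtype=float) / grid_n
            x = np.clip(x, 1e-10, None)
            x = x / x.sum()
            pts.append(x)
    pts = np.array(pts)
    ph = _Phase(mix, T, P)
    lnact = np.empty_like(pts)
    for k, x in enumerate(pts):
        lnact[k] = np.log(x) + ph.lngamma(x)
    g = np.sum(pts * lnact, axis=1)
    # TPD_z(y) = g(y) - y . d(z); rows are feeds z, columns trial phases y
    tpd = g[None, :] - lnact @ pts.T
    unstable = tpd.min(axis=1) < -1e-6
    return pts, g, lnact, unstable


def oracle_path_entry(system: TernarySystem, T: float, P: float,
                      drug_load: float, lnact_grid=None, grid=None,
                      n_path: int = 200, grid_n: int = 40):
    """Water content at which a hydration path first becomes unstable,
    judged by tangent-plane distance against an exhaustive grid."""
    if lnact_grid is None or grid is None:
        grid, g, lnact_grid, _ = oracle_grid_stability(system, T, P, grid_n)
    else:
        g = np.sum(grid * lnact_grid, axis=1)
    ph = _Phase(system.mixture, T, P)
    for a in np.linspace(1e-3, 0.95, n_path):
        w = system.path_mass(drug_load, a)
        x = system.mass_to_mole(w)
        d = np.log(x) + ph.lngamma(x)
        tpd = g - grid @ d
        if tpd.min() < -1e-6:
            return a
    return None


def ss_site_fractions(rho, x, n_don, n_acc, delta, damping: float = 0.5,
                      tol: float = 1e-12, max_iter: int = 200000):
    """Plain damped successive-substitution association oracle."""
    k = len(x)
    xa = np.full(k, 1.0)
    xb = np.full(k, 1.0)
    ca = rho * np.asarray(x) * np.asarray(n_acc)
    cb = rho * np.asarray(x) * np.asarray(n_don)
    for _ in range(max_iter):
        xa_new = 1.0 / (1.0 + (delta * (ca * xb)[None, :]).sum(axis=1))
        xb_new = 1.0 / (1.0 + (delta * (cb * xa)[None, :]).sum(axis=1))
        if max(np.max(np.abs(xa_new - xa)), np.max(np.abs(xb_new - xb))) < tol:
            return xa_new, xb_new
        xa = (1 - damping) * xa + damping * xa_new
        xb = (1 - damping) * xb + damping * xb_new
    raise RuntimeError("successive substitution did not converge")


# --- regression tables --------------------------------------------------------

def regression_tables():
    """Packaged expected-value table (published hydration-pathway readouts)
    as a DataFrame; every row carries its tolerance class."""
    import pandas as pd
    ref = resources.files("asdphase").joinpath("data/regression_expected.csv")
    return pd.read_csv(ref.open())


def regression_lookup(api: str, temperature_c: float, drug_load_wt,
                      row: str, quantity: str):
    """Single expected value, or ``None`` when no such row was published."""
    import pandas as pd
    df = regression_tables()
    if drug_load_wt is None or drug_load_wt == "":
        dl_mask = df.drug_load_wt.isna()
    else:
        dl_mask = pd.to_numeric(df.drug_load_wt, errors="coerce").sub(
            float(drug_load_wt)).abs() < 1e-9
    m = df[(df.api == api) & (df.temperature_c == temperature_c)
           & dl_mask & (df.row == row) & (df.quantity == quantity)]
    if len(m) == 0:
        return None
    return float(m.iloc[0]["value"])
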