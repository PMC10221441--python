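# asdphase

Thermodynamic prediction of the drug-load-dependent **loss of release (LoR)**
of amorphous solid dispersions (ASDs) in water, from PC-SAFT ternary
API/polymer/water phase diagrams combined with the Gordon–Taylor glass
transition.

## Who this is for

Formulation scientists and thermodynamic modelers who need to know, before
running dissolution experiments, whether an ASD at a given drug load will
release its API or passivate at the ASD/water interface — and whether the
failure mode is interfacial crystallization (LoR Type I, fast crystallizers)
or amorphous–amorphous phase separation (LoR Type II, slow crystallizers).

## The model

The surface of a dissolving ASD absorbs water along the straight **hydration
pathway** from the dry composition (DL, 1−DL, 0) toward pure water. Three
loci of the ternary diagram decide its fate:

* **Solubility line** (solid–liquid equilibrium), from
  `x_API γ_API = exp[−Δh_SL/(RT)(1−T/T_SL) − Δcp_SL/R(ln(T_SL/T) − T_SL/T + 1)]`,
  the Δcp term used only when a Δcp value is tabulated;
* **Binodal with tie lines and spinodal** (liquid–liquid equilibrium), from the
  isoactivity condition `x_i γ_i^{L1} = x_i γ_i^{L2}` for every component;
* **eGT line** ("escape glass transition"): compositions where the
  Gordon–Taylor mixture glass transition
  `Tg = Σ K_i w_i Tg,i / Σ K_i w_i` (Simha–Boyer
  `K_i = ρ_ref Tg,ref / (ρ_i Tg,i)`) equals the medium temperature; below it
  the surface layer is a glassy gel layer.

Activity coefficients come from PC-SAFT (hard-chain + dispersion +
association residual Helmholtz energy) with the published pure-component and
temperature-dependent binary parameters for naproxen, venetoclax, PVPVA64 and
water, shipped as a checksummed fixture. If the path reaches saturation at or
before eGT, a fast crystallizer crystallizes inside the gel layer (Type I,
congruent collapse of API and polymer release); if it meets the binodal at or
before eGT, a slow crystallizer demixes there and the immobile API-rich phase
passivates the surface (Type II, polymer-only release).

## Worked example

```python
import math
from asdphase import (TernarySystem, builtin_fixture, sle_solubility,
                      lor_threshold_dl, trace_binodal, hydration_report)

pset = builtin_fixture()                       # packaged parameter tables
nap = TernarySystem(pset, "naproxen", "PVPVA64")
T, P = 310.15, 1e5                             # 37 C, 0.1 MPa

pt = sle_solubility(nap, T, P, solvent_ratio=math.inf)
print(f"naproxen solubility in dry PVPVA64: {100*pt.w[0]:.1f} wt%")

dl = lor_threshold_dl(nap, T, P, "fast")
print(f"Type-I LoR threshold: {100*dl:.1f} wt% DL")

ven = TernarySystem(pset, "venetoclax", "PVPVA64")
_, ties = trace_binodal(ven, T, P, step_wt=0.01)
rep = hydration_report(ven, T, P, [0.005, 0.025], "slow", tie_lines=ties)
for dl_, rows, cls in rep.blocks:
    print(f"DL {100*dl_:g} wt%: {cls.lor_type} -> {cls.release_expectation}")
```

prints

```
naproxen solubility in dry PVPVA64: 23.1 wt%
Type-I LoR threshold: 18.5 wt% DL
DL 0.5 wt%: none -> congruent release
DL 2.5 wt%: Type II -> incongruent (polymer-only) release
```

Up to 23 wt% naproxen the dry ASD is thermodynamically stable; above ~19 wt%
DL the hydration path saturates inside the gel layer, so crystallization
passivates the interface. The 2.5 wt% venetoclax ASD meets the LLPS binodal
before escaping its glass transition, so only the polymer-rich phase
releases.

A CLI wraps the same operations:

```sh
asdphase diagram --api naproxen --temp-c 37 --out out/
asdphase lor --api venetoclax --temp-c 37 --propensity slow \
         --dl 0.5 --dl 1 --dl 2.5 --out out/
asdphase threshold --api naproxen --temp-c 37 --propensity fast
```

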