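# Methods

## Scope and model

`asdphase` predicts the phase behavior of an API/polymer/water ternary at a
fixed temperature and 0.1 MPa, and classifies the drug-load-dependent loss of
release (LoR) of PVPVA64-based amorphous solid dispersions. Three model
layers are combined:

1. **PC-SAFT** supplies activity coefficients for all equilibria. The
   residual Helmholtz energy is the sum of hard-chain, dispersion and
   association contributions in the standard perturbed-chain form with the
   universal dispersion constants. Unlike-pair parameters use the
   arithmetic-mean diameter, the geometric-mean dispersion energy corrected
   by a linear-in-T binary coefficient `k_ij = k_ij,m T + k_ij,b`, and the
   Wolbach–Sandler rules for cross association. The association strength is
   `Δ^AiBj = σ_ij³ g_ij^hs κ^AiBj (exp(ε^AiBj/kT) − 1)`. Site counts written
   `N/N` are read as N donor plus N acceptor sites; only donor–acceptor
   bonding contributes, so PVPVA64 (κ = 0.02, ε = 0, 653/653 sites)
   self-associates with zero strength but cross-associates with water and
   naproxen (induced association). Water's segment diameter is
   temperature-dependent and is used everywhere water enters, including
   cross diameters.
2. **Solid–liquid equilibrium**: the crystalline API activity
   `ln(xγ) = −Δh_SL/(RT)(1 − T/T_SL) − Δcp_SL/R(ln(T_SL/T) − T_SL/T + 1)`.
   The Δcp term is dropped exactly when no Δcp is tabulated (venetoclax).
3. **Gordon–Taylor glass transition** with Simha–Boyer coefficients
   referenced to PVPVA64 (K_PVPVA64 = 1; the mixing rule is invariant under
   uniform rescaling of K, so the reference is presentational). Temperatures
   are kelvin inside the rule and reported in °C. The eGT composition on a
   hydration path is found by bisection on the water coordinate to 1e−10.

## Numerical design

* **Units.** Internal canonical units are K, Pa, J, mol, kg, Å; number
  densities are Å⁻³. Parameter files carry explicit unit strings and are
  normalized on load.
* **Derivatives.** Fugacity coefficients are exact complex-step derivatives
  of the Helmholtz function (step 1e−30); central finite differences appear
  only as test oracles. This keeps tie-line Jacobians smooth.
* **Association.** The mass-action system (at most six site-type unknowns
  here) is solved by a short damped successive-substitution warmup followed
  by Newton iterations to 1e−12, with a pure damped-SS fallback (damping 0.5,
  10⁴-iteration cap). Plain damped SS is retained as an independent oracle in
  the tests.
* **Density.** The liquid root of P(ρ) = P is warm-started Newton where a
  neighboring solution exists, else a dense scan over packing fractions up to
  0.7405 with Brent refinement; among mechanically stable roots the one with
  the lowest ln φ (fixed-T,P Gibbs ranking) is kept, ties broken toward the
  liquid-like root.
* **Conditioning.** The polymer is a 65 kg/mol pseudo-component, so its mole
  fractions are O(1e−5) and the API-rich phase can hold polymer at mole
  fractions below 1e−100. All phase solvers therefore work in log-mole-
  fraction variables and each phase eliminates its *largest* component, so
  the small coordinates are explicit. Equilibria are solved in mole-fraction
  space and reported in mass fractions (round-half-up to one decimal in
  tables); the two bases round-trip to 1e−12.
* **Binodal tracing.** Continuation starts from a binary-face tie line
  (dry API/polymer face first, then API/water), found by a convex-envelope
  double-tangent construction on a dense Gibbs-energy grid and polished by
  Newton. Because a binary tie line has a component at exactly zero, the
  trace first "lifts" off the face at fixed trace amounts (3e−5 and 1e−4 mole
  fraction) to obtain a finite secant direction, then marches with an
  adaptive predictor that fixes the fastest-moving log coordinate each step
  (nominal 0.5–1 wt% moves, halving on failure, floor 1e−4), stopping at a
  plait point (phase distance < 0.2 wt%), a simplex boundary or 99.5 wt%
  water.
* **Path crossings.** The saturation crossing of a hydration path is a
  bracketed 1-D root of the saturation residual. The binodal crossing solves
  a three-unknown Newton system — the water coordinate of the on-path
  (incipient) phase plus two log coordinates of the conjugate phase — seeded
  by interpolating the traced tie lines on the water-free API ratio, or by a
  tangent-plane stability bisection along the path when no trace is
  available.
* **Stability.** Michelsen-style tangent-plane analysis with five seeds
  (three corner-dominant, an API-rich polymer-free and a water-rich
  polymer-free trial), successive substitution with early exit once the
  modified tangent-plane distance is clearly negative.
* **Spinodal.** Zero locus of the determinant of the Gibbs-curvature matrix
  in two independent mole fractions (the largest component eliminated; the
  zero locus is invariant under that choice), scanned along fixed water
  levels and refined by bisection. The dry face is sampled at a trace water
  level (1e−6) where the two-dimensional determinant remains defined; the
  1-D face condition is an independent test oracle.

## Classification rules

Type I requires a *fast* crystallizer whose saturation crossing lies at a
water content not exceeding the eGT water content; Type II requires a *slow*
crystallizer whose binodal crossing does. Crystallization propensity is a
user input — there is no in-model way to compute it. Crossings within
0.05 wt% water of eGT are reported "at the gel-layer boundary"; crossings
within 5 wt% on either side are annotated *borderline*, which reproduces the
intermediate phenomenology (gel-front crystallization of 20 wt% naproxen,
near-gel LLPS of 1 wt% venetoclax) without changing the strict rule. The
threshold drug load is the first sign change of (crossing water − eGT water)
on a 16-point drug-load scan refined by bisection to 0.1 wt%; the scan is
needed because at very high drug loads the dry blend is no longer glassy and
the gel-layer question disappears. Hydration paths are straight lines; the
curvature induced by preferential polymer release is out of scope.

## Known limitations and observed discrepancies

* The published hydration tables appear to be discrete/graphical readouts:
  several printed "crossing" compositions do not lie exactly on their
  hydration path. Where the path and the binodal branch meet at a grazing
  angle this matters: for 0.5 wt% venetoclax our exact intersection is
  ~25.7 wt% water versus the printed 20.5, even though our binodal passes
  through the printed tie-line points themselves to within ~0.1 wt%. The
  1 wt% and 2.5 wt% crossings agree within 0.7 wt%.
* The lever-rule fraction of the API-rich phase at the 2.5 wt%-DL eGT point
  is hypersensitive for the same reason (its numerator is a ~1 wt%
  difference); exact endpoints give ~1%, rounded published endpoints ~5%.
* Dry naproxen/PVPVA64 Gordon–Taylor Tg values reconstruct 0.6–1.1 °C above
  the published rows from the same printed densities and Tg inputs
  (venetoclax rows reproduce exactly); tests carry a ±1.5 °C band.
* Pure-liquid polymer densities from PC-SAFT are ~20% above the true solid
  density — normal for polymer pseudo-components and irrelevant to the
  equilibrium compositions, which depend on activity ratios.
* Three-phase (solid + two liquids) equilibrium, demixing/crystallization
  kinetics, buffered media and copolymer-resolved PVPVA64 are out of scope.

## Problem sizes used in tests and the acceptance script

The venetoclax binodal is traced with ~100–150 tie lines (0.01–0.015 mass-
fraction steps), the naproxen binodal with ~90; grid oracles use 24–40-point
simplex grids and 300–400-point binary grids. These sizes are chosen so the
oracle–solver comparisons resolve the 1 wt% agreement bands they assert.
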