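# Methods

## Scope and model

`ssrflux` models the transport of an ionizable, complexable drug across
the UWL–membrane–UWL barrier of a side-by-side diffusion cell, and the
statistics used to test what drives that transport. The central object
is the supersaturation-ratio (SSR) flux law

```
J = B_e (SSR_D − SSR_A),     SSR = c / S(medium),
1/B_e = 1/B_UWL + 1/B_m,     B = D · C* / h,
```

where `c` is the total dissolved drug concentration in a compartment and
`S` its thermodynamic solubility *in exactly that medium* (so the donor
solubility includes the solubilizing ligand's contribution). Each `B`
coefficient is diffusivity × saturation concentration / film thickness,
with units of flux per unit SSR (µg cm⁻² min⁻¹ internally). Because a
1:1 complexing ligand raises `S` in the same proportion as it lowers the
free fraction, the SSR form predicts that adding ligand to the donor
moves points *along* the flux-vs-ΔSSR line rather than changing its
slope — the package's main testable claim.

Permeability-space bookkeeping is equivalent and interconvertible:
`B = P·C*` with `P` in cm/min, so in a shared medium
`J = B_e·ΔSSR = P_app·(c_D − c_A)` exactly.

### Assumptions

1. Quasi-equilibrium 1:1 binding: the complexation equilibrium is
   re-solved algebraically (closed-form quadratic root, no iteration,
   no binding kinetics) at every integrator step.
2. Only the free, neutral drug partitions into a lipophilic membrane:
   `P_m = f_u · f_0 · P_m,u,0`, with `f_0` Henderson–Hasselbalch and
   `f_u` either from binding or from the solubility ratio
   `S_buffer / S_CD`.
3. Both compartments are well stirred; all spatial structure is lumped
   into the film thicknesses (no PDE film diffusion).
4. Local solubility is linear in local ligand concentration,
   `S(L) = S_buffer + slope·L`, the A_L phase-solubility line implied by
   the stability constant. As ligand leaks into the acceptor, the
   acceptor solubility (hence its SSR denominator) rises accordingly.
5. Size-exclusion membranes pass the ligand (and the drug–ligand
   complex) with first-order two-compartment kinetics at a single
   permeability; the complex carries drug flux in addition to the SSR
   term. A lipophilic membrane passes neither.
6. Precipitation, when enabled, is an instantaneous clamp of the donor
   dissolved concentration at its local solubility; the excess sits in
   a redissolvable precipitated mass. An optional induction time delays
   the clamp (a metastable supersaturated window). No nucleation or
   growth kinetics.

## Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| drug MW / pKa | 406.482 / 7.78 | g/mol / – | carvedilol, monoprotic weak base |
| ligand MW | 1391 | g/mol | hydroxypropyl-β-cyclodextrin |
| `K_1:1` | 178.4 (Form I), 254.1 (Form II) | M⁻¹ | measured 1:1 stability constants at pH 10, 37 °C |
| buffer solubility | 2.15 | µg/mL | carvedilol Form I in pH 10 buffer, 37 °C |
| `P_m,u,0` (lipophilic) | 2.89 × 10⁻⁴ | cm/s | Gutknecht estimate for the n-dodecane membrane |
| `P_m` (size-exclusion) | 4 × 10⁻⁵ | cm/s | aqueous pore permeability, pH-independent; chosen so unstirred runs give similar apparent permeability across membranes while stirred size-exclusion runs stay well below the lipophilic ones |
| diffusivity law | α = 9.9 × 10⁻⁵ cm²/s, β = 0.453 | – | empirical aqueous `D = α·MW^(−β)` at 37 °C, configurable |
| UWL thickness by rpm | 0.30 cm at 0 rpm → 0.022 cm at 600 rpm | cm | mm-scale films in unstirred planar cells, a few hundred µm under vigorous stirring |
| cell geometry | 18 mL / 18 mL / 1.54 cm² | – | µFLUX-style cell (the ligand-transport assay uses 20 mL) |
| ligand permeability | 1.61 × 10⁻⁵ (fast) / 1.16 × 10⁻⁵ (slow) cm/s | cm/s | calibrated by inverting the two-compartment exponential so a 15 mg/mL donor yields 516 / 377 µg/mL in the acceptor after 8 h — the observed 6 kDa and 1 kDa MWCO endpoints |
| noise | multiplicative lognormal, sd 2 % | – | UV-probe relative error; concentrations span orders of magnitude |
| dose ladders | 2.5–20 µg/mL (buffer), 5–50 µg/mL (+ligand) | µg/mL | study dosing ranges; the ligand arm extends higher because solubilization permits it |

## Numerical choices

- **Integrator**: explicit adaptive Runge–Kutta (DOP853) with rtol 10⁻¹⁰
  and atol 10⁻¹². The right-hand side sums to zero identically in both
  regimes, so drug and ligand mass balances close to integrator
  roundoff; the simulator enforces 10⁻⁸ relative and raises otherwise.
- **Precipitation** is a regime switch, not a stiff penalty term: in the
  clamped regime the dissolved donor pool algebraically tracks
  `V_D·S_D(c_L)` and the difference flows to/from the precipitate;
  terminal integration events handle clamp engagement (dissolved
  crossing the falling solubility) and release (precipitate exhausted).
- **Binding solve** uses the cancellation-stable quadratic root
  `x = 2D/(b + √(b² + 4KD))`; `f_u = 1` by convention at zero drug.
- **Gutknecht fit**: bounded nonlinear least squares on the unweighted
  reciprocal model `1/P_app = 1/P_UWL + 1/(f_0·P₀)`, initialized from
  the most membrane-limited point (P₀) and the largest observed P_app
  (P_UWL). The problem is linear given `f_0`, so the fit lands on the
  constrained linear solution (cross-checked against non-negative least
  squares in the tests). When the fitted UWL permeability exceeds 10³ ×
  the largest observed P_app, its resistance is invisible and it is
  reported as unidentifiable (∞) rather than as a number.
- **Initial-flux window**: regression of acceptor *amount* (conc ×
  live volume, immune to withdrawal events) over the longest prefix
  after a 1-min mixing offset with r² ≥ 0.98 and ≤ 10 % donor decline,
  truncated at any detected precipitation onset. Onset detection uses a
  centered moving slope *relative* to the local concentration
  (default −2 %/min) gated on SSR > 1: transport drains a stirred cell
  at well under 0.1 %/min and 2 % probe noise stays below ~0.3 %/min,
  while a solubility clamp collapses the donor orders of magnitude
  faster.
- **Homogeneity of slopes**: classical ANCOVA interaction F-test,
  computed directly from the residual sums of squares of the
  separate-slopes vs. parallel-slopes models, F(1, n₁+n₂−4); verified
  against the statsmodels OLS interaction term. A residual-permutation
  variant is available for small groups. Slopes carry standard errors;
  no multiple-testing correction is applied.
- **Units**: one conversion table (`ssrflux.units`), molar internally
  for binding (K is M⁻¹), µg/mL–min–cm elsewhere, conversions only at
  the I/O boundary.

## Design decisions

- `K_1:1` and CE are computed from the *measured* intrinsic solubility
  `S₀`, not from the regression intercept, which is reported for
  diagnostics only; this is the convention under which the published
  constants reproduce exactly, and it avoids leveraging intercept noise
  into K.
- The compound registry stores pKa 7.78; tabulated ionization
  percentages are asserted robust to the 7.78 vs 7.8 rounding
  convention rather than pinned to either. The pH 7.0 and 9.5 rows of
  such tables are rounding-sensitive (13.7 vs 14.2 % and 98.0 vs
  98.1 %) and are deliberately not hard targets.
- `B_e` is shared between the ±ligand arms of a scenario: in the SSR
  formulation solubilization enters through the SSR denominator, not
  the coefficient. This is the model assumption under test, not a
  fitted convenience.
- P-form coefficients convert to B-form through the donor-medium
  saturation concentration at t = 0, which makes the conversion exact
  in the shared-medium linear regime.
- The per-volume "endpoint concentration / elapsed time" flux figure is
  implemented as such (`average_flux_from_endpoint`) because that is
  the convention in which the 8-h ligand-transport endpoints (516 and
  377 µg/mL → 1.075 and 0.785) are quoted, although dimensionally a
  mass flux per 1.54 cm² from a 20 mL cell would be ≈ 13× larger. The
  discrepancy is documented in the function's docstring.
- Acceptor SSR uses the acceptor medium's *current* effective
  solubility, including any ligand that has leaked in.
- Scenario configs are validated with unknown-key rejection; all
  randomness derives from the single scenario seed (one
  `default_rng(seed)` stream consumed in dose-major, replicate-minor
  order), making fixtures byte-identical under a fixed seed.
- The command-line layer is deliberately thin; the library functions
  are the primary interface and the CLI simply wires CSV/JSON around
  them.

## What the generator does and does not emulate

The synthetic-data module reproduces the *structure* of a µFLUX-style
study — geometry, media, dose ladders, binding, leakage, precipitation,
multiplicative probe noise — with known ground truth, so every analysis
stage can be validated against its generating parameters. It does not
emulate UV spectral evaluation, colorimetric ligand quantification,
solid-state transformations of the precipitate, micellar or LLPS
reservoirs, ionic-strength or temperature dependence of K, or
higher-order (1:2, 2:1) complexes. Passing tests therefore demonstrate
the internal consistency and statistical calibration of the methods
under the stated model, not instrument-level fidelity to any particular
apparatus.

Test and acceptance runs use 5-min sampling over 8 h, 5-dose ladders
with ≤ 3 replicates, 200-seed recovery studies and 1000-resample
calibration checks — sizes chosen so the full suite completes in well
under a minute while keeping Monte-Carlo error comfortably inside the
asserted tolerances.

## Known limitations

- The complex is assumed to cross size-exclusion membranes at the
  ligand's permeability (separately configurable); no hindered-pore
  model relates permeability to MWCO mechanically.
- The UWL thickness → stirring-rate map is a lookup, not a hydrodynamic
  correlation; values between configured rpm levels are not
  interpolated.
- The ANCOVA assumes homoscedastic residuals within arms; for strongly
  heteroscedastic flux data use the permutation variant.
- The precipitation clamp cannot describe slow desupersaturation
  kinetics; only the existence and end of a stable window.
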