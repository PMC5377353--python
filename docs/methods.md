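# Methods

## Model

The package computes the equilibrium relative humidity above aqueous
solutions as the water activity. The core expression treats a liquid of
N₁ solvent molecules of specific volume v₁ and N₂ solute units of
specific volume v₂:

    RH = φ₁ · exp[ N₂(v₂ − v₁) / V ],    V = N₁v₁ + N₂v₂,  φ₁ = N₁v₁/V.

The first factor is the ratio of solvent concentrations in the solution
and in pure solvent; the second is a Boltzmann factor for the difference
in work functions for removing a solvent molecule from the two liquids,
which arises from the cohesive-pressure work of swapping molecules of
unequal volume. The temperature cancels between the work difference
(∝ kT through the cohesive pressure) and the Boltzmann exponent, so RH
carries no temperature dependence in this model. Algebraically the
expression equals the Flory–Huggins solvent activity
`ln a₁ = ln φ₁ + (1 − 1/r)φ₂` with `r = v₂/v₁`; the test suite verifies
that equivalence to 10⁻¹² against an independently coded log-activity
form, which guards the algebra of the mass-fraction front-end below.

Assumptions: athermal mixing (no enthalpic interaction term; the
exponential factor is purely geometric), a non-volatile solute, a single
solute species, and incompressible molecular volumes. Electrolyte
non-ideality beyond volume exclusion (ion pairing, activity
coefficients) is outside the model.

### Salt front-end

For a salt of molarity M that dissociates into x independent ions and
pre-empts y litres per mole, one litre of solution retains
`W = (1000/18)(1 − yM)` moles of water next to `xM` moles of ions, and

    RH = W / (W + xM).

Because ions and water molecules are of comparable size, the v₂ ≠ v₁
exponential is not applied to salts; the specific volume enters only
through the excluded volume `yM`. The domain boundary is `yM < 1`
(the salt cannot fill the whole litre); beyond it a `DomainError` is
raised. Water's molar mass is taken as exactly 18 g/mol, fixing pure
water at 1000/18 = 55.56 mol/L; with that convention the initial slope
of RH versus molarity is −x/55.56, so the low-concentration depression
directly reads off the dissociation count.

Non-integer x is accepted (effective dissociation of weak
electrolytes); the fitting module relies on that continuity.

### Polymer front-end

Polymer concentrations arrive as mass fraction w (w/w). With monomer
units of effective mass m occupying one lattice site each,
`r = n/m` for chain mass n, the mole ratio is
`N₂/N₁ = (18/n)·w/(1 − w)` and the site ratio
`f = r·N₂/N₁ = (18/m)·w/(1 − w)` — independent of n. Then

    RH = 1/(1+f) · exp[(1 − 1/r)·f/(1+f)].

Chain length only survives in the 1/r correction, so RH converges to a
chain-independent curve as n grows, at rate 1/n (drift between n = 10⁸
and 10⁹ is ~10⁻⁷ RH at w = 0.5). The default m = 38 g/mol is the value
that best reproduces measured PEG curves; it ships with every built-in
PEG record and is the fallback, with a logged warning, for registry
records that omit it. `n_mw < m_monomer` is rejected rather than
clamped: a "polymer" smaller than its monomer has no meaning in the
lattice picture.

### Limit behaviour and numerical checks

Both reductions to Raoult's law are checked numerically. Equal specific
volumes give agreement to 10⁻¹² across the composition range. The
extreme-dilution reduction holds for any volume ratio r, but the
deviation relative to the depression scales as (N₂/N₁)·r²/2, so the
check picks a dilution deep enough for each r: 10⁻⁶ up to r = 100 and
10⁻⁸ at r = 1000, both against a 10⁻² band. Testing r = 1000 at
dilution 10⁻⁶ would sit outside the asymptotic regime (ratio ≈ 0.5) and
says nothing about the limit.

### Inversion

Both forward models are strictly decreasing, so target-RH inversion has
a unique root. `solve_concentration` brackets it on
[0, domain boundary − 10⁻⁹] — the boundary being `1/y` for salts (a
10⁶ mol/L cap when y = 0) and mass fraction 1 for polymers — and runs
Brent's method at machine-level tolerances, comfortably inside the
10⁻¹⁰ RH contract. Targets below the RH attainable at the boundary
raise a `RangeError` reporting the attainable interval.

## Two-phase Boltzmann demonstrator

`statmech` implements the argument underlying the model as a concrete,
checkable system: a ladder of liquid levels and a ladder of vapour
levels offset by a work function W (energies in kT), evenly spaced with
degeneracy proportional to the phase volume, truncated at
`n_levels_per_phase` with the requirement that the last retained weight
be < 10⁻¹² of the first (violations raise an error naming the needed
depth). Even spacing is a deliberate simplification — the argument only
needs level density proportional to volume — and keeps the per-level
brute-force oracle in the tests trivial to write independently of the
vectorized implementation.

Ideal dilution multiplies the solvent count by (1 − x) while touching
neither ladder, so the vapour count is exactly linear in (1 − x); the
test asserts that identity at machine precision, which is the point of
the demonstrator.

For the volume-split experiment the liquid must be treated as
incompressible: the reference state (all `n_total` units filling
`liquid_volume`) fixes the liquid number density, and for each split of
the fixed container volume the equilibrium liquid content is solved
self-consistently (Brent on the occupancy imbalance, with the liquid's
level degeneracy tracking its *remaining* volume). With volumes treated
instead as fixed external parameters the vapour concentration would
depend on the split, contradicting the physics the demonstrator is
meant to exhibit. The operation requires W > 0; at W = 0 liquid and
vapour are degenerate and the split has no stable equilibrium. Points
where the liquid fully evaporates are flagged `depleted`, not raised.

## Synthetic curves and fitting

Published equilibrium curves for these solutions exist mostly as
figures, so the fitting module is exercised end-to-end on synthetic
data. The generator evaluates the forward model on a concentration grid
and adds homoscedastic Gaussian noise on the RH fraction, clipped to
(0, 1], with an explicit integer seed (numpy `default_rng`; no global
state). The default noise s.d. of 0.003 RH represents the run-to-run
stability of a modern humidity-control device reading an equilibrium
point; real measurements may add drift, temperature sensitivity and
concentration errors that this generator does not emulate, so passing
recovery tests certify the estimator, not field accuracy.

`fit_salt` minimizes squared RH residuals over x ∈ [1, 5], y ∈ [0, 0.5];
`fit_polymer_m` over m ∈ [10, 200] at known chain mass n. Bounds
bracket all physically plausible values; the optimizer is scipy's
bounded trust-region least squares with xtol = ftol = gtol = 10⁻¹⁵, so
zero-noise recovery is limited only by the optimizer contract (10⁻⁶
relative is asserted; observed much tighter). Losses are unweighted —
there are no per-point uncertainties to weight by. Non-convergence is
reported in the result (`converged = False` plus the optimizer
message), never silently. Identifiability: x controls the initial
slope, y the curvature at higher molarity, so a curve spanning
0.25–3 M separates them; pinning x (`fix_x`) demonstrably sharpens the
y estimate at realistic noise.

Problem sizes used throughout the tests and the acceptance script —
12-point salt grids over 0.25–3 M, 10-point PEG grids over 0.05–0.50
w/w, 50-seed bias averages, 1000 retained levels per phase — are the
scale at which every asserted property is already exhibited to its
tolerance.

## Design choices

* RH is a fraction in (0, 1] everywhere inside the library
  (`RHValue`, a float subclass with a `.percent` view); percent appears
  only at the CLI boundary and in file columns named `rh_percent`.
  One convention prevents factor-of-100 bugs.
* `--unit` is mandatory on the CLI and never inferred: misreading
  0.5 M as 0.5 w/w is the costliest mistake the tool could make.
* The registry is JSON with a `schema_version`, case-insensitive
  lookup, a small alias table, and strict validation that names the
  offending record. PEG chain masses come from the product name
  (PEG 6000 → n = 6000); polydispersity is ignored.
* Multi-solute rows are rejected with a clear message: the model covers
  single-solute solutions, and silently combining activities would be
  wrong for interacting solutes.
* The CLI accepts no temperature argument for computation: the model is
  temperature-free by construction.

## Limitations

* No activity-coefficient corrections (Pitzer, Flory–Huggins χ); salts
  are ideal apart from dissociation and excluded volume.
* Constants are supplied for three salts only; other salts need
  user-provided or fitted (x, y).
* The fitting module demonstrates least-squares calibration of m on
  synthetic curves; it cannot claim to reproduce how the historical
  value 38 was originally obtained, since that fit's inputs are not
  published.
* The demonstrator is pedagogy, not prediction: no real level spectra,
  no quantum statistics, no kinetics.
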