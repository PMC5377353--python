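# rhcalc

Equilibrium relative humidity (RH) of salt and polymer solutions used in
macromolecular crystallization.

Humidity-control devices on crystallography beamlines deliver an air
stream of defined RH to a crystal. The first step of every such
experiment is finding the equilibrium point between the air and the
mother liquor: too dry and the drop shrinks, too humid and it grows. At
equilibrium the RH equals the water activity of the solution, so the
equilibrium point can be *predicted* from the solution's composition
instead of titrated by eye. `rhcalc` does that prediction, inverts it
(target RH → concentration), fits model parameters to measured RH
curves, and demonstrates the statistical-mechanics argument the model
rests on.

## The model

For an ideal solution Raoult's law gives the vapour pressure ratio as
the solvent mole fraction: `p/p0 = 1 − x`. When solvent and solute
molecules occupy different volumes (N₁ solvent molecules of specific
volume v₁, N₂ solute of v₂) the activity generalizes to

    RH = φ₁ · exp[ N₂(v₂ − v₁) / (N₁v₁ + N₂v₂) ],   φ₁ = N₁v₁/(N₁v₁ + N₂v₂)

— the solvent volume fraction times an exponential factor from the
difference in work functions for removing a solvent molecule from the
solution versus from pure solvent. This is identical to the
Flory–Huggins solvent activity `ln a₁ = ln φ₁ + (1 − 1/r)φ₂` with
`r = v₂/v₁`, and it reduces to Raoult's law when v₁ = v₂ and at extreme
dilution.

Two working forms cover the practical cases:

* **Salts** (concentration as molarity M): each litre of solution keeps
  `1 − yM` litres of water, i.e. `W = (1000/18)(1 − yM)` moles, and
  carries `xM` moles of free ions, where `x` is the dissociation count
  and `y` (L/mol) the salt's specific-volume factor. Then
  `RH = W/(W + xM)`. Built-in constants: NaCl (x=2, y=0.027), ammonium
  sulfate (2, 0.074), sodium malonate (3, 0.095).
* **Polymers** (concentration as mass fraction w/w): on a lattice where
  a water molecule or a monomer unit of mass `m` occupies one site,
  `r = n/m` for a polymer of molecular weight `n`, the site ratio is
  `f = (18/m)·w/(1 − w)`, and `RH = 1/(1+f) · exp[(1 − 1/r)·f/(1+f)]`.
  For PEGs `m = 38` g/mol describes the measured curves best; RH becomes
  independent of `n` for long chains.

A small two-phase Boltzmann model (`rhcalc.statmech`) demonstrates why
all this works: with liquid and vapour level ladders separated by a work
function W and level densities proportional to phase volumes, the vapour
count is exactly proportional to the solvent fraction `(1 − x)` —
Raoult's law — and the saturated vapour concentration is independent of
how much liquid the container holds.

## Worked example

```
$ python examples/predict_rh.py
Salt solutions (molarity -> RH %):
  sodium chloride     1.0 M   ->  96.43%
  ammonium sulfate    2.0 M   ->  92.21%
  sodium malonate     1.5 M   ->  91.37%

PEG solutions (mass fraction w/w -> RH %):
  PEG 400            0.30 w/w ->  96.84%
  PEG 6000           0.30 w/w ->  98.30%
  PEG 20000          0.30 w/w ->  98.37%
  PEG 6000           0.50 w/w ->  93.39%
```

1 M NaCl equilibrates at 96.43% RH: of the 54.05 mol of water and 2 mol
of ions in a litre, water is a 0.9643 mole fraction. The PEG rows show
the two signatures of the lattice model: at fixed 30% w/w, PEG 6000 and
PEG 20000 differ by only 0.07% RH (chain-length independence), while
PEG 400 sits lower because its shorter chains contribute more
depression per gram.

The same predictions are available from the shell:

```
$ rh predict --solute "sodium chloride" --conc 1.0 --unit M
96.43
$ rh invert --solute "PEG 6000" --target-rh 95.0
0.453977
$ rh predict --table curves.csv        # appends an rh_percent column
```

`rh synth` generates seeded synthetic curves, `rh fit` estimates (x, y)
or m from a curve, and `rh simulate` runs the two-phase demonstrator.
Exit codes: 0 success, 2 domain/range error, 1 unexpected failure.

Other examples: `examples/invert_target_rh.py` (target RH →
concentration), `examples/fit_monomer_mass.py` (parameter recovery from
noisy curves), `examples/raoult_from_statmech.py` (the Boltzmann
demonstrator).

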