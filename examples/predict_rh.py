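"""Predict the equilibrium RH above common crystallization solutions.

Builds the built-in solute registry and evaluates the forward models: the
dissociation-corrected Raoult's law for salts (molarity in, RH out) and
the lattice polymer model for PEGs (mass fraction in, RH out).  The
printed percentages are the air humidity at which a drop of each solution
neither grows nor shrinks.
"""

from rhcalc import builtin_registry, polymer_rh, salt_rh

registry = builtin_registry()

print("Salt solutions (molarity -> RH %):")
for name, molarity in [
    ("sodium chloride", 1.0),
    ("ammonium sulfate", 2.0),
    ("sodium malonate", 1.5),
]:
    params = registry.lookup(name).params
    rh = salt_rh(molarity, params)
    print(f"  {name:18s} {molarity:4.1f} M   -> {rh.percent:6.2f}%")

print("\nPEG solutions (mass fraction w/w -> RH %):")
for name, w in [("PEG 400", 0.30), ("PEG 6000", 0.30),
                ("PEG 20000", 0.30), ("PEG 6000", 0.50)]:
    params = registry.lookup(name).params
    rh = polymer_rh(w, params)
    print(f"  {name:18s} {w:4.2f} w/w -> {rh.percent:6.2f}%")

print(
    "\nHigher concentration means lower equilibrium RH; a salt's initial\n"
    "slope scales with its ion count, and heavier PEGs at equal w/w sit\n"
    "close together because RH loses its dependence on chain length."
)
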