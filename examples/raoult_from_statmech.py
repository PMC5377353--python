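"""Watch Raoult's law emerge from a two-phase Boltzmann model.

A ladder of liquid levels and a ladder of vapour levels offset by a work
function W (in kT) share N solvent units.  Replacing a fraction x of the
solvent by an ideal solute changes neither the levels nor W, so the
vapour count scales exactly as (1 - x) — that proportionality IS
Raoult's law.  The second block shows that the equilibrium vapour
concentration does not care how the container is split between liquid
and vapour, because level densities track their phase volumes.
"""

from dataclasses import replace

from rhcalc import TwoPhaseSystem, vapour_concentration_vs_volume, \
    vapour_count_after_dilution, vapour_fraction

sys = TwoPhaseSystem(n_total=1e6, work_function_W=2.0)
print(f"work function W = {sys.work_function_W} kT, "
      f"vapour fraction = {vapour_fraction(sys):.6f} "
      f"(suppression ~ exp(-W) = {2.718281828**-2:.6f})")

print("\ndilution x -> vapour count / undiluted count:")
undiluted = vapour_count_after_dilution(sys)
for x in (0.0, 0.1, 0.25, 0.5, 0.9):
    count = vapour_count_after_dilution(replace(sys, dilution_x=x))
    print(f"  x = {x:4.2f}: ratio = {count / undiluted:.15f} "
          f"(Raoult predicts {1 - x})")

print("\nliquid fraction of container -> vapour concentration:")
for p in vapour_concentration_vs_volume(sys, [0.2, 0.5, 0.8]):
    print(f"  {p.liquid_fraction:.1f}: {p.vapour_concentration:.6f}"
          + ("  (depleted)" if p.depleted else ""))
print("The concentration column is constant: saturated vapour pressure "
      "does not depend on how much liquid is present.")
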