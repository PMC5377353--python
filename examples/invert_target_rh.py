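"""Find the concentration that equilibrates at a chosen RH.

A humidity-control experiment starts from the equilibrium point between
the air stream and the mother liquor; this inverts the forward model
(Brent root finding on the strictly decreasing RH curve) to answer "what
concentration matches 95% RH?".
"""

from rhcalc import builtin_registry, salt_rh, solve_concentration

registry = builtin_registry()
target = 0.95  # RH fraction, i.e. 95%

for name, unit in [("sodium chloride", "M"), ("PEG 6000", "w/w")]:
    params = registry.lookup(name).params
    conc = solve_concentration(target, params)
    print(f"{name}: {conc:.4f} {unit} equilibrates at {100 * target:.1f}% RH")

# Round trip: pushing the answer back through the forward model
# reproduces the target to solver tolerance.
nacl = registry.lookup("sodium chloride").params
conc = solve_concentration(target, nacl)
print(f"check: salt_rh({conc:.4f} M) = {salt_rh(conc, nacl).percent:.10f}%")
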