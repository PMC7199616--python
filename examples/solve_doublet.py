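"""Solve the double-well tunneling doublet and read off the LDL/HDL transfer times.

Builds the square double well (hard walls at z = ±l, barrier V0 on |z| < d),
solves the symmetric and antisymmetric secular equations for the lowest
sub-barrier pair, and prints the splitting and state-transfer times.
"""

from fracwell import DoubleWellGeometry, EffectiveCoefficients, solve_doublet, transfer_times

geometry = DoubleWellGeometry(l=2.0, d=0.5, V0=10.0)
coeffs = EffectiveCoefficients.from_mu_hbar(mu=1.0, hbar_eff=2.0)

doublet = solve_doublet(geometry, coeffs)
times = transfer_times(doublet)

print(f"geometry: l={geometry.l}, d={geometry.d}, V0={geometry.V0}  (mu=1, hbar_eff=2)")
print(f"E_S (symmetric / LDL-like)      = {doublet.E_S:.6f}")
print(f"E_A (antisymmetric / HDL-like)  = {doublet.E_A:.6f}")
print(f"splitting delta_E = E_A - E_S   = {doublet.delta_E:.6f}")
print(f"tau_S = hbar_eff/E_S            = {times['tau_S']:.6f}")
print(f"tau_A = hbar_eff/E_A            = {times['tau_A']:.6f}")
print(f"E_A/E_S = tau_S/tau_A           = {doublet.ratio:.6f}  (> 1)")
print()
print("The finite barrier splits the unsplit well level into a doublet; the")
print("antisymmetric (HDL-labelled) state carries the higher energy and hence")
print("the shorter state-transfer time: the HDL-to-LDL conversion is faster")
print("than the reverse.")
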