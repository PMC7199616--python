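"""Watch the LDL<->HDL state transfer as a well-to-well population oscillation.

An equal superposition of the doublet starts localized in the right well.
Unitary propagation swaps the well populations after half a period and
returns them after a full period T = 2*pi*hbar_eff/delta_E.
"""

import math

import numpy as np

from fracwell import (
    DoubleWellGeometry,
    EffectiveCoefficients,
    GridField,
    assemble_state,
    population_series,
    propagate,
    solve_doublet,
    tunneling_period,
    uniform_grid,
)

geometry = DoubleWellGeometry(l=2.0, d=0.5, V0=10.0)
coeffs = EffectiveCoefficients.from_mu_hbar(1.0, 2.0)
doublet = solve_doublet(geometry, coeffs)
sym = assemble_state(doublet.E_S, "symmetric", geometry, coeffs.mu)
anti = assemble_state(doublet.E_A, "antisymmetric", geometry, coeffs.mu)

T = tunneling_period(doublet)
z = uniform_grid(geometry.l, 1201)
psi0 = GridField(z=z, values=((sym(z) + anti(z)) / math.sqrt(2)).astype(complex))

series = propagate(psi0, geometry, coeffs, t_final=T, n_steps=4000)
table = population_series(series)

print(f"delta_E = {doublet.delta_E:.6f}   predicted period T = {T:.4f}")
for frac in (0.0, 0.25, 0.5, 0.75, 1.0):
    row = table.iloc[int(frac * (len(table) - 1))]
    print(f"t = {row.t:7.3f} ({frac:4.2f} T):  P_left = {row.P_left:.4f}   "
          f"P_right = {row.P_right:.4f}   norm = {row.norm:.12f}")

print()
print("The population starts in the right well, fully transfers to the left")
print("well at T/2 and returns at T, while the norm stays constant to ~1e-12:")
print("this oscillation is the tunneling state transfer between the two")
print("cholesterol states made visible.")
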