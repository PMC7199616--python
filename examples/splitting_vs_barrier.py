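"""Sweep the barrier height: the doublet collapses as the wells decouple.

As V0 grows the evanescent coupling through the barrier dies off, the
splitting delta_E -> 0, and E_A/E_S -> 1: independent wells share one
degenerate level, so the state transfer shuts down.
"""

from fracwell import DoubleWellGeometry, EffectiveCoefficients, splitting_sweep

coeffs = EffectiveCoefficients.from_mu_hbar(1.0, 2.0)
geometries = [DoubleWellGeometry(l=2.0, d=1.0, V0=v) for v in (5, 10, 50, 200, 1000)]

table = splitting_sweep(geometries, coeffs)
print(table.to_string(index=False, float_format=lambda x: f"{x:.8g}"))
print()
print("delta_E decreases monotonically with V0 and the energy ratio falls")
print("toward 1: a taller barrier suppresses the tunneling coupling between")
print("the wells, lengthening both state-transfer times without bound.")
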