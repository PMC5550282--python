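"""Effective stiffness of the tissue's two-layer elastic surround.

The sensory epithelium pushes on a band of transitional epithelium (modulus
E1) embedded in a softer or stiffer matrix (E2).  The closed-form plane
elasticity solution shows the pair acts like a single band with an effective
modulus E_eff, and the equilibrium expansion of the tissue scales as 1/E_eff
(hence its area change as 1/E_eff^2) - the rationale for controlling organ
size through the stiffness of the surroundings.
"""

import numpy as np

from utrisim.elastic import (
    LayeredAnnulus,
    effective_modulus,
    equilibrium_expansion,
    solve_layers,
    thin_band_modulus,
)

an = LayeredAnnulus(E1=2.0, E2=1.0, R1=1.0, R2=2.0, nu=0.3, p=1.0)
sol = solve_layers(an)
E = effective_modulus(an)
print(f"two-layer system E1={an.E1}, E2={an.E2}, R1={an.R1}, R2={an.R2}, nu={an.nu}")
print(f"  inner displacement u(R1)   = {float(sol.u(an.R1)):.6f}")
print(f"  effective modulus E_eff    = {E:.4f}")

thin = LayeredAnnulus(E1=2.0, E2=1.0, R1=1.0, R2=1.1, nu=0.3)
print(f"thin band (R2 = 1.1 R1): exact E_eff = {effective_modulus(thin):.4f}, "
      f"first-order approximation = {thin_band_modulus(thin):.4f}")

# softening the matrix softens the effective boundary
for e2 in (0.25, 0.5, 1.0, 2.0):
    an2 = LayeredAnnulus(E1=2.0, E2=e2, R1=1.0, R2=2.0, nu=0.3)
    print(f"  E2 = {e2:4.2f} -> E_eff = {effective_modulus(an2):.3f}")

# equilibrium expansion against a homeostatic pressure
PH, R1, nu = 0.5, 1.0, 0.45
for e in (0.5, 1.0, 2.0):
    dR = equilibrium_expansion(PH, R1, nu, e)
    print(f"  E_eff = {e:3.1f}: dR = {dR:.4f} (dR*E constant: {dR * e:.4f})")
print("dR scales as 1/E, so the area change scales as 1/E^2.")
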