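"""Grow a sensory epithelium against an elastic boundary.

Runs the desk-scale elasticity-limited preset and prints the growth
trajectory's milestones.  The tissue expands by cell division until the
stretched elastic boundary balances cellular pressure; the quiescence rule
then freezes the remaining slow stochastic creep, so the final area is an
arrested steady state rather than a lattice artefact.
"""

from utrisim.workbench import reduced_elasticity_config
from utrisim import run_model

config = reduced_elasticity_config(seed=1)
result = run_model(config)
tr = result.trajectory

print(f"lattice {config.height}x{config.width}, boundary modulus E = {config.energy.E}")
for frac in (0.1, 0.25, 0.5, 1.0):
    row = tr.iloc[int(frac * (len(tr) - 1))]
    print(
        f"  t = {row.time_s / 86400:5.1f} d  area = {row.area_px:6.0f} px "
        f"({row.area_m2:.3e} m^2 at dA = 8.6e-13)  cells = {row.n_cells:4.0f}  "
        f"quiescent = {row.n_quiescent:4.0f}"
    )
print(f"divisions: {int(tr.n_divisions.iloc[-1])}; "
      f"final perimeter S = {int(tr.S.iloc[-1])} links")
print("All cells quiescent at the end:", tr.n_quiescent.iloc[-1] == tr.n_cells.iloc[-1])
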