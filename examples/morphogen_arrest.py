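"""Arrest tissue growth with a secreted diffusible inhibitor.

Runs the desk-scale morphogen-limited preset: every cell secretes an
inhibitor from its centre of mass; where the accumulated concentration
crosses the threshold, division stops.  The arrest front starts at the
organ's centre (where the field is highest) and sweeps outward, capping
growth well below what the deliberately soft elastic boundary would allow.
"""

from utrisim import run_model
from utrisim.workbench import reduced_morphogen_config

config = reduced_morphogen_config(seed=5)
result = run_model(config)
tr = result.trajectory

mcs, rnorm = result.first_arrest
print(f"first arrested cell: MCS {mcs}, at {rnorm:.2f} of the tissue radius")
for frac in (0.25, 0.5, 1.0):
    row = tr.iloc[int(frac * (len(tr) - 1))]
    print(
        f"  t = {row.time_s / 86400:5.1f} d  area = {row.area_px:6.0f} px  "
        f"arrested cells = {row.n_arrested:4.0f}/{row.n_cells:4.0f}  "
        f"sites above threshold = {row.arrest_sites:6.0f}"
    )
print(f"final area {result.final_area_px} px; peak field "
      f"{result.field.M.max():.0f} pM vs threshold {config.morphogen.M_TH:.0f} pM")
print("Arrest spreads centre-outward; growth stops when the front reaches the rim.")
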