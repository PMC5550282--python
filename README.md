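# utrisim

**Cellular Potts modelling and analysis of elastic size control in the
utricular sensory epithelium.**

During development the sensory patch (macula) of the utricle — a vestibular
organ of the inner ear — grows rapidly by supporting-cell division and then
stops at a reproducible size. `utrisim` implements and compares the two
candidate stopping mechanisms at the tissue scale:

* **elasticity-limited growth** — the epithelium pushes against an elastic
  surround; growth arrests when the boundary's restoring pressure balances
  the pressure of proliferation, which predicts that the final area scales
  as `1/E²` with the boundary's Young's modulus `E`;
* **morphogen-limited growth** — every cell secretes a diffusible inhibitor;
  cells stop dividing where its concentration exceeds a threshold, so arrest
  sweeps outward from the organ's centre.

It is a library for people studying mechanical feedback in tissue growth:
the simulator is a hexagonal-lattice cellular Potts (Glazier–Graner–Hogeweg)
engine with Metropolis kinetics,

    H = c·J_C·L_cc + c·E·S² + Σ λ_vol (v − V_T)² + Σ λ_surf (s − S_T)²,

where the `c·E·S²` term is the stored elastic energy of a boundary stretched
to tissue perimeter `S`, plus cell division with Gaussian refractory
periods, a quiescence timer that closes residual stochastic growth, EdU
pulse-chase labelling, and a pressure read-out `P = −2λ_vol(v − V_T)`.
Around the simulator sit the analysis tools the problem needs: the
closed-form plane elasticity of a pressurized disk in a two-layer surround
(effective boundary modulus and the `ΔR = P_H·R1(1+ν)/E` equilibrium),
saturating von Bertalanffy growth-curve fitting, piezoelectric-bimorph
rheometry for gel moduli, an EdU boundary-distance image profiler, and
seeded synthetic-data generators with recorded ground truth for every input
class. `docs/methods.md` documents the model, parameters and numerical
choices in detail.

## A worked example

```python
from utrisim import run_model
from utrisim.workbench import reduced_elasticity_config

result = run_model(reduced_elasticity_config(seed=1))
```

`examples/simulate_growth.py` runs exactly this and prints:

```
lattice 150x150, boundary modulus E = 0.12
  t =   1.5 d  area =   1979 px (1.702e-09 m^2 at dA = 8.6e-13)  cells =   94  quiescent =    0
  t =   3.6 d  area =   4939 px (4.248e-09 m^2 at dA = 8.6e-13)  cells =  291  quiescent =    0
  t =   7.3 d  area =   4976 px (4.279e-09 m^2 at dA = 8.6e-13)  cells =  295  quiescent =  166
  t =  14.6 d  area =   4976 px (4.279e-09 m^2 at dA = 8.6e-13)  cells =  295  quiescent =  295
divisions: 280; final perimeter S = 490 links
All cells quiescent at the end: True
```

The tissue grows fast while the boundary is slack, decelerates as the
stretched boundary pushes back (a saturating, von Bertalanffy-shaped
trajectory), and freezes once every cell has failed to divide for the
quiescence time — the arrested area, times the spatial scale `dA`, is the
model's prediction for the organ's final size. Each `examples/*.py` script
demonstrates one capability the same way: `morphogen_arrest.py` (the
inhibitor front starts at 9% of the tissue radius and sweeps outward),
`elastic_theory.py` (the two-layer surround acts like one band with
`E_eff = 1.72` on the worked parameters, and `ΔR·E` is constant so area
changes scale as `1/E²`), `growth_curve_fit.py` (recovers
`A∞ = 1.85·10⁻⁷ m²`, `r = 3.4·10⁻⁶ s⁻¹`, `R² = 0.99` from a noisy 8-stage
series), `rheometry.py` (638.8 Pa fitted for a 640 Pa gel at 2% noise), and
`edu_profile.py` (a proliferation ring placed 15 px inside the boundary is
profiled at −16.5 px).

A thin CLI mirrors the library for shell use:

```bash
utrisim simulate --model elasticity --preset reduced --seed 1 --out out/
utrisim experiment --name modulus-sweep --seed 0 --out out/
utrisim theory effective-modulus --e1 2 --e2 1 --r1 1 --r2 2 --nu 0.3
utrisim fit vonbert growth_curve.csv
```

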