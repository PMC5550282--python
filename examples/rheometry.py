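"""Measure a gel's Young's modulus with a simulated piezoelectric bimorph.

A cantilever presses a collagen-like gel in successive probes; each probe's
voltage change converts to force (F = K_F*W/L * dV), the bimorph's own yield
(X = F/K_B) is subtracted from the base displacement to get the gel's
compression, and the modulus is the slope of stress against strain.
"""

import numpy as np

from utrisim.fitting import extract_voltage_steps, fit_modulus, stress_strain
from utrisim.synth import gen_voltage_trace

for E_true in (640.0, 40.0):  # stiff vs soft gel regimes
    trace, truth = gen_voltage_trace(E=E_true, noise=0.02, seed=7)
    dv = extract_voltage_steps(trace, truth["n_steps"])
    series = stress_strain(
        dv,
        truth["step"] * np.arange(1, truth["n_steps"] + 1),
        truth["A0"],
        truth["L0"],
    )
    E_fit, sigma0, r2 = fit_modulus(series)
    print(
        f"gel with true E = {E_true:5.0f} Pa: fitted E = {E_fit:7.1f} Pa, "
        f"sigma0 = {sigma0:+.3f} Pa, R^2 = {r2:.4f} "
        f"({int(series.valid.sum())}/{truth['n_steps']} probes used)"
    )
print("Stress-strain linearity (R^2 > 0.98) marks a well-behaved measurement.")
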