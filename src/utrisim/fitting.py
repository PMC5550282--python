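"""Growth-curve fitting, linear scaling fits, and bimorph rheometry.

Three analysis blocks:

* **von Bertalanffy growth** — macular area follows ``dA/dt = r*(A_inf - A)``
  whose saturating solution ``A(t) = A_inf*(1 - exp(-r*(t - t0)))`` is fit to
  (time, area) measurements by nonlinear least squares.
* **linear scaling fits** — ordinary least squares used for the final-area
  versus ``1/E**2`` and versus ``D`` relations and for gel calibration.
* **bimorph rheometry** — a piezoelectric bimorph cantilever presses a gel;
  each probe's voltage change converts to force, stress, and strain, and the
  gel's Young's modulus is the slope of the stress-strain relation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

SECONDS_PER_DAY = 86_400.0
#: embryonic day of birth used for the P-stage to time conversion
BIRTH_EDAY = 19.5


def stage_to_seconds(stage: str) -> float:
    """Developmental stage label -> seconds from conception.

    ``"E15.5"`` is embryonic day 15.5; ``"P2"`` is postnatal day 2, counted
    from birth at E19.5.
    """
    stage = stage.strip().upper()
    if stage.startswith("E"):
        day = float(stage[1:])
    elif stage.startswith("P"):
        day = BIRTH_EDAY + float(stage[1:])
    else:
        raise ValueError(f"unrecognized stage label {stage!r}")
    return day * SECONDS_PER_DAY


# ---------------------------------------------------------------------------
# von Bertalanffy growth
# ---------------------------------------------------------------------------


def vb_area(t, A_inf: float, r: float, t0: float = 0.0):
    """Saturating von Bertalanffy area ``A_inf*(1 - exp(-r*(t - t0)))``.

    This is the solution of ``dA/dt = r*(A_inf - A)`` with ``A(t0) = 0``.
    """
    if r <= 0:
        raise ValueError("rate constant r must be positive")
    t = np.asarray(t, dtype=float)
    return A_inf * (1.0 - np.exp(-r * (t - t0)))


@dataclass
class VBFit:
    A_inf: float
    r: float
    t0: float
    r_squared: float
    se: tuple[float, float, float] = (np.nan, np.nan, np.nan)
    cov: np.ndarray | None = None

    def __call__(self, t):
        return vb_area(t, self.A_inf, self.r, self.t0)


def _r_squared(y, yhat) -> float:
    y = np.asarray(y, float)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")


def fit_vb(t, A, sem=None) -> VBFit:
    """Fit the saturating von Bertalanffy curve by (weighted) least squares.

    Starting values: ``A_inf = 1.05*max(A)``; ``r`` and ``t0`` from the
    log-linearization ``log(1 - A/A_inf) = -r*(t - t0)``; a small multistart
    over rate scalings guards against shallow starts.
    """
    t = np.asarray(t, dtype=float)
    A = np.asarray(A, dtype=float)
    if t.size < 4:
        raise ValueError("need at least 4 points to fit 3 parameters")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    # fit in normalized coordinates for conditioning (t spans ~1e6 s, A ~1e-7)
    t_ref, t_span = t[0], t[-1] - t[0]
    a_ref = float(A.max())
    tn = (t - t_ref) / t_span
    an = A / a_ref
    a0 = 1.05
    frac = np.clip(1.0 - an / a0, 1e-12, None)
    slope, intercept = np.polyfit(tn, np.log(frac), 1)
    r0 = max(-slope, 1e-3)
    t00 = float(np.clip(intercept / r0, -10.0, tn[0]))

    def model(tt, a_inf, r, t0):
        return a_inf * (1.0 - np.exp(-r * (tt - t0)))

    sigma = np.asarray(sem, float) / a_ref if sem is not None else None
    best = None
    errors = []
    for scale in (1.0, 0.3, 3.0, 10.0):
        p0 = (a0, r0 * scale, t00)
        try:
            popt, pcov = curve_fit(
                model, tn, an, p0=p0, sigma=sigma, maxfev=20_000,
                bounds=([0, 1e-12, -np.inf], [np.inf, np.inf, tn[-1]]),
            )
        except RuntimeError as exc:  # pragma: no cover - depends on data
            errors.append(str(exc))
            continue
        ss = float(np.sum((an - model(tn, *popt)) ** 2))
        if best is None or ss < best[0]:
            best = (ss, popt, pcov)
    if best is None:
        raise RuntimeError(
            "von Bertalanffy fit failed to converge from all starts: "
            + "; ".join(errors)
        )
    _, popt, pcov = best
    # map back to physical units
    scale_vec = np.array([a_ref, 1.0 / t_span, t_span])
    popt_phys = np.array([popt[0] * a_ref, popt[1] / t_span,
                          t_ref + popt[2] * t_span])
    pcov_phys = pcov * np.outer(scale_vec, scale_vec)
    se = tuple(np.sqrt(np.diag(pcov_phys)))
    yhat = vb_area(t, *popt_phys)
    return VBFit(
        A_inf=float(popt_phys[0]), r=float(popt_phys[1]),
        t0=float(popt_phys[2]), r_squared=_r_squared(A, yhat), se=se,
        cov=pcov_phys,
    )


# ---------------------------------------------------------------------------
# linear fits
# ---------------------------------------------------------------------------


def linear_fit(x, y) -> tuple[float, float, float]:
    """Ordinary least squares ``y = slope*x + intercept``; returns R² too."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept), _r_squared(y, slope * x + intercept)


# ---------------------------------------------------------------------------
# bimorph rheometry
# ---------------------------------------------------------------------------


@dataclass
class BimorphConstants:
    """Calibration constants of the piezoelectric bimorph cantilever (SI)."""

    K_F: float = 2.62e-3  # sensitivity, N per volt
    W: float = 6.5e-3     # width, m
    L: float = 22e-3      # length, m
    K_B: float = 645.0    # stiffness, N/m

    @property
    def force_per_volt(self) -> float:
        return self.K_F * self.W / self.L


def extract_voltage_steps(
    trace,
    n_steps: int,
    sample_dt: float = 500e-6,
    onset0: float = 1.0,
    period: float = 3.0,
    duration: float = 1.0,
    baseline: float = 0.5,
    smooth: float = 0.05,
) -> np.ndarray:
    """Per-probe voltage changes from a sampled bimorph trace.

    For each scheduled probe, ``dV = max(window after onset) - mean(baseline
    window before onset)``.  Probes start at ``onset0`` and repeat every
    ``period`` seconds (1 s contact, 2 s separation by default).  The trace
    is moving-average filtered over ``smooth`` seconds before peak-picking so
    the max statistic is not dominated by sampling noise.
    """
    trace = np.asarray(trace, dtype=float)
    n_sm = max(1, int(round(smooth / sample_dt)))
    if n_sm > 1:
        kernel = np.ones(n_sm) / n_sm
        trace = np.convolve(trace, kernel, mode="same")
    dv = np.empty(n_steps)
    for i in range(n_steps):
        onset = onset0 + i * period
        i_on = int(round(onset / sample_dt))
        # the baseline window ends a smoothing-width before onset so the
        # smeared rising edge cannot leak into the baseline mean
        i_base_end = i_on - n_sm
        i_base = int(round((onset - baseline) / sample_dt)) - n_sm
        i_end = int(round((onset + duration) / sample_dt))
        if i_end > trace.size or i_base < 0:
            raise ValueError(
                f"trace too short for {n_steps} probes (probe {i} ends at "
                f"sample {i_end}, trace has {trace.size})"
            )
        dv[i] = trace[i_on:i_end].max() - trace[i_base:i_base_end].mean()
    return dv


@dataclass
class StressStrain:
    strain: np.ndarray
    stress: np.ndarray
    force: np.ndarray
    tip_displacement: np.ndarray
    valid: np.ndarray  # False where the gel would have negative compression


def stress_strain(
    dV,
    base_steps,
    A0: float,
    L0: float,
    constants: BimorphConstants | None = None,
) -> StressStrain:
    """Convert voltage changes to a stress-strain series.

    ``base_steps`` is the cumulative base displacement of the manipulator at
    each probe (m).  Force ``F_B = (K_F*W/L)*dV``; stress ``F_B/A0``; the
    bimorph tip yields by ``X_B = F_B/K_B`` so the gel compresses by
    ``dL = base - X_B`` and the strain is ``dL/L0``.  Probes with negative
    computed compression are flagged invalid and excluded from fits.
    """
    if A0 <= 0 or L0 <= 0:
        raise ValueError("gel geometry must be positive")
    consts = constants or BimorphConstants()
    dV = np.asarray(dV, dtype=float)
    base = np.asarray(base_steps, dtype=float)
    if dV.shape != base.shape:
        raise ValueError("dV and base_steps must align")
    F = consts.force_per_volt * dV
    X_B = F / consts.K_B
    dL = base - X_B
    strain = dL / L0
    stress = F / A0
    return StressStrain(
        strain=strain, stress=stress, force=F, tip_displacement=X_B,
        valid=dL >= 0,
    )


def fit_modulus(series: StressStrain) -> tuple[float, float, float]:
    """Young's modulus from ``stress = E*strain + sigma0``; returns (E, sigma0, R²)."""
    eps = series.strain[series.valid]
    sig = series.stress[series.valid]
    if eps.size < 3:
        raise ValueError("need at least 3 valid stress-strain points")
    E, sigma0, r2 = linear_fit(eps, sig)
    return E, sigma0, r2
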