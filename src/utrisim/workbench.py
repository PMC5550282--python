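"""Experiment orchestration: presets, sweeps, configuration files, provenance.

Two scales ship with the package:

* **full** — the published simulation conditions (600x600 hexagonal lattice,
  the published parameter set, ~8400 MCS spanning E15.5 to P14 at
  210 s per MCS).  Hours of compute; documented for completeness.
* **reduced** — desk-scale presets (150x150 and 250x250 lattices) with the
  boundary modulus rescaled so the arrested tissue fits the smaller domain.
  All scaling *relations* (area against 1/E**2 and against D, realization
  variability, spatial proliferation patterns) are preserved; only the
  absolute pixel counts shrink.  These presets drive the test-suite and the
  reproduction script.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, replace

import numpy as np
import pandas as pd
import yaml

from .dynamics import DivisionParams, ModelConfig, RunResult, run_model
from .fitting import linear_fit
from .lattice import EnergyParams
from .morphogen import MorphogenParams

#: published morphogen diffusion coefficient, m^2/s
D_PUBLISHED = 1.19e-14


def full_config(model: str = "elasticity", **overrides) -> ModelConfig:
    """Published full-scale conditions (hours of compute)."""
    E = 0.069 if model != "morphogen" else 0.055
    cfg = ModelConfig(
        model=model,
        energy=EnergyParams(E=E),
        height=600,
        width=600,
        initial_cell_count=20,
        total_mcs=8400,  # E15.5 -> P14 at 210 s per MCS
    )
    return replace(cfg, **overrides)


def reduced_elasticity_config(**overrides) -> ModelConfig:
    """Desk-scale elasticity-limited preset used for modulus sweeps."""
    cfg = ModelConfig(
        model="elasticity",
        energy=EnergyParams(E=0.12),
        height=150,
        width=150,
        initial_cell_count=15,
        total_mcs=6000,
        record_every=50,
    )
    return replace(cfg, **overrides)


#: calibrated pixel target of the reduced calibrated preset (the package's
#: own analogue of fitting E so the arrested size matches the measured organ)
CALIBRATED_TARGET_PX = 28_000


def reduced_calibrated_config(**overrides) -> ModelConfig:
    """Larger desk-scale preset for realization-variability statistics.

    The boundary modulus is calibrated — in the same spirit as fitting E so
    that simulated growth ceases at the measured organ size — so the arrested
    area is ~:data:`CALIBRATED_TARGET_PX` pixels.
    """
    cfg = ModelConfig(
        model="elasticity",
        energy=EnergyParams(E=0.055),
        height=250,
        width=250,
        initial_cell_count=20,
        total_mcs=9000,
        record_every=100,
    )
    return replace(cfg, **overrides)


def reduced_morphogen_config(**overrides) -> ModelConfig:
    """Desk-scale morphogen-limited preset (soft boundary, arrest by field).

    The secretion rate and diffusion coefficient keep their published SI
    values; the arrest threshold is recalibrated for the reduced domain (the
    field accumulates in proportion to total secretion, so the threshold
    scales with tissue size and simulated span).
    """
    cfg = ModelConfig(
        model="morphogen",
        energy=EnergyParams(E=0.05),
        morphogen=MorphogenParams(D=D_PUBLISHED, kM=0.23, M_TH=300.0),
        height=150,
        width=150,
        initial_cell_count=15,
        total_mcs=6000,
        record_every=50,
    )
    return replace(cfg, **overrides)


#: default sweep grids (6 values) for the scaling experiments
DEFAULT_E_VALUES = tuple(np.geomspace(0.09, 0.18, 6).round(4))
DEFAULT_D_VALUES = tuple((np.linspace(0.7, 1.5, 6) * D_PUBLISHED).tolist())


def _sem(values: np.ndarray) -> float | None:
    if values.size < 2:
        return None
    return float(values.std(ddof=1) / np.sqrt(values.size))


def run_realizations(base: ModelConfig, seeds) -> tuple[list[RunResult], list[str]]:
    """Run one configuration across seeds; failures are recorded, not fatal.

    Raises if fewer than 3 realizations succeed (or fewer than all when
    fewer than 3 were requested).
    """
    results, failures = [], []
    for s in seeds:
        try:
            results.append(run_model(replace(base, seed=int(s))))
        except RuntimeError as exc:
            failures.append(f"seed {s}: {exc}")
    need = min(3, len(list(seeds)))
    if len(results) < need:
        raise RuntimeError(
            "too few successful realizations: " + "; ".join(failures)
        )
    return results, failures


def elasticity_sweep(
    E_values=DEFAULT_E_VALUES,
    n_seeds: int = 3,
    base: ModelConfig | None = None,
    seed: int = 0,
) -> dict:
    """Final area versus boundary modulus; linear fit of mean area on 1/E**2."""
    base = base or reduced_elasticity_config()
    rows = []
    for i, E in enumerate(E_values):
        cfg = replace(base, energy=replace(base.energy, E=float(E)))
        seeds = [seed + 1000 * i + j for j in range(n_seeds)]
        results, failures = run_realizations(cfg, seeds)
        finals = np.array([r.final_area_px for r in results], dtype=float)
        rows.append(
            {
                "E": float(E),
                "inv_E2": float(E) ** -2,
                "mean_area_px": finals.mean(),
                "sem_area_px": _sem(finals),
                "n_ok": len(results),
                "n_failed": len(failures),
            }
        )
    table = pd.DataFrame(rows)
    slope, intercept, r2 = linear_fit(table["inv_E2"], table["mean_area_px"])
    return {
        "table": table,
        "fit": {"slope": slope, "intercept": intercept, "r_squared": r2},
        "x": "inv_E2",
    }


def morphogen_sweep(
    D_values=DEFAULT_D_VALUES,
    n_seeds: int = 3,
    base: ModelConfig | None = None,
    seed: int = 0,
) -> dict:
    """Final area versus morphogen diffusion coefficient; linear fit on D."""
    base = base or reduced_morphogen_config()
    rows = []
    for i, D in enumerate(D_values):
        cfg = replace(base, morphogen=replace(base.morphogen, D=float(D)))
        seeds = [seed + 1000 * i + j for j in range(n_seeds)]
        results, failures = run_realizations(cfg, seeds)
        finals = np.array([r.final_area_px for r in results], dtype=float)
        rows.append(
            {
                "D": float(D),
                "mean_area_px": finals.mean(),
                "sem_area_px": _sem(finals),
                "n_ok": len(results),
                "n_failed": len(failures),
            }
        )
    table = pd.DataFrame(rows)
    slope, intercept, r2 = linear_fit(table["D"], table["mean_area_px"])
    return {
        "table": table,
        "fit": {"slope": slope, "intercept": intercept, "r_squared": r2},
        "x": "D",
    }


def realization_variability(
    base: ModelConfig | None = None,
    n_realizations: int = 5,
    seed: int = 0,
) -> dict:
    """Final-area statistics across independent realizations.

    Reports the relative standard error of the mean in percent,
    ``100 * (SD/sqrt(n)) / mean``, the headline realization-variability
    statistic.
    """
    base = base or reduced_calibrated_config()
    results, failures = run_realizations(base, range(seed, seed + n_realizations))
    finals = np.array([r.final_area_px for r in results], dtype=float)
    sem = _sem(finals)
    return {
        "finals_px": finals,
        "finals_m2": finals * base.dA,
        "mean_px": float(finals.mean()),
        "sem_px": sem,
        "rel_sem_pct": 100.0 * sem / finals.mean() if sem is not None else None,
        "n_ok": len(results),
        "failures": failures,
        "results": results,
    }


# ---------------------------------------------------------------------------
# configuration files and provenance
# ---------------------------------------------------------------------------

_BLOCKS = {
    "energy": EnergyParams,
    "division": DivisionParams,
    "morphogen": MorphogenParams,
}
_SCALARS = {
    f.name for f in dataclasses.fields(ModelConfig)
    if f.name not in _BLOCKS
}


def config_from_dict(data: dict | None) -> ModelConfig:
    """Build a :class:`ModelConfig` from nested dicts.

    Missing keys take the published defaults; unknown keys are rejected with
    a message listing them.
    """
    data = dict(data or {})
    kwargs = {}
    for block, cls in _BLOCKS.items():
        sub = data.pop(block, None)
        if sub is not None:
            valid = {f.name for f in dataclasses.fields(cls)}
            bad = set(sub) - valid
            if bad:
                raise ValueError(f"unknown keys in '{block}': {sorted(bad)}")
            kwargs[block] = cls(**sub)
    bad = set(data) - _SCALARS
    if bad:
        raise ValueError(f"unknown configuration keys: {sorted(bad)}")
    kwargs.update(data)
    return ModelConfig(**kwargs)


def load_config(path) -> ModelConfig:
    """Read a YAML model configuration (empty file = published defaults)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data)


def config_to_dict(cfg: ModelConfig) -> dict:
    return asdict(cfg)


def provenance(cfg: ModelConfig, seeds) -> dict:
    from . import __version__

    blob = json.dumps(config_to_dict(cfg), sort_keys=True, default=float)
    return {
        "config": config_to_dict(cfg),
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seeds": [int(s) for s in seeds],
        "version": __version__,
    }


def write_trajectory_csv(result: RunResult, path) -> None:
    result.trajectory.to_csv(path, index=False, float_format="%.10g")


def write_report_json(report: dict, path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="records")
        raise TypeError(type(o))

    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=default)
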