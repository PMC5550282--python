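"""Shared fixtures: small oracle lattices and session-scoped simulations.

The expensive growth simulations are session-scoped so several tests can
interrogate the same trajectories (growth shape, quiescence closure,
division geography, EdU maps, arrest fronts).
"""

from __future__ import annotations

import numpy as np
import pytest

from utrisim import EnergyParams, Lattice, ModelConfig, run_model
from utrisim.morphogen import MorphogenParams
from utrisim.workbench import (
    reduced_calibrated_config,
    reduced_morphogen_config,
    run_realizations,
)


def make_speckle_lattice(
    height=40, width=40, n_ids=6, box=20, seed=0, params=None
) -> Lattice:
    """Random multi-cell lattice (fragmented, with 1-pixel cells) for
    energy-bookkeeping oracles."""
    rng = np.random.default_rng(seed)
    owner = np.zeros((height, width), dtype=np.int64)
    r0 = (height - box) // 2
    c0 = (width - box) // 2
    owner[r0 : r0 + box, c0 : c0 + box] = rng.integers(
        0, n_ids, size=(box, box)
    )
    return Lattice(owner, params or EnergyParams())


@pytest.fixture(scope="session")
def speckle():
    return make_speckle_lattice()


@pytest.fixture(scope="session")
def elasticity_run():
    """Reduced-scale elasticity-limited growth run with an EdU pulse."""
    cfg = ModelConfig(
        model="elasticity",
        energy=EnergyParams(E=0.12),
        height=150,
        width=150,
        initial_cell_count=15,
        total_mcs=6000,
        edu_on_mcs=1000,
        edu_off_mcs=1206,  # ~12 h pulse at 210 s per MCS, during active growth
        seed=42,
        record_every=25,
    )
    return run_model(cfg)


@pytest.fixture(scope="session")
def growing_run():
    """Short elasticity-limited run stopped while still growing."""
    cfg = ModelConfig(
        model="elasticity",
        energy=EnergyParams(E=0.12),
        height=150,
        width=150,
        initial_cell_count=15,
        total_mcs=1500,
        seed=43,
        record_every=25,
    )
    return run_model(cfg)


@pytest.fixture(scope="session")
def morphogen_run():
    """Reduced-scale morphogen-limited run (records the arrest front)."""
    return run_model(reduced_morphogen_config(seed=5))


@pytest.fixture(scope="session")
def calibrated_runs():
    """Five realizations of the calibrated elasticity-limited preset."""
    results, failures = run_realizations(
        reduced_calibrated_config(), seeds=range(1, 6)
    )
    assert not failures, failures
    return results
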