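"""Tissue growth dynamics: division, refractory and quiescence rules,
EdU pulse-chase labelling, pressure read-out, and the model orchestrations.

Three model variants share the Potts engine:

* ``elasticity`` — growth arrests when the elastic boundary's restoring
  pressure balances cell growth; the quiescence rule (``Tdiv``) then closes
  the residual stochastic growth.
* ``morphogen`` — a soft boundary plus a secreted inhibitor field; cells stop
  dividing where the concentration exceeds the threshold.
* ``stemcell`` — only a central patch of stem cells divides; daughters
  differentiate into supporting cells with a configured probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernels, hexgrid
from .lattice import EnergyParams, Lattice
from .morphogen import MorphogenField, MorphogenParams, cm_sites
from .synth import gen_initial_tissue

#: EdU detectability threshold: undetectable below (1/2)**4
EDU_DETECTION = 0.5**4

TYPE_SC = 1
TYPE_STEM = 2


@dataclass
class DivisionParams:
    """Division, refractory and quiescence parameters (MCS units)."""

    Tref_mean: float = 200.0
    sigma_ref: float = 50.0
    Tdiv: float = 2000.0
    enable_quiescence: bool = True

    def __post_init__(self):
        if self.Tref_mean <= 0 or self.sigma_ref < 0:
            raise ValueError("Tref_mean must be positive and sigma_ref >= 0")
        if self.Tdiv <= self.Tref_mean:
            raise ValueError("Tdiv must exceed the mean refractory time")


@dataclass
class ModelConfig:
    """Full configuration of one simulation run."""

    model: str = "elasticity"  # elasticity | morphogen | stemcell
    energy: EnergyParams = field(default_factory=EnergyParams)
    division: DivisionParams = field(default_factory=DivisionParams)
    morphogen: MorphogenParams = field(default_factory=MorphogenParams)
    height: int = 600
    width: int = 600
    initial_cell_count: int = 20
    total_mcs: int = 8000
    dt: float = 210.0       # seconds per MCS
    dA: float = 8.6e-13     # m^2 per pixel
    edu_on_mcs: int | None = None
    edu_off_mcs: int | None = None
    stem_fraction: float = 0.1
    stem_retention: float = 0.5
    seed: int = 0
    record_every: int = 1

    def __post_init__(self):
        if self.model not in ("elasticity", "morphogen", "stemcell"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.dt <= 0 or self.dA <= 0:
            raise ValueError("dt and dA must be positive")
        if (self.edu_on_mcs is None) != (self.edu_off_mcs is None):
            raise ValueError("set both or neither of edu_on_mcs/edu_off_mcs")
        if self.edu_on_mcs is not None and not (
            0 <= self.edu_on_mcs < self.edu_off_mcs <= self.total_mcs
        ):
            raise ValueError("need edu_on_mcs < edu_off_mcs <= total_mcs")


class CellState:
    """Per-cell dynamic state, aligned with the lattice's cell-id arrays."""

    def __init__(self, capacity: int):
        self.mcs_since_division = np.zeros(capacity, dtype=np.int64)
        self.refractory_draw = np.zeros(capacity, dtype=np.float64)
        self.quiescent = np.zeros(capacity, dtype=bool)
        self.arrested = np.zeros(capacity, dtype=bool)
        self.edu = np.zeros(capacity, dtype=np.float64)
        self.divisions_since_label = np.zeros(capacity, dtype=np.int64)

    def ensure_capacity(self, max_id: int) -> None:
        cap = len(self.mcs_since_division)
        if max_id < cap:
            return
        new_cap = max(2 * (max_id + 1), 2 * cap)
        for name, arr in vars(self).items():
            new = np.zeros(new_cap, dtype=arr.dtype)
            new[: len(arr)] = arr
            setattr(self, name, new)


def draw_refractory(params: DivisionParams, rng: np.random.Generator) -> float:
    """Gaussian refractory draw, truncated at zero by redrawing."""
    if params.sigma_ref == 0:
        return params.Tref_mean
    while True:
        x = rng.normal(params.Tref_mean, params.sigma_ref)
        if x >= 0:
            return float(x)


def attempt_division(
    volume: int,
    state: CellState,
    cid: int,
    division: DivisionParams,
    VT: int,
    is_stem_model: bool = False,
    cell_type: int = TYPE_SC,
) -> bool:
    """Division eligibility: refractory elapsed, volume >= VT/2, not
    quiescent, not morphogen-arrested (and stem type in the stem model)."""
    if state.quiescent[cid] or state.arrested[cid]:
        return False
    if is_stem_model and cell_type != TYPE_STEM:
        return False
    if state.mcs_since_division[cid] <= state.refractory_draw[cid]:
        return False
    return volume >= VT / 2


def update_quiescence(state: CellState, division: DivisionParams, ids: np.ndarray) -> None:
    """Render cells quiescent (permanently) once they have failed to divide
    for more than ``Tdiv`` Monte Carlo steps."""
    if not division.enable_quiescence:
        return
    late = state.mcs_since_division[ids] > division.Tdiv
    state.quiescent[ids[late]] = True


def cell_pressure(volume, params: EnergyParams):
    """Internal cellular pressure ``P = -2*lambda_vol*(v - VT)``."""
    return -2.0 * params.lambda_vol * (np.asarray(volume) - params.VT)


def edu_update(state: CellState, parent: int, daughters, labeling_active: bool) -> None:
    """Apply the EdU labelling rule at a division event.

    During the labelling window both daughters are set to ``[EdU] = 1``;
    afterwards each daughter inherits half the parent's level.  A level is
    detectable while ``[EdU] >= (1/2)**4``.
    """
    if labeling_active:
        for d in daughters:
            state.edu[d] = 1.0
            state.divisions_since_label[d] = 0
    else:
        level = state.edu[parent] / 2.0
        gen = state.divisions_since_label[parent] + 1
        for d in daughters:
            state.edu[d] = level
            state.divisions_since_label[d] = gen


def edu_detectable(level) -> np.ndarray:
    return np.asarray(level) >= EDU_DETECTION


def split_cell(lattice: Lattice, cid: int, rng: np.random.Generator):
    """Split a cell through its centre of mass, perpendicular to its longest
    axis; returns ``(cid, new_id)``.

    Pixels are ranked by their projection on the principal axis and the
    upper half (ties broken by rank) becomes the new cell, so daughter
    volumes differ by at most one pixel.
    """
    rows, cols = lattice.cell_pixels(cid)
    n = rows.size
    if n < 2:
        raise ValueError(f"cell {cid} has fewer than 2 pixels; cannot divide")
    x, y = hexgrid.to_cartesian(rows, cols)
    xc, yc = x.mean(), y.mean()
    dx, dy = x - xc, y - yc
    cov = np.array([[dx @ dx, dx @ dy], [dx @ dy, dy @ dy]]) / n
    w, v = np.linalg.eigh(cov)
    axis = v[:, int(np.argmax(w))]
    proj = dx * axis[0] + dy * axis[1]
    order = np.argsort(proj, kind="stable")
    take = order[n // 2:]  # upper half -> new id
    new_id = lattice._max_id + 1
    lattice.ensure_capacity(new_id)
    lattice.owner[rows[take], cols[take]] = new_id
    # bookkeeping: volumes, CM sums, then local surface recounts
    xb, yb = x[take], y[take]
    lattice.volumes[new_id] = take.size
    lattice.volumes[cid] = n - take.size
    lattice.sumx[new_id] = xb.sum()
    lattice.sumy[new_id] = yb.sum()
    lattice.sumx[cid] -= xb.sum()
    lattice.sumy[cid] -= yb.sum()
    keep = order[: n // 2]
    lattice.surfaces[cid] = _kernels.surface_of_pixels(
        lattice.owner, rows[keep], cols[keep], cid
    )
    lattice.surfaces[new_id] = _kernels.surface_of_pixels(
        lattice.owner, rows[take], cols[take], new_id
    )
    return cid, new_id


@dataclass
class RunResult:
    """Output of :func:`run_model`."""

    trajectory: pd.DataFrame
    divisions: pd.DataFrame
    lattice: Lattice
    state: CellState
    config: ModelConfig
    field: MorphogenField | None = None
    #: (mcs, normalized radius) of the first morphogen-arrested cell(s)
    first_arrest: tuple[int, float] | None = None

    @property
    def final_area_px(self) -> int:
        return int(self.trajectory["area_px"].iloc[-1])

    @property
    def final_area_m2(self) -> float:
        return float(self.trajectory["area_m2"].iloc[-1])

    def edu_map(self) -> np.ndarray:
        """Per-pixel EdU level of the owning cell (0 in the medium)."""
        levels = np.zeros(len(self.state.edu))
        ids = self.lattice.cell_ids()
        levels[ids] = self.state.edu[ids]
        return levels[self.lattice.owner]

    def pressure_map(self) -> np.ndarray:
        """Per-pixel pressure of the owning cell (0 in the medium)."""
        p = np.zeros(len(self.lattice.volumes))
        ids = self.lattice.cell_ids()
        p[ids] = cell_pressure(self.lattice.volumes[ids], self.config.energy)
        return p[self.lattice.owner]


def tissue_centroid(lattice: Lattice) -> tuple[float, float]:
    ids = lattice.cell_ids()
    v = lattice.volumes[ids].sum()
    return lattice.sumx[ids].sum() / v, lattice.sumy[ids].sum() / v


def radial_positions(lattice: Lattice, ids: np.ndarray) -> np.ndarray:
    """Distance of each cell's CM from the tissue centroid, normalized by the
    equivalent tissue radius ``sqrt(area_cartesian/pi)``."""
    cx, cy = tissue_centroid(lattice)
    v = lattice.volumes[ids]
    x = lattice.sumx[ids] / v
    y = lattice.sumy[ids] / v
    area = lattice.tissue_area * hexgrid.SITE_AREA
    radius = np.sqrt(area / np.pi)
    return np.hypot(x - cx, y - cy) / radius


def run_model(config: ModelConfig) -> RunResult:
    """Evolve a tissue under the configured model; returns the trajectory,
    the division log, and the final lattice/state."""
    rng = np.random.default_rng(config.seed)
    _kernels.seed_rng(int(rng.integers(0, 2**31 - 1)))
    p = config.energy
    owner = gen_initial_tissue(
        config.initial_cell_count, config.height, config.width, p.VT,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    lattice = Lattice(owner, p)
    state = CellState(len(lattice.volumes))
    ids0 = lattice.cell_ids()
    for cid in ids0:
        state.refractory_draw[cid] = draw_refractory(config.division, rng)

    if config.model == "stemcell":
        rnorm = radial_positions(lattice, ids0)
        n_stem = max(1, int(round(config.stem_fraction * ids0.size)))
        stem_ids = ids0[np.argsort(rnorm, kind="stable")[:n_stem]]
        lattice.cell_type[ids0] = TYPE_SC
        lattice.cell_type[stem_ids] = TYPE_STEM

    field_ = None
    if config.model == "morphogen":
        field_ = MorphogenField(
            config.height, config.width, config.morphogen, config.dt, config.dA
        )

    rows_traj: list[tuple] = []
    rows_div: list[tuple] = []
    n_divisions = 0
    vt_half = p.VT / 2.0
    first_arrest = None

    for mcs in range(1, config.total_mcs + 1):
        lattice.monte_carlo_step()
        ids = lattice.cell_ids()
        state.ensure_capacity(lattice._max_id)
        state.mcs_since_division[ids] += 1
        update_quiescence(state, config.division, ids)

        if field_ is not None:
            src_r, src_c = cm_sites(lattice, ids)
            field_.step(src_r, src_c)
            state.arrested[ids] = field_.arrested_mask(src_r, src_c)
            if first_arrest is None and state.arrested[ids].any():
                rn = radial_positions(lattice, ids[state.arrested[ids]])
                first_arrest = (mcs, float(rn.max()))

        labeling = (
            config.edu_on_mcs is not None
            and config.edu_on_mcs <= mcs < config.edu_off_mcs
        )
        eligible = (
            (lattice.volumes[ids] >= vt_half)
            & ~state.quiescent[ids]
            & ~state.arrested[ids]
            & (state.mcs_since_division[ids] > state.refractory_draw[ids])
        )
        if config.model == "stemcell":
            eligible &= lattice.cell_type[ids] == TYPE_STEM
        div_ids = ids[eligible]
        if div_ids.size:
            cx, cy = tissue_centroid(lattice)
            area = lattice.tissue_area * hexgrid.SITE_AREA
            radius = np.sqrt(area / np.pi)
        for cid in div_ids:
            cid = int(cid)
            a, b = split_cell(lattice, cid, rng)
            state.ensure_capacity(lattice._max_id)
            edu_update(state, cid, (a, b), labeling)
            for d in (a, b):
                state.mcs_since_division[d] = 0
                state.refractory_draw[d] = draw_refractory(config.division, rng)
                state.quiescent[d] = False
            if config.model == "stemcell":
                for d in (a, b):
                    lattice.cell_type[d] = (
                        TYPE_STEM if rng.random() < config.stem_retention else TYPE_SC
                    )
            n_divisions += 1
            x = lattice.sumx[a] + lattice.sumx[b]
            y = lattice.sumy[a] + lattice.sumy[b]
            v = lattice.volumes[a] + lattice.volumes[b]
            rnorm = np.hypot(x / v - cx, y / v - cy) / radius
            rows_div.append((mcs, cid, b, x / v, y / v, float(rnorm)))

        if mcs % config.record_every == 0 or mcs == config.total_mcs:
            ids = lattice.cell_ids()
            area_px = lattice.tissue_area
            mean_p = float(np.mean(cell_pressure(lattice.volumes[ids], p)))
            arrest_sites = (
                int((field_.M >= field_.params.M_TH).sum())
                if field_ is not None else 0
            )
            rows_traj.append(
                (
                    mcs, mcs * config.dt, ids.size, area_px,
                    area_px * config.dA, lattice.perimeter(), n_divisions,
                    int(state.quiescent[ids].sum()), mean_p,
                    int(state.arrested[ids].sum()), arrest_sites,
                )
            )

    traj = pd.DataFrame(
        rows_traj,
        columns=[
            "mcs", "time_s", "n_cells", "area_px", "area_m2", "S",
            "n_divisions", "n_quiescent", "mean_pressure", "n_arrested",
            "arrest_sites",
        ],
    )
    divs = pd.DataFrame(
        rows_div, columns=["mcs", "parent", "daughter", "x", "y", "rnorm"]
    )
    return RunResult(
        trajectory=traj, divisions=divs, lattice=lattice, state=state,
        config=config, field=field_, first_arrest=first_arrest,
    )
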