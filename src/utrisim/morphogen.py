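"""Diffusible growth-inhibitor field with threshold division arrest.

Each cell secretes inhibitor at rate ``kM`` from its centre of mass; the
field obeys ``d[M]/dt = D * lap([M]) + kM * sum_cells delta(CM)`` integrated
by forward Euler on the hexagonal lattice with no-flux boundaries.  A cell
whose centre-of-mass concentration reaches the threshold ``M_TH`` stops
dividing; arrest is re-evaluated every Monte Carlo step (in practice the
field only accumulates, so the arrest front advances outward from the
centre).

Units: the field value is an amount per site (pM); ``D`` and ``kM`` are
given in SI and converted through the model's spatial scale ``dA`` (m² per
site, giving the site spacing ``h = sqrt(2*dA/sqrt(3))``) and the Monte
Carlo step time ``dt`` (s).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels, hexgrid


@dataclass
class MorphogenParams:
    """Inhibitor-field parameters (SI units; defaults are the published values)."""

    D: float = 1.19e-14    # diffusion coefficient, m^2/s
    kM: float = 0.23       # secretion rate per cell, 1/s (pM per s deposited)
    M_TH: float = 0.1      # arrest threshold, pM
    alpha_max: float = 0.2  # stability bound on D*dt_sub/h^2 per substep
    substeps: int | None = None  # explicit override; validated for stability

    def __post_init__(self):
        if self.D < 0 or self.kM < 0 or self.M_TH < 0:
            raise ValueError("D, kM and M_TH must be non-negative")
        if not 0 < self.alpha_max <= 0.25:
            raise ValueError("alpha_max must be in (0, 0.25] for stability")


class MorphogenField:
    """Concentration grid matched to a lattice, with secretion sources."""

    def __init__(
        self,
        height: int,
        width: int,
        params: MorphogenParams | None = None,
        dt: float = 210.0,
        dA: float = 8.6e-13,
    ):
        self.params = params or MorphogenParams()
        self.dt = dt
        self.dA = dA
        self.M = np.zeros((height, width), dtype=np.float64)
        # site spacing squared (m^2): hexagon of area dA has spacing h with
        # dA = sqrt(3)/2 * h^2
        self.h2 = 2.0 * dA / np.sqrt(3.0)
        #: diffusion coefficient in site^2 per MCS
        self.D_mcs = self.params.D * dt / self.h2
        nsub_min = max(1, int(np.ceil(self.D_mcs / self.params.alpha_max)))
        nsub = self.params.substeps if self.params.substeps else nsub_min
        if self.D_mcs / nsub > 0.25 + 1e-12:
            raise ValueError(
                f"{nsub} substeps violate the forward-Euler stability bound "
                f"(D*dt_sub/h^2 = {self.D_mcs / nsub:.3f} > 0.25)"
            )
        self.substeps = nsub

    def total_mass(self) -> float:
        return float(self.M.sum())

    def step(self, src_rows: np.ndarray, src_cols: np.ndarray, n_mcs: int = 1) -> None:
        """Advance the field by ``n_mcs`` Monte Carlo steps (``n_mcs*dt`` s).

        ``src_rows/src_cols`` are the centre-of-mass sites of the secreting
        cells; each deposits ``kM*dt`` (pM) per MCS into its site.
        """
        alpha = self.D_mcs / self.substeps
        amount = self.params.kM * self.dt / self.substeps
        rows = np.ascontiguousarray(src_rows, dtype=np.int64)
        cols = np.ascontiguousarray(src_cols, dtype=np.int64)
        for _ in range(n_mcs):
            _kernels.diffuse_secrete(self.M, alpha, self.substeps, rows, cols, amount)

    def arrest_check(self, site: tuple[int, int]) -> bool:
        """True once the concentration at the site reaches the threshold."""
        return bool(self.M[site] >= self.params.M_TH)

    def arrested_mask(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        return self.M[rows, cols] >= self.params.M_TH


def center_of_mass_site(lattice, cid: int) -> tuple[int, int]:
    """Grid site of a cell's centre of mass.

    The pixel-centroid (Cartesian) is rounded to the nearest site; if that
    site is not owned by the cell (non-convex shapes), the nearest owned
    pixel is used instead.
    """
    x, y = lattice.center_of_mass(cid)
    site = hexgrid.nearest_site(x, y, lattice.height, lattice.width)
    if lattice.owner[site] == cid:
        return site
    rows, cols = lattice.cell_pixels(cid)
    px, py = hexgrid.to_cartesian(rows, cols)
    i = int(np.argmin((px - x) ** 2 + (py - y) ** 2))
    return int(rows[i]), int(cols[i])


def cm_sites(lattice, ids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centre-of-mass sites for many cells (vectorized fast path).

    Uses the rounded centroid site; falls back to the nearest owned pixel
    only where the rounded site is not inside the cell.
    """
    v = lattice.volumes[ids]
    x = lattice.sumx[ids] / v
    y = lattice.sumy[ids] / v
    rows = np.clip(np.round(y / hexgrid.SQRT3_2), 0, lattice.height - 1).astype(np.int64)
    cols = np.clip(np.round(x - 0.5 * (rows % 2)), 0, lattice.width - 1).astype(np.int64)
    bad = lattice.owner[rows, cols] != ids
    for i in np.nonzero(bad)[0]:
        rows[i], cols[i] = center_of_mass_site(lattice, int(ids[i]))
    return rows, cols
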