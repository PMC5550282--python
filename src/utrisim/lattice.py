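"""Hexagonal-lattice cellular Potts (GGH) engine.

The tissue is a set of cells, each a domain of hexagonal pixels, embedded in
a medium (cell id 0) that doubles as the *elastic boundary* (EB).  The
effective energy is

``H = c*JC*L_cc + c*E*S**2 + sum_s lam_vol*(v - VT)**2 + sum_s lam_surf*(s - ST)**2``

where ``L_cc`` counts unordered heterotypic cell-cell links, ``S`` counts
unordered cell-EB links (the tissue perimeter), and ``c`` (default 2) maps
the unordered counts onto the conventional ordered-pair double sums.  The
``c*E*S**2`` term replaces the per-link cell-medium contact energy: stretching
the surrounding elastic material by ``S`` stores elastic energy quadratic in
``S``, with the boundary Young's modulus ``E`` playing the role of the
cell-EB contact coefficient.

Dynamics are Metropolis index-copy attempts at membrane-fluctuation
amplitude ``Tm``; one Monte Carlo step (MCS) is ``width*height`` attempts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels, hexgrid


@dataclass
class EnergyParams:
    """Energy parameters of the Potts Hamiltonian.

    Defaults are the published simulation values for the utricle
    (elasticity-limited variant).  ``E`` is the Young's modulus of the
    elastic boundary (dimensionless in lattice units); the morphogen-limited
    variant uses ``E = 0.055``.
    """

    Tm: float = 5.0
    VT: int = 40
    lambda_vol: float = 9.0
    ST: int = 25
    lambda_surf: float = 1.5
    JC: float = 20.0
    E: float = 0.069
    boundary_pair_factor: float = 2.0  # "c": ordered-pair counting convention

    def __post_init__(self):
        if self.Tm <= 0:
            raise ValueError("Tm must be strictly positive")
        for name in ("lambda_vol", "lambda_surf", "JC", "E"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.VT < 2:
            raise ValueError("VT must be at least 2")


@dataclass
class CellRecord:
    """Read-only snapshot of one cell's bookkeeping."""

    id: int
    type: int
    volume: int
    surface: int
    center_of_mass: tuple[float, float]  # Cartesian (x, y)


class Lattice:
    """Site-ownership grid plus incremental per-cell bookkeeping.

    Attributes maintained incrementally (and auditable against
    :meth:`recount`): per-cell volume ``v``, surface ``s`` (heterotypic link
    count), Cartesian coordinate sums for centres of mass, and the tissue
    perimeter ``S``.
    """

    EB = 0

    def __init__(self, owner: np.ndarray, params: EnergyParams | None = None):
        owner = np.ascontiguousarray(owner, dtype=np.int64)
        if owner.ndim != 2:
            raise ValueError("owner grid must be 2-D")
        if owner.min() < 0:
            raise ValueError("cell ids must be non-negative (0 = EB)")
        self.owner = owner
        self.params = params or EnergyParams()
        self.mcs = 0
        self._rebuild()

    # -- construction -----------------------------------------------------

    @classmethod
    def empty(cls, height: int, width: int, params: EnergyParams | None = None):
        return cls(np.zeros((height, width), dtype=np.int64), params)

    @property
    def height(self) -> int:
        return self.owner.shape[0]

    @property
    def width(self) -> int:
        return self.owner.shape[1]

    def _rebuild(self) -> None:
        """Recompute all bookkeeping from the owner grid (brute force)."""
        p = self.params
        max_id = int(self.owner.max())
        cap = max(2 * (max_id + 1), 64)
        vols, surfs, sumx, sumy, S, *_ = _kernels.recount(
            self.owner, max_id, p.VT, p.lambda_vol, p.ST, p.lambda_surf,
            p.JC, p.E, p.boundary_pair_factor,
        )
        self.volumes = np.zeros(cap, dtype=np.int64)
        self.surfaces = np.zeros(cap, dtype=np.int64)
        self.sumx = np.zeros(cap, dtype=np.float64)
        self.sumy = np.zeros(cap, dtype=np.float64)
        self.cell_type = np.ones(cap, dtype=np.int64)
        n = max_id + 1
        self.volumes[:n] = vols
        self.surfaces[:n] = surfs
        self.sumx[:n] = sumx
        self.sumy[:n] = sumy
        self._S = np.array([S], dtype=np.int64)
        self._max_id = max_id

    def ensure_capacity(self, max_id: int) -> None:
        if max_id < len(self.volumes):
            self._max_id = max(self._max_id, max_id)
            return
        cap = max(2 * (max_id + 1), 2 * len(self.volumes))
        for name in ("volumes", "surfaces", "sumx", "sumy", "cell_type"):
            old = getattr(self, name)
            new = np.zeros(cap, dtype=old.dtype)
            if name == "cell_type":
                new[:] = 1
            new[: len(old)] = old
            setattr(self, name, new)
        self._max_id = max(self._max_id, max_id)

    # -- queries -----------------------------------------------------------

    def neighbors(self, site: tuple[int, int]) -> list[tuple[int, int]]:
        """In-bounds hexagonal neighbours of ``site``."""
        return hexgrid.neighbors(site, self.height, self.width)

    def cell_ids(self) -> np.ndarray:
        """Ids of live cells (volume > 0)."""
        n = self._max_id + 1
        ids = np.nonzero(self.volumes[:n] > 0)[0]
        return ids[ids != self.EB]

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids())

    @property
    def tissue_area(self) -> int:
        """Total cell pixels."""
        n = self._max_id + 1
        return int(self.volumes[1:n].sum())

    def perimeter(self) -> int:
        """Tissue perimeter S: unordered cell-EB neighbour links."""
        return int(self._S[0])

    def center_of_mass(self, cid: int) -> tuple[float, float]:
        v = self.volumes[cid]
        if v <= 0:
            raise ValueError(f"cell {cid} has no pixels")
        return self.sumx[cid] / v, self.sumy[cid] / v

    def cell(self, cid: int) -> CellRecord:
        return CellRecord(
            id=cid,
            type=int(self.cell_type[cid]),
            volume=int(self.volumes[cid]),
            surface=int(self.surfaces[cid]),
            center_of_mass=self.center_of_mass(cid),
        )

    def cell_pixels(self, cid: int) -> tuple[np.ndarray, np.ndarray]:
        rows, cols = np.nonzero(self.owner == cid)
        return rows, cols

    # -- energies ----------------------------------------------------------

    def energy_terms(self) -> dict[str, float]:
        """Full (brute-force) energy decomposition.

        Returns contact, volume, surface and boundary terms plus their sum
        ``total``.  Pure function of the current grid; does not touch the
        incremental bookkeeping.
        """
        p = self.params
        *_, H_contact, H_vol, H_surf, H_boundary = _kernels.recount(
            self.owner, int(self.owner.max()), p.VT, p.lambda_vol, p.ST,
            p.lambda_surf, p.JC, p.E, p.boundary_pair_factor,
        )
        return {
            "contact": float(H_contact),
            "volume": float(H_vol),
            "surface": float(H_surf),
            "boundary": float(H_boundary),
            "total": float(H_contact + H_vol + H_surf + H_boundary),
        }

    def delta_H(self, source_site: tuple[int, int], target_site: tuple[int, int]) -> float:
        """Incremental energy change of copying the source owner onto the target.

        A same-owner pair is a no-op and returns 0.  Sites must be
        neighbours (the move the Metropolis kinetics can actually propose).
        """
        if target_site not in self.neighbors(source_site):
            raise ValueError("source and target must be neighbouring sites")
        p = self.params
        B = int(self.owner[source_site])
        dH, _, _, _ = _kernels.proposal_delta(
            self.owner, self.volumes, self.surfaces, int(self._S[0]),
            target_site[0], target_site[1], B,
            p.VT, p.lambda_vol, p.ST, p.lambda_surf, p.JC, p.E,
            p.boundary_pair_factor,
        )
        return float(dH)

    # -- dynamics ----------------------------------------------------------

    def monte_carlo_step(self) -> dict[str, int]:
        """Perform ``width*height`` index-copy attempts (one MCS).

        Returns step statistics.  Raises ``RuntimeError`` if a cell pixel
        reached the lattice border (the fixed-boundary lattice cannot
        represent tissue beyond its edge).
        """
        p = self.params
        accepted, edge = _kernels.run_mcs(
            self.owner, self.volumes, self.surfaces, self.sumx, self.sumy,
            self._S, p.Tm, p.VT, p.lambda_vol, p.ST, p.lambda_surf, p.JC,
            p.E, p.boundary_pair_factor,
        )
        self.mcs += 1
        if edge:
            raise RuntimeError(
                f"tissue touched the lattice edge at MCS {self.mcs}; "
                "enlarge the lattice or stiffen the boundary"
            )
        return {"mcs": self.mcs, "accepted": int(accepted)}

    def audit(self) -> None:
        """Assert incremental bookkeeping equals a brute-force recount."""
        p = self.params
        n = self._max_id + 1
        vols, surfs, sumx, sumy, S, *_ = _kernels.recount(
            self.owner, self._max_id, p.VT, p.lambda_vol, p.ST,
            p.lambda_surf, p.JC, p.E, p.boundary_pair_factor,
        )
        np.testing.assert_array_equal(self.volumes[:n], vols)
        np.testing.assert_array_equal(self.surfaces[:n], surfs)
        np.testing.assert_allclose(self.sumx[:n], sumx, atol=1e-6)
        np.testing.assert_allclose(self.sumy[:n], sumy, atol=1e-6)
        assert int(self._S[0]) == int(S), (self._S[0], S)

    # -- serialization -----------------------------------------------------

    def to_labels(self) -> np.ndarray:
        return self.owner.copy()

    def save_text(self, path) -> None:
        """Plain-text integer label matrix, one lattice row per line."""
        np.savetxt(path, self.owner, fmt="%d")

    @classmethod
    def load_text(cls, path, params: EnergyParams | None = None) -> "Lattice":
        return cls(np.loadtxt(path, dtype=np.int64), params)


def metropolis_accept(dH: float, Tm: float, rng: np.random.Generator) -> bool:
    """Boltzmann acceptance: always if ``dH <= 0``, else ``exp(-dH/Tm)``."""
    if Tm <= 0:
        raise ValueError("Tm must be strictly positive")
    if dH <= 0:
        return True
    return rng.random() < np.exp(-dH / Tm)
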