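"""Hexagonal-lattice geometry helpers.

Sites live on an "odd-r" offset grid: site ``(row, col)`` maps to the
Cartesian point ``x = col + 0.5*(row % 2)``, ``y = row * sqrt(3)/2`` so that
all six nearest neighbours sit at unit distance.  The lattice is bounded
(non-periodic); edge and corner sites simply have fewer neighbours.
"""

from __future__ import annotations

import numpy as np

SQRT3_2 = np.sqrt(3.0) / 2.0

#: per-parity neighbour offsets (d_row, d_col); row parity indexes axis 0
NEIGHBOR_OFFSETS = np.array(
    [
        # even rows
        [(0, -1), (0, 1), (-1, -1), (-1, 0), (1, -1), (1, 0)],
        # odd rows
        [(0, -1), (0, 1), (-1, 0), (-1, 1), (1, 0), (1, 1)],
    ],
    dtype=np.int64,
)

#: area of one hexagonal site when neighbour spacing is 1
SITE_AREA = SQRT3_2


def to_cartesian(row, col):
    """Cartesian coordinates of site centres (unit neighbour spacing)."""
    row = np.asarray(row)
    col = np.asarray(col)
    x = col + 0.5 * (row % 2)
    y = row * SQRT3_2
    return x, y


def nearest_site(x: float, y: float, height: int, width: int) -> tuple[int, int]:
    """Site whose centre is closest to the Cartesian point ``(x, y)``.

    Rounds to the nearest row first, then the nearest column within that
    row's parity; clamped to the lattice bounds.
    """
    row = int(np.clip(round(y / SQRT3_2), 0, height - 1))
    col = int(np.clip(round(x - 0.5 * (row % 2)), 0, width - 1))
    return row, col


def neighbors(site: tuple[int, int], height: int, width: int) -> list[tuple[int, int]]:
    """In-bounds hexagonal neighbours of ``site`` (≤ 6 of them).

    Raises ``IndexError`` for an out-of-bounds site.
    """
    r, c = site
    if not (0 <= r < height and 0 <= c < width):
        raise IndexError(f"site {site!r} outside {height}x{width} lattice")
    out = []
    for dr, dc in NEIGHBOR_OFFSETS[r % 2]:
        rr, cc = r + dr, c + dc
        if 0 <= rr < height and 0 <= cc < width:
            out.append((rr, cc))
    return out
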