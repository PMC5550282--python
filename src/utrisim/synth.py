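"""Seeded synthetic-data generators with recorded ground truth.

Every generator returns ``(data, truth)`` where ``truth`` is a plain dict of
the generating parameters, enabling closed-loop parameter-recovery tests of
the fitting and image-analysis pipelines.  Identical arguments and seed give
identical output.
"""

from __future__ import annotations

import numpy as np

from . import hexgrid
from .fitting import BimorphConstants, stage_to_seconds, vb_area

#: default developmental stages emulating the measured growth series
DEFAULT_STAGES = ("E15.5", "E16.5", "E17.5", "E18.5", "P0", "P2", "P6", "P14")

#: default von Bertalanffy truth: published fitted asymptote and rate, with
#: the growth onset t0 placed at E15 so the curve rises E15.5 -> P2
DEFAULT_VB_TRUTH = {
    "A_inf": 1.8e-7,   # m^2
    "r": 3.6e-6,       # 1/s
    "t0": 15.0 * 86_400.0,
}


def gen_growth_curve(
    A_inf: float = DEFAULT_VB_TRUTH["A_inf"],
    r: float = DEFAULT_VB_TRUTH["r"],
    t0: float = DEFAULT_VB_TRUTH["t0"],
    stages=DEFAULT_STAGES,
    noise: float = 0.03,
    seed: int = 0,
):
    """Saturating growth-curve measurements with relative Gaussian noise.

    Returns ``(t, A, sem, truth)``: stage times (s), noisy areas (m²), the
    per-point SEM implied by the noise level, and the truth record.
    """
    if A_inf <= 0 or r <= 0:
        raise ValueError("A_inf and r must be positive")
    rng = np.random.default_rng(seed)
    t = np.array([stage_to_seconds(s) for s in stages])
    mean = vb_area(t, A_inf, r, t0)
    A = mean * (1.0 + noise * rng.standard_normal(t.size))
    sem = np.maximum(noise * mean, 1e-12 * A_inf)
    truth = {"A_inf": A_inf, "r": r, "t0": t0, "noise": noise, "seed": seed}
    return t, A, sem, truth


def gen_voltage_trace(
    E: float = 640.0,
    sigma0: float = 0.0,
    A0: float = 2.0e-5,
    L0: float = 2.0e-3,
    n_steps: int = 30,
    step: float = 2.0e-6,
    noise: float = 0.02,
    sample_dt: float = 500e-6,
    onset0: float = 1.0,
    period: float = 3.0,
    duration: float = 1.0,
    constants: BimorphConstants | None = None,
    seed: int = 0,
):
    """Synthetic bimorph voltage trace for a gel of Young's modulus ``E`` (Pa).

    Each probe presses the gel with a cumulative base displacement
    ``i*step``; the gel (spring ``E*A0/L0``) and the bimorph (spring ``K_B``)
    act in series, and the plateau voltage of probe ``i`` reports the total
    contact force.  White Gaussian noise is added at ``noise`` times the
    largest plateau.  Returns ``(trace, truth)``.
    """
    consts = constants or BimorphConstants()
    rng = np.random.default_rng(seed)
    n_samples = int(round((onset0 + n_steps * period) / sample_dt))
    trace = np.zeros(n_samples)
    k_gel = E * A0 / L0
    k_ser = 1.0 / (1.0 / consts.K_B + 1.0 / k_gel) if E > 0 else 0.0
    plateaus = np.empty(n_steps)
    for i in range(n_steps):
        force = sigma0 * A0 + k_ser * (i + 1) * step
        plateaus[i] = force / consts.force_per_volt
        i_on = int(round((onset0 + i * period) / sample_dt))
        i_off = int(round((onset0 + i * period + duration) / sample_dt))
        trace[i_on:i_off] = plateaus[i]
    if noise > 0 and n_steps > 0:
        trace += noise * plateaus.max() * rng.standard_normal(n_samples)
    truth = {
        "E": E, "sigma0": sigma0, "A0": A0, "L0": L0, "n_steps": n_steps,
        "step": step, "noise": noise, "sample_dt": sample_dt,
        "onset0": onset0, "period": period, "duration": duration,
        "plateaus": plateaus, "seed": seed,
    }
    return trace, truth


def _blob_radius(theta, radius, modes, rng):
    """Smooth low-frequency radial perturbation of a circle."""
    r = np.full_like(np.asarray(theta, float), float(radius))
    for k, amp in modes:
        phase = rng.uniform(0, 2 * np.pi)
        r += radius * amp * np.cos(k * np.asarray(theta) + phase)
    return r


def gen_edu_images(
    n_images: int = 5,
    shape: tuple[int, int] = (320, 320),
    radius: float = 80.0,
    ring_offset: float = 15.0,
    ring_width: float = 6.0,
    punctae_per_image: int = 400,
    puncta_sigma: float = 1.5,
    puncta_intensity: float = 120.0,
    sox2_intensity: float = 180.0,
    background: float = 8.0,
    boundary_modes=((3, 0.04), (5, 0.02)),
    max_shift: float = 6.0,
    seed: int = 0,
):
    """Paired EdU/Sox2 images: a punctate proliferation ring inside a blob.

    The Sox2 channel is a filled smooth blob; the EdU channel carries
    Gaussian punctae whose radial positions sit ``ring_offset`` pixels inside
    the blob boundary (SD ``ring_width``).  Each image is independently
    jittered and translated.  Returns ``(pairs, truth)`` where ``pairs`` is a
    list of ``(edu, sox2)`` float arrays.
    """
    if ring_offset < 0 or ring_offset + 3 * ring_width >= radius:
        raise ValueError("ring must lie inside the blob")
    rng = np.random.default_rng(seed)
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    pairs = []
    shifts = []
    for _ in range(n_images):
        cy = h / 2 + rng.uniform(-max_shift, max_shift)
        cx = w / 2 + rng.uniform(-max_shift, max_shift)
        shifts.append((cy, cx))
        theta = np.arctan2(yy - cy, xx - cx)
        rad = np.hypot(yy - cy, xx - cx)
        rb = _blob_radius(theta, radius, boundary_modes, rng)
        sox2 = np.where(rad <= rb, sox2_intensity, 0.0)
        sox2 += background * rng.standard_normal(shape)
        edu = np.zeros(shape)
        th = rng.uniform(0, 2 * np.pi, punctae_per_image)
        rb_p = np.interp(th, np.linspace(-np.pi, np.pi, 720),
                         _blob_radius(np.linspace(-np.pi, np.pi, 720),
                                      radius, boundary_modes, rng))
        rp = rb_p - ring_offset + ring_width * rng.standard_normal(punctae_per_image)
        px = cx + rp * np.cos(th)
        py = cy + rp * np.sin(th)
        for x0, y0 in zip(px, py):
            x_lo, x_hi = int(max(x0 - 5, 0)), int(min(x0 + 6, w))
            y_lo, y_hi = int(max(y0 - 5, 0)), int(min(y0 + 6, h))
            if x_lo >= x_hi or y_lo >= y_hi:
                continue
            sub_y, sub_x = np.mgrid[y_lo:y_hi, x_lo:x_hi].astype(float)
            edu[y_lo:y_hi, x_lo:x_hi] += puncta_intensity * np.exp(
                -((sub_x - x0) ** 2 + (sub_y - y0) ** 2) / (2 * puncta_sigma**2)
            )
        edu += background * rng.standard_normal(shape)
        pairs.append((np.clip(edu, 0, 255), np.clip(sox2, 0, 255)))
    truth = {
        "radius": radius, "ring_offset": ring_offset, "ring_width": ring_width,
        "punctae_per_image": punctae_per_image, "shifts": shifts, "seed": seed,
    }
    return pairs, truth


def gen_initial_tissue(
    n_cells: int,
    height: int = 200,
    width: int = 200,
    VT: int = 40,
    seed: int = 0,
    lloyd_iterations: int = 8,
):
    """Centered disk of ``n_cells`` roughly equal cells of ~``VT`` pixels each.

    The ``n_cells*VT`` hexagonal sites nearest the lattice centre are
    partitioned by a seeded farthest-point initialization followed by Lloyd
    relaxation, giving compact cells with volumes close to ``VT``.  Returns
    the integer owner grid (ids 1..n_cells, 0 = medium).
    """
    if n_cells < 1:
        raise ValueError("need at least one cell")
    rng = np.random.default_rng(seed)
    n_px = n_cells * VT
    if n_px > height * width:
        raise ValueError("requested tissue area exceeds the lattice")
    rows, cols = np.mgrid[0:height, 0:width]
    x, y = hexgrid.to_cartesian(rows.ravel(), cols.ravel())
    cx, cy = (width - 0.5) / 2.0, (height - 1) * hexgrid.SQRT3_2 / 2.0
    d2 = (x - cx) ** 2 + (y - cy) ** 2
    order = np.argsort(d2, kind="stable")[:n_px]
    rr, cc = rows.ravel()[order], cols.ravel()[order]
    if (rr.min() == 0 or rr.max() == height - 1
            or cc.min() == 0 or cc.max() == width - 1):
        raise ValueError("requested tissue area reaches the lattice edge")
    pts = np.column_stack(hexgrid.to_cartesian(rr, cc))

    # farthest-point seeding, then Lloyd relaxation toward equal cells
    seeds = np.empty((n_cells, 2))
    seeds[0] = pts[rng.integers(len(pts))]
    dist = np.sum((pts - seeds[0]) ** 2, axis=1)
    for i in range(1, n_cells):
        seeds[i] = pts[int(np.argmax(dist))]
        dist = np.minimum(dist, np.sum((pts - seeds[i]) ** 2, axis=1))
    for _ in range(lloyd_iterations):
        d = ((pts[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
        label = np.argmin(d, axis=1)
        for i in range(n_cells):
            mask = label == i
            if mask.any():
                seeds[i] = pts[mask].mean(axis=0)
    d = ((pts[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    label = np.argmin(d, axis=1)

    owner = np.zeros((height, width), dtype=np.int64)
    # relabel so every id 1..n is non-empty
    used = np.unique(label)
    remap = {int(old): new for new, old in enumerate(used, start=1)}
    owner[rr, cc] = np.array([remap[int(l)] for l in label], dtype=np.int64)
    return owner
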