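"""Minimal rendering helpers (PNG snapshots, field heatmaps, profiles)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np


def render_lattice(owner: np.ndarray, path=None, ax=None):
    """Render a label grid; cells coloured by id, medium white."""
    if ax is None:
        fig, ax = plt.subplots(figsize=(5, 5))
    else:
        fig = ax.figure
    img = np.ma.masked_equal(owner, 0)
    rng = np.random.default_rng(0)
    n = int(owner.max()) + 1
    colors = rng.uniform(0.2, 0.95, size=(max(n, 2), 3))
    shown = np.ones(owner.shape + (3,))
    mask = owner > 0
    shown[mask] = colors[owner[mask] % len(colors)]
    ax.imshow(shown, interpolation="nearest")
    ax.set_axis_off()
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return ax


def render_field(M: np.ndarray, path=None, threshold: float | None = None):
    """Heatmap of the inhibitor field (spectral colormap); optional threshold
    contour marking the arrest front."""
    fig, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(M, cmap="Spectral_r", interpolation="bilinear")
    fig.colorbar(im, ax=ax, label="[M] (pM)")
    if threshold is not None and M.max() >= threshold:
        ax.contour(M, levels=[threshold], colors="white", linewidths=1.5)
    ax.set_axis_off()
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def plot_profile(profile, path=None):
    """EdU density against signed boundary distance (negative = interior)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(profile.distance, profile.mean, color="tab:green")
    ax.fill_between(
        profile.distance,
        profile.mean - profile.se,
        profile.mean + profile.se,
        alpha=0.3,
        color="tab:green",
    )
    ax.axvline(0, color="k", lw=0.8, ls="--")
    ax.set_xlabel("distance from boundary (px; negative = inside)")
    ax.set_ylabel("mean EdU intensity")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
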