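"""EdU boundary-distance profiling of averaged, registered image pairs.

The procedure mirrors pulse-chase quantification: several EdU/Sox2 image
pairs are Gaussian-blurred (to merge punctae), centred by the Sox2-mask
centroid, and averaged; the mean Sox2 mask yields a smoothed closed outline
of the sensory epithelium; intensity strips perpendicular to the outline are
averaged into a profile of EdU density versus signed distance from the
boundary (negative = inside the epithelium).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path as MplPath
from scipy import ndimage
from scipy.interpolate import splev, splprep
from skimage import filters, measure


@dataclass
class ImagePair:
    """One registered two-channel acquisition (float arrays, 0-255 scale)."""

    edu: np.ndarray
    sox2: np.ndarray
    pixel_size: float = 1.0  # micrometres per pixel (metadata only)

    def __post_init__(self):
        if self.edu.shape != self.sox2.shape:
            raise ValueError("channel dimensions differ")


@dataclass
class Outline:
    """Closed polyline in array coordinates (row, col), stored open-ended."""

    vertices: np.ndarray  # (N, 2) float, implicitly cyclic
    closed: bool = True

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be (N, 2)")

    @property
    def n(self) -> int:
        return len(self.vertices)

    def signed_area(self) -> float:
        """Shoelace area in (x=col, y=row) coordinates."""
        y = self.vertices[:, 0]
        x = self.vertices[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.vertices, self.vertices[:1]]), axis=0)
        return float(np.sum(np.hypot(d[:, 0], d[:, 1])))

    def as_path(self) -> MplPath:
        return MplPath(self.vertices[:, ::-1])  # (x, y) order


@dataclass
class BoundaryProfile:
    """Mean intensity versus signed boundary distance (negative = interior)."""

    distance: np.ndarray
    mean: np.ndarray
    se: np.ndarray
    n_strips: int

    @property
    def peak_distance(self) -> float:
        return float(self.distance[int(np.argmax(self.mean))])


def _mask_and_centroid(sox2: np.ndarray, threshold: float | None):
    thr = filters.threshold_otsu(sox2) if threshold is None else threshold
    mask = sox2 > thr
    if not mask.any():
        raise ValueError("empty Sox2 mask; lower the threshold")
    cy, cx = ndimage.center_of_mass(mask)
    return mask, (cy, cx)


def blur_center_average(
    pairs: list[ImagePair],
    sigma: float = 5.0,
    threshold: float | None = None,
) -> tuple[ImagePair, list[tuple[float, float]]]:
    """Gaussian-blur, translation-align, and average image pairs.

    Each pair is shifted so its Sox2-mask centroid moves to the cohort-mean
    centroid (a single image is therefore returned unshifted); the EdU
    channel is blurred with ``sigma`` before averaging (``sigma = 0`` leaves
    it untouched).  Returns the averaged pair and the applied shifts.
    """
    if not pairs:
        raise ValueError("need at least one image pair")
    shape = pairs[0].edu.shape
    cents = []
    for p in pairs:
        if p.edu.shape != shape:
            raise ValueError("image dimensions differ across the cohort")
        cents.append(_mask_and_centroid(p.sox2, threshold)[1])
    target = np.mean(np.asarray(cents), axis=0)
    edu_acc = np.zeros(shape)
    sox_acc = np.zeros(shape)
    shifts = []
    for p, c in zip(pairs, cents):
        dy, dx = target[0] - c[0], target[1] - c[1]
        shifts.append((dy, dx))
        edu = filters.gaussian(p.edu, sigma=sigma, preserve_range=True) if sigma > 0 else p.edu
        edu_acc += ndimage.shift(edu, (dy, dx), order=1, mode="nearest")
        sox_acc += ndimage.shift(p.sox2, (dy, dx), order=1, mode="nearest")
    n = len(pairs)
    return ImagePair(edu_acc / n, sox_acc / n, pairs[0].pixel_size), shifts


def mean_outline(
    sox2_images: list[np.ndarray],
    threshold: float | None = None,
) -> Outline:
    """Median boundary of the thresholded Sox2 masks.

    Per-image binary masks (given threshold, or Otsu per image) are averaged
    through their signed distance transforms (positive inside) and the zero
    level set of the mean is extracted.  For a single mask this is its 0.5
    contour; for a cohort it is the boundary lying midway between the
    per-image boundaries, which stays well defined even where a plain mean
    mask plateaus at exactly 0.5.  Oriented so the shoelace area is positive.
    """
    if not sox2_images:
        raise ValueError("need at least one Sox2 image")
    acc = np.zeros(sox2_images[0].shape)
    for img in sox2_images:
        mask = _mask_and_centroid(img, threshold)[0]
        acc += ndimage.distance_transform_edt(mask) - ndimage.distance_transform_edt(~mask)
    mean_sdf = acc / len(sox2_images)
    contours = measure.find_contours(mean_sdf, 0.0)
    if not contours:
        raise ValueError("no boundary contour in the mean mask")
    verts = max(contours, key=len)
    if np.allclose(verts[0], verts[-1]):
        verts = verts[:-1]
    out = Outline(verts)
    if out.signed_area() < 0:
        out = Outline(verts[::-1])
    return out


def smooth_outline(
    outline: Outline,
    smoothing: float | None = None,
    n_points: int = 400,
    n_harmonics: int = 12,
    max_deviation: float | None = None,
) -> Outline:
    """Smooth a closed outline, removing sharp short-wavelength variation.

    By default the outline is resampled at uniform arc length and low-passed
    to its first ``n_harmonics`` Fourier harmonics, then re-interpolated with
    a periodic spline; smooth shapes (a circle, a gently lobed blob) pass
    through essentially unchanged while pixel staircase and high-frequency
    zigzag are removed.  Passing ``smoothing`` instead uses a classical
    smoothing spline with that residual budget (scipy's ``s``).  If
    ``max_deviation`` is given, the result is required to stay within that
    distance of the input vertices.
    """
    if not outline.closed:
        raise ValueError("outline must be closed")
    if outline.n < 8:
        raise ValueError("need at least 8 vertices to smooth")
    pts = outline.vertices
    if smoothing is None:
        # uniform arc-length resampling, then harmonic truncation
        closed = np.vstack([pts, pts[:1]])
        seg = np.hypot(*np.diff(closed, axis=0).T)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        m = max(4 * n_harmonics, 64)
        targets = np.linspace(0, arc[-1], m, endpoint=False)
        resampled = np.column_stack([
            np.interp(targets, arc, closed[:, 0]),
            np.interp(targets, arc, closed[:, 1]),
        ])
        z = resampled[:, 0] + 1j * resampled[:, 1]
        F = np.fft.fft(z)
        keep = np.zeros(m, dtype=bool)
        keep[: n_harmonics + 1] = True
        keep[-n_harmonics:] = True
        zs = np.fft.ifft(np.where(keep, F, 0.0))
        low = np.column_stack([zs.real, zs.imag])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tck, _ = splprep([low[:, 0], low[:, 1]], s=0, per=1)
            u = np.linspace(0, 1, n_points, endpoint=False)
            rr, cc = splev(u, tck)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tck, _ = splprep([pts[:, 0], pts[:, 1]], s=smoothing, per=1)
            u = np.linspace(0, 1, n_points, endpoint=False)
            rr, cc = splev(u, tck)
    sm = Outline(np.column_stack([rr, cc]))
    if sm.signed_area() < 0:
        sm = Outline(sm.vertices[::-1])
    if max_deviation is not None:
        d = np.min(
            np.hypot(
                pts[:, None, 0] - sm.vertices[None, :, 0],
                pts[:, None, 1] - sm.vertices[None, :, 1],
            ),
            axis=1,
        )
        if d.max() > max_deviation:
            raise ValueError(
                f"smoothed outline deviates {d.max():.2f} px > {max_deviation}"
            )
    return sm


def boundary_profile(
    image: np.ndarray,
    outline: Outline,
    strip_length: int = 400,
    n_strips: int = 200,
) -> BoundaryProfile:
    """Average intensity strips perpendicular to the outline.

    ``n_strips`` points are placed at uniform arc length along the outline;
    at each, the image is sampled bilinearly along the local normal at
    ``strip_length`` unit-spaced offsets centred on the boundary.  Offsets
    are signed with negative values inside the epithelium.  Strips with any
    sample outside the image are dropped (with a warning).  Returns the mean
    and standard error across strips.
    """
    verts = outline.vertices
    closed = np.vstack([verts, verts[:1]])
    seg = np.diff(closed, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    arc = np.concatenate([[0.0], np.cumsum(seglen)])
    total = arc[-1]
    targets = np.linspace(0, total, n_strips, endpoint=False)
    idx = np.searchsorted(arc, targets, side="right") - 1
    frac = (targets - arc[idx]) / np.maximum(seglen[idx], 1e-12)
    points = closed[idx] + frac[:, None] * seg[idx]
    # tangents by cyclic central differences of the anchor points: smooth and
    # insensitive to anchors landing exactly on polygon vertices
    diff = np.roll(points, -1, axis=0) - np.roll(points, 1, axis=0)
    tangents = diff / np.maximum(np.hypot(diff[:, 0], diff[:, 1]), 1e-12)[:, None]
    normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])

    path = outline.as_path()
    offsets = np.arange(strip_length) - strip_length / 2 + 0.5
    h, w = image.shape
    strips = []
    dropped = 0
    for p, nvec in zip(points, normals):
        probe = p + 2.0 * nvec
        if path.contains_point((probe[1], probe[0])):
            nvec = -nvec  # make the normal point outward
        rows = p[0] + offsets * nvec[0]
        cols = p[1] + offsets * nvec[1]
        if rows.min() < 0 or rows.max() > h - 1 or cols.min() < 0 or cols.max() > w - 1:
            dropped += 1
            continue
        strips.append(ndimage.map_coordinates(image, [rows, cols], order=1))
    if dropped:
        warnings.warn(f"dropped {dropped}/{n_strips} strips exiting the image")
    if not strips:
        raise ValueError("no strip fits inside the image; shorten strip_length")
    stack = np.asarray(strips)
    return BoundaryProfile(
        distance=offsets,
        mean=stack.mean(axis=0),
        se=stack.std(axis=0, ddof=1) / np.sqrt(len(stack)) if len(stack) > 1
        else np.full(strip_length, np.nan),
        n_strips=len(stack),
    )


def profile_pipeline(
    pairs: list[ImagePair],
    sigma: float = 5.0,
    threshold: float | None = None,
    smoothing: float | None = None,
    strip_length: int = 400,
    n_strips: int = 200,
):
    """Full procedure: blur/centre/average, mean Sox2 outline, smooth, profile.

    Returns ``(profile, smoothed_outline, averaged_pair)``.
    """
    avg, shifts = blur_center_average(pairs, sigma=sigma, threshold=threshold)
    aligned_sox = [
        ndimage.shift(p.sox2, s, order=1, mode="nearest")
        for p, s in zip(pairs, shifts)
    ]
    outline = smooth_outline(mean_outline(aligned_sox, threshold), smoothing)
    prof = boundary_profile(avg.edu, outline, strip_length, n_strips)
    return prof, outline, avg


def tissue_outline(mask: np.ndarray) -> Outline:
    """Closed outline of a boolean tissue mask (e.g. simulated owner > 0)."""
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ValueError("empty mask")
    verts = max(contours, key=len)
    if np.allclose(verts[0], verts[-1]):
        verts = verts[:-1]
    out = Outline(verts)
    if out.signed_area() < 0:
        out = Outline(verts[::-1])
    return out
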