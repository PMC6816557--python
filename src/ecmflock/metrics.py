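"""Matrix-topology metrics for fiber grids and grayscale matrix images.

Five metrics summarize a matrix pattern:

* **LRA / SRA** — long-/short-range alignment: per fiber, the weighted median
  acute angle to all fibers within a neighbourhood length (200 um / 20 um by
  default); the image value is the weighted mean of per-fiber medians D-bar,
  reported as the score ``1 - D-bar / (pi/2)`` so 1 = perfectly aligned and
  0.5 = the isotropic-random expectation.
* **HDM** — percentage of pixels above an intensity threshold.
* **Curv** — mean absolute turning angle (degrees) along skeletonized fiber
  paths sampled at a fixed arclength window.
* **Frac** — box-counting fractal dimension of the fiber mask.

Alignment metrics operate on an :class:`OrientedFiberField` (built directly
from a simulated grid, or estimated from an image via the structure tensor);
HDM, Curv and Frac operate on a grayscale image (for simulations, the
rendered matrix).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, asdict
from typing import Optional, Union

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import draw as skdraw
from skimage.feature import structure_tensor
from skimage.filters import gaussian, threshold_otsu
from skimage.morphology import skeletonize

from .fiber_grid import FiberGrid

__all__ = [
    "OrientedFiberField",
    "MetricSet",
    "MetricConfig",
    "field_from_grid",
    "field_from_image",
    "alignment",
    "lra",
    "sra",
    "high_density_matrix",
    "curvature",
    "fractal_dimension",
    "render_matrix",
    "compute_metric_set",
    "starplot_normalize",
]

METRIC_NAMES = ("lra", "sra", "hdm", "curv", "frac")


@dataclass
class OrientedFiberField:
    """Weighted apolar fiber orientations at spatial positions (um)."""

    positions: np.ndarray    # (n, 2)
    orientations: np.ndarray  # (n,) in [0, pi)
    weights: np.ndarray      # (n,) > 0

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        self.orientations = np.mod(np.asarray(self.orientations, dtype=float), np.pi)
        self.weights = np.asarray(self.weights, dtype=float)

    def __len__(self):
        return self.orientations.size


@dataclass
class MetricSet:
    """The five topology metrics for one matrix; missing values are NaN."""

    lra: float
    sra: float
    hdm: float
    curv: float
    frac: float

    def as_dict(self):
        return asdict(self)


@dataclass
class MetricConfig:
    """Tunable metric parameters (lengths in um, windows/sigmas in pixels)."""

    lra_length: float = 200.0
    sra_length: float = 20.0
    max_focal: int = 400           # focal-fiber subsample for alignment
    alignment_seed: int = 0
    hdm_threshold: Optional[float] = None  # None -> Otsu
    curvature_window: int = 10
    blur_sigma_large: float = 8.0
    blur_sigma_small: float = 2.0
    pixel_scale: float = 2.5       # um per pixel for rendered matrix
    render_cutoff: float = 25.0    # fiber count rendered at full intensity


def field_from_grid(grid: FiberGrid) -> OrientedFiberField:
    """One field entry per nonzero bin per grid point; orientation is the
    bin's left bound, weight its fiber count, position the grid-cell centre."""
    ix, iy, b = np.nonzero(grid.bins)
    dx, dy = grid.spacing
    pos = np.column_stack([(ix + 0.5) * dx, (iy + 0.5) * dy])
    ori = b * np.pi / grid.n_bins
    return OrientedFiberField(pos, ori, grid.bins[ix, iy, b])


def field_from_image(image: np.ndarray, pixel_scale: float = 1.0,
                     threshold: Optional[float] = None,
                     sigma: float = 2.0) -> OrientedFiberField:
    """Estimate a fiber field from a grayscale image via the structure tensor.

    Pixels above ``threshold`` (Otsu by default) become fibers whose apolar
    orientation is the dominant local edge direction and whose weight is the
    pixel intensity.
    """
    image = np.asarray(image, dtype=float)
    if threshold is None:
        threshold = threshold_otsu(image)
    mask = image > threshold
    if not mask.any():
        return OrientedFiberField(np.zeros((0, 2)), np.zeros(0), np.zeros(0))
    Arr, Arc, Acc = structure_tensor(image, sigma=sigma, order="rc")
    # orientation of least intensity variation = along the fiber
    ori = 0.5 * np.arctan2(2 * Arc, Acc - Arr) + np.pi / 2
    rr, cc = np.nonzero(mask)
    pos = np.column_stack([cc, rr]).astype(float) * pixel_scale
    return OrientedFiberField(pos, ori[rr, cc], image[rr, cc])


def _weighted_median(values, weights):
    # interpolated weighted median (midpoint convention, unbiased for
    # equal weights and small samples)
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5 * w.sum(), cum, v))


def alignment(field: OrientedFiberField, neighbourhood_length: float,
              max_focal: int = 400, seed: int = 0) -> float:
    """Alignment score in [0, 1] at the given neighbourhood length.

    Per fiber, the weighted median acute angle (in [0, pi/2]) to all other
    fibers within the neighbourhood; the image-level deviation D-bar is the
    weighted mean of per-fiber medians over (a seeded subsample of) focal
    fibers; the score is ``1 - D-bar / (pi/2)``.  NaN when fewer than two
    fibers or no fiber has a neighbour in range.
    """
    n = len(field)
    if n < 2 or neighbourhood_length <= 0:
        return float("nan")
    rng = np.random.default_rng(seed)
    focal = np.arange(n)
    if n > max_focal:
        focal = rng.choice(n, size=max_focal, replace=False, p=field.weights / field.weights.sum())
    tree = cKDTree(field.positions)
    neighbours = tree.query_ball_point(field.positions[focal], neighbourhood_length)
    medians, fw = [], []
    for f, idx in zip(focal, neighbours):
        idx = np.asarray(idx)
        idx = idx[idx != f]
        if idx.size == 0:
            continue
        dev = np.abs(field.orientations[idx] - field.orientations[f]) % np.pi
        dev = np.minimum(dev, np.pi - dev)
        medians.append(_weighted_median(dev, field.weights[idx]))
        fw.append(field.weights[f])
    if not medians:
        return float("nan")
    d_bar = np.average(medians, weights=fw)
    return float(1.0 - d_bar / (np.pi / 2))


def lra(field: OrientedFiberField, length: float = 200.0, **kw) -> float:
    """Long-range alignment (default neighbourhood 200 um)."""
    return alignment(field, length, **kw)


def sra(field: OrientedFiberField, length: float = 20.0, **kw) -> float:
    """Short-range alignment (default neighbourhood 20 um)."""
    return alignment(field, length, **kw)


def high_density_matrix(image: np.ndarray, threshold: Optional[float] = None) -> float:
    """Percentage of pixels above ``threshold`` (Otsu by default)."""
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    if threshold is None:
        if image.min() == image.max():
            return 0.0 if image.max() <= 0 else 100.0
        threshold = threshold_otsu(image)
    return 100.0 * float(np.count_nonzero(image > threshold)) / image.size


# ---- curvature --------------------------------------------------------------

_NBRS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _trace_paths(skel: np.ndarray):
    """Decompose a skeleton into ordered pixel paths (branches and cycles)."""
    kernel = np.ones((3, 3)); kernel[1, 1] = 0
    degree = ndimage.convolve(skel.astype(np.uint8), kernel, mode="constant")
    pixels = set(zip(*np.nonzero(skel)))
    endpoints = [p for p in pixels if degree[p] == 1]
    visited = set()

    def walk(start):
        path = [start]
        visited.add(start)
        cur = start
        while True:
            if degree[cur] > 2 and len(path) > 1:
                break  # stop at junctions
            nxt = None
            for dr, dc in _NBRS:
                q = (cur[0] + dr, cur[1] + dc)
                if q in pixels and q not in visited:
                    nxt = q
                    break
            if nxt is None:
                break
            path.append(nxt)
            visited.add(nxt)
            cur = nxt
        return path

    paths = [walk(p) for p in endpoints if p not in visited]
    # remaining unvisited pixels are cycles (e.g. closed loops)
    for p in pixels:
        if p not in visited and degree[p] > 0:
            paths.append(walk(p))
    return [np.asarray(p, dtype=float) for p in paths if len(p) > 1]


def curvature(image: np.ndarray, window: int = 10,
              blur_sigma_large: float = 8.0,
              threshold: Optional[float] = None) -> float:
    """Mean absolute turning angle (degrees) per sampling window.

    The image is blurred with a large-radius Gaussian and thresholded to a
    mask of the principal fiber structure, skeletonized, and each skeleton
    path is resampled at equal arclength increments of ``window`` pixels; the
    metric is the average absolute angle between consecutive chords.
    """
    if window < 2:
        raise ValueError("window must be >= 2 pixels")
    image = np.asarray(image, dtype=float)
    blurred = gaussian(image, sigma=blur_sigma_large) if blur_sigma_large > 0 else image
    if threshold is None:
        if blurred.min() == blurred.max():
            # constant image: everything is fiber (if nonzero) or nothing is
            mask = blurred > 0
            if not mask.any():
                return float("nan")
        else:
            mask = blurred > threshold_otsu(blurred)
    else:
        mask = blurred > threshold
    if not mask.any():
        return float("nan")
    skel = skeletonize(mask)
    angles = []
    for path in _trace_paths(skel):
        seg = np.hypot(*np.diff(path, axis=0).T)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        if cum[-1] < 2 * window:
            continue
        targets = np.arange(0, cum[-1] + 1e-9, window)
        pts = np.column_stack([np.interp(targets, cum, path[:, 0]),
                               np.interp(targets, cum, path[:, 1])])
        chords = np.diff(pts, axis=0)
        if len(chords) < 2:
            continue
        a, b = chords[:-1], chords[1:]
        cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
        dot = (a * b).sum(axis=1)
        angles.extend(np.abs(np.degrees(np.arctan2(cross, dot))))
    return float(np.mean(angles)) if angles else float("nan")


def fractal_dimension(image: np.ndarray, blur_sigma_small: float = 2.0,
                      threshold: Optional[float] = None) -> float:
    """Box-counting dimension of the blurred-and-thresholded fiber mask.

    Occupied boxes are counted at dyadic side lengths from half the (padded)
    image size down to 2 px; the dimension is minus the slope of the
    least-squares fit of log(count) against log(side).
    """
    image = np.asarray(image, dtype=float)
    blurred = gaussian(image, sigma=blur_sigma_small) if blur_sigma_small > 0 else image
    if threshold is None:
        if blurred.min() == blurred.max():
            mask = blurred > 0
        else:
            mask = blurred > threshold_otsu(blurred)
    else:
        mask = blurred > threshold
    if not mask.any():
        return float("nan")
    # crop to the occupied bounding box (translation invariance), keep the
    # aspect ratio on a square canvas, then resample to a dyadic square so
    # box counts scale exactly with no partial-box distortion
    rr, cc = np.nonzero(mask)
    crop = mask[rr.min():rr.max() + 1, cc.min():cc.max() + 1]
    side = max(crop.shape)
    square = np.zeros((side, side), dtype=bool)
    square[: crop.shape[0], : crop.shape[1]] = crop
    size = 1 << int(np.ceil(np.log2(max(side, 4))))
    if square.shape != (size, size):
        from skimage.transform import resize

        padded = resize(square.astype(float), (size, size), order=0,
                        anti_aliasing=False) > 0.5
    else:
        padded = square
    sides, counts = [], []
    s = size // 2
    while s >= 2:
        nb = size // s
        blocks = padded.reshape(nb, s, nb, s).any(axis=(1, 3))
        sides.append(s)
        counts.append(blocks.sum())
        s //= 2
    slope = np.polyfit(np.log(sides), np.log(counts), 1)[0]
    return float(-slope)


def render_matrix(grid: FiberGrid, pixel_scale: float = 2.5,
                  cutoff: float = 25.0, bundle_width: float = 5.0) -> np.ndarray:
    """Render a fiber grid to a grayscale image in [0, 1].

    Each occupied grid point is drawn as a fiber-bundle segment along its
    densest bin's orientation, centred on the grid cell, with intensity
    ``min(density / cutoff, 1)`` — density at or above the cut-off renders at
    full intensity.  Segments span twice the grid spacing (so collinear
    neighbours join up) and are ``bundle_width`` um wide; overlaps keep the
    maximum intensity.
    """
    w, h = grid.width, grid.height
    H, W = int(round(h / pixel_scale)), int(round(w / pixel_scale))
    img = np.zeros((H, W))
    totals = grid.bins.sum(axis=2)
    dense_bin = grid.bins.argmax(axis=2)
    dx, dy = grid.spacing
    half_len = dx / pixel_scale  # half-length = grid spacing (segments join up)
    n_w = max(int(round(bundle_width / pixel_scale)), 1)
    lateral = np.arange(n_w) - n_w // 2  # integer pixel offsets across the bundle
    for b in range(grid.n_bins):
        sel = (totals > 0) & (dense_bin == b)
        if not sel.any():
            continue
        ix, iy = np.nonzero(sel)
        intens = np.minimum(grid.bins[ix, iy, b] / cutoff, 1.0)
        phi = b * np.pi / grid.n_bins
        # canonical thick-segment offsets for this orientation (rows=y, cols=x)
        rr0_parts, cc0_parts = [], []
        for off in lateral:
            orr = int(round(off * np.cos(phi)))
            occ = int(round(-off * np.sin(phi)))
            rr1, cc1 = skdraw.line(
                int(round(-half_len * np.sin(phi))) + orr,
                int(round(-half_len * np.cos(phi))) + occ,
                int(round(half_len * np.sin(phi))) + orr,
                int(round(half_len * np.cos(phi))) + occ,
            )
            rr0_parts.append(rr1)
            cc0_parts.append(cc1)
        rr0 = np.concatenate(rr0_parts)
        cc0 = np.concatenate(cc0_parts)
        cr = np.round((iy + 0.5) * dy / pixel_scale).astype(int)
        cc = np.round((ix + 0.5) * dx / pixel_scale).astype(int)
        rr = (cr[:, None] + rr0[None, :]) % H
        cols = (cc[:, None] + cc0[None, :]) % W
        vals = np.broadcast_to(intens[:, None], rr.shape)
        np.maximum.at(img, (rr.ravel(), cols.ravel()), vals.ravel())
    return img


def compute_metric_set(source: Union[FiberGrid, np.ndarray],
                       config: Optional[MetricConfig] = None) -> MetricSet:
    """Dispatch the five metrics for a fiber grid or a grayscale image.

    Grids use the fiber field directly for LRA/SRA and the rendered image
    for HDM/Curv/Frac; the rendered intensity scale is fixed against the
    density cut-off, so grid HDM uses a fixed threshold of 0.5 (half the
    cut-off density) unless overridden.
    """
    cfg = config or MetricConfig()
    if isinstance(source, FiberGrid):
        fld = field_from_grid(source)
        image = render_matrix(source, cfg.pixel_scale, cfg.render_cutoff)
        hdm_thr = 0.5 if cfg.hdm_threshold is None else cfg.hdm_threshold
    else:
        image = np.asarray(source, dtype=float)
        fld = field_from_image(image, pixel_scale=cfg.pixel_scale)
        hdm_thr = cfg.hdm_threshold
    return MetricSet(
        lra=alignment(fld, cfg.lra_length, cfg.max_focal, cfg.alignment_seed),
        sra=alignment(fld, cfg.sra_length, cfg.max_focal, cfg.alignment_seed),
        hdm=high_density_matrix(image, hdm_thr),
        curv=curvature(image, cfg.curvature_window, cfg.blur_sigma_large),
        frac=fractal_dimension(image, cfg.blur_sigma_small),
    )


def starplot_normalize(metric_sets):
    """Min-max normalize each metric axis across a collection of MetricSets.

    Constant axes map to 0.5.  Returns a list of dicts in input order.
    """
    if len(metric_sets) < 2:
        raise ValueError("need at least two metric sets to normalize")
    rows = [m.as_dict() if isinstance(m, MetricSet) else dict(m) for m in metric_sets]
    out = [dict(r) for r in rows]
    for name in METRIC_NAMES:
        vals = np.array([r[name] for r in rows], dtype=float)
        lo, hi = np.nanmin(vals), np.nanmax(vals)
        scaled = np.full_like(vals, 0.5) if hi == lo else (vals - lo) / (hi - lo)
        for r, v in zip(out, scaled):
            r[name] = float(v)
    return out
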