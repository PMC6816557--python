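"""Deterministic synthetic matrix patterns with known metric values.

These generators provide ground-truth inputs for the metrics pipeline with
no external data: aligned stripes (alignment 1, curvature ~0), seeded
isotropic fields (alignment ~0.5), swirls (short-range > long-range
alignment), circles (curvature from chord geometry), Hilbert-curve rasters
(fractal dimension -> 2), and blank/filled images.  Field-based fixtures are
built as a :class:`~ecmflock.fiber_grid.FiberGrid` and rendered with the
same pipeline as simulated matrix, so thresholds transfer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .fiber_grid import FiberGrid, bin_of
from .metrics import OrientedFiberField, field_from_grid, render_matrix

__all__ = ["FixtureSpec", "generate", "hilbert_points", "KINDS"]

KINDS = (
    "aligned_stripes",
    "isotropic",
    "swirl",
    "checkerboard_domains",
    "circle_arcs",
    "hilbert_raster",
    "blank",
    "filled",
)


@dataclass
class FixtureSpec:
    """Parameters for one synthetic pattern.

    ``domain`` (um) and ``grid_shape`` size the field-based fixtures;
    ``image_size`` (px) sizes the purely image-based ones.  ``density`` is
    the fiber count written into each occupied bin (the default 25 renders
    at full intensity).
    """

    kind: str
    domain: float = 1000.0
    grid_shape: tuple = (100, 100)
    density: float = 25.0
    angle: float = 0.0              # stripe orientation, radians
    stripe_period: int = 10         # grid rows per stripe repeat
    block: int = 25                 # checkerboard block size, grid points
    radius: float = 60.0            # circle radius, px
    order: int = 7                  # Hilbert-curve order
    image_size: int = 400
    pixel_scale: float = 2.5        # um per px for rendered fields
    seed: int = 0


def hilbert_points(order: int) -> np.ndarray:
    """Vertices of the Hilbert curve of the given order on a 2^order grid."""
    n = 1 << order
    pts = np.empty((n * n, 2), dtype=int)
    for d in range(n * n):
        rx = ry = 0
        x = y = 0
        t = d
        s = 1
        while s < n:
            rx = 1 & (t // 2)
            ry = 1 & (t ^ rx)
            if ry == 0:  # rotate quadrant
                if rx == 1:
                    x, y = s - 1 - x, s - 1 - y
                x, y = y, x
            x += s * rx
            y += s * ry
            t //= 4
            s *= 2
        pts[d] = (x, y)
    return pts


def _grid_fixture(spec: FixtureSpec) -> FiberGrid:
    nx, ny = spec.grid_shape
    grid = FiberGrid((nx, ny), (spec.domain, spec.domain))
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "aligned_stripes":
        # solid bands a few grid rows thick, separated by gaps, so the
        # curvature mask resolves distinct straight ridges
        iy = np.arange(ny)
        band = max(min(3, spec.stripe_period - 2), 1)
        rows = iy[(iy % spec.stripe_period) < band]
        grid.bins[:, rows[:, None], bin_of(spec.angle) - 1] = spec.density
    elif spec.kind == "isotropic":
        b = rng.integers(0, grid.n_bins, size=(nx, ny))
        ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        grid.bins[ix, iy, b] = spec.density
    elif spec.kind == "checkerboard_domains":
        ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        odd = ((ix // spec.block) + (iy // spec.block)) % 2 == 1
        b0, b90 = bin_of(0.0) - 1, bin_of(np.pi / 2) - 1
        grid.bins[~odd, b0] = spec.density
        grid.bins[odd, b90] = spec.density
    elif spec.kind == "swirl":
        dx, dy = grid.spacing
        cx = cy = spec.domain / 2
        for radius in np.arange(6 * dx, 0.48 * spec.domain, 2 * dx):
            n_pts = max(int(2 * np.pi * radius / dx), 8)
            ang = np.linspace(0, 2 * np.pi, n_pts, endpoint=False)
            x, y = cx + radius * np.cos(ang), cy + radius * np.sin(ang)
            tangent = ang + np.pi / 2
            ix, iy = grid.point_index(x, y)
            grid.bins[ix, iy, bin_of(tangent) - 1] = spec.density
    else:
        raise ValueError(f"not a grid fixture: {spec.kind}")
    return grid


def _image_fixture(spec: FixtureSpec) -> np.ndarray:
    size = spec.image_size
    if spec.kind == "blank":
        return np.zeros((size, size))
    if spec.kind == "filled":
        return np.ones((size, size))
    if spec.kind == "circle_arcs":
        rr, cc = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
        dist = np.hypot(rr - size / 2, cc - size / 2)
        return (np.abs(dist - spec.radius) <= 1.5).astype(float)
    if spec.kind == "hilbert_raster":
        n = 1 << spec.order
        scale = max(size // n, 1)
        img = np.zeros((n * scale, n * scale))
        pts = hilbert_points(spec.order) * scale + scale // 2
        for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
            rr = np.linspace(y0, y1, max(abs(x1 - x0), abs(y1 - y0)) + 1).astype(int)
            cc = np.linspace(x0, x1, rr.size).astype(int)
            img[rr, cc] = 1.0
        return img
    raise ValueError(f"not an image fixture: {spec.kind}")


def generate(spec: FixtureSpec):
    """Build a fixture: returns ``(field, image, expected_metrics)``.

    ``expected_metrics`` maps metric names to ``(value, tolerance)`` where an
    analytic expectation exists, plus optional ordering relations under the
    key ``"relations"``.  ``field`` is None for purely image-based kinds.
    """
    if spec.kind not in KINDS:
        raise ValueError(f"unknown fixture kind {spec.kind!r}; choose from {KINDS}")

    if spec.kind in ("aligned_stripes", "isotropic", "checkerboard_domains", "swirl"):
        grid = _grid_fixture(spec)
        field = field_from_grid(grid)
        if spec.kind == "isotropic":
            # continuous uniform apolar orientations (the grid image stays
            # bin-quantized, matching the rendering pipeline)
            rng = np.random.default_rng(spec.seed + 1)
            field = OrientedFiberField(
                field.positions,
                rng.uniform(0.0, np.pi, len(field)),
                field.weights,
            )
        image = render_matrix(grid, spec.pixel_scale)
        if spec.kind == "aligned_stripes":
            expected = {"lra": (1.0, 1e-9), "sra": (1.0, 1e-9), "curv": (0.0, 1.0)}
        elif spec.kind == "isotropic":
            # median acute deviation of uniform apolar angles is pi/4 -> 0.5
            expected = {"lra": (0.5, 0.03), "sra": (0.5, 0.03)}
        elif spec.kind == "swirl":
            expected = {"relations": ("sra>lra",)}
        else:  # checkerboard_domains: domains are locally uniform
            expected = {"relations": ("sra>=lra",)}
        return field, image, expected

    image = _image_fixture(spec)
    if spec.kind == "blank":
        expected = {"hdm": (0.0, 1e-9)}
    elif spec.kind == "filled":
        expected = {"hdm": (100.0, 1e-9), "frac": (2.0, 0.05)}
    elif spec.kind == "circle_arcs":
        expected = {"curv_per_window": lambda w: np.degrees(w / spec.radius)}
    else:  # hilbert_raster
        expected = {"frac": (2.0, 0.1)}
    return None, image, expected
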