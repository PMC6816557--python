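"""The matrix layer: a lattice of grid points with binned apolar fiber densities.

Each grid point holds ``n_bins`` (default 8) non-negative fiber counts; bin
``b`` (1-based) covers orientations ``[(b-1)*pi/n_bins, b*pi/n_bins)`` so the
bins partition ``[0, pi)``.  Fibers are apolar: an orientation ``theta`` and
``theta + pi`` fall in the same bin.  Cells deposit, degrade and rearrange
fibers at the grid point under their head, and are guided by a bin sampled
with probability proportional to its fiber count (Gillespie-style selection).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "FiberGrid",
    "bin_of",
    "deposit",
    "degrade",
    "rearrange",
    "select_guidance_bin",
    "density_feedback_scale",
]


def bin_of(theta, n_bins: int = 8):
    """Return the 1-based orientation bin for ``theta`` (radians).

    Orientations are folded into ``[0, pi)`` first (fibers are apolar), then
    binned in increments of ``pi / n_bins``.  Accepts scalars or arrays.
    """
    folded = np.mod(theta, np.pi)
    # snap values a few ulp below a boundary (e.g. 11*pi/8 folding to just
    # under 3*pi/8) onto it, then guard the folded == pi roundoff case
    b = np.floor(folded * n_bins / np.pi + 1e-9).astype(int) + 1
    return np.where(b > n_bins, 1, b) if np.ndim(b) else (1 if b > n_bins else int(b))


def deposit(bins: np.ndarray, theta: float, rate: float) -> np.ndarray:
    """Add ``rate`` fibers to the bin that ``theta`` falls in; returns a copy."""
    if rate < 0:
        raise ValueError("deposition rate must be >= 0")
    out = np.array(bins, dtype=float)
    out[bin_of(theta, out.size) - 1] += rate
    return out


def degrade(bins: np.ndarray, rate: float) -> np.ndarray:
    """Deplete every bin by ``rate``, flooring at zero; returns a copy."""
    if rate < 0:
        raise ValueError("degradation rate must be >= 0")
    return np.maximum(np.asarray(bins, dtype=float) - rate, 0.0)


def rearrange(bins: np.ndarray, theta: float, rate: float) -> np.ndarray:
    """Move up to ``rate`` fibers from each cyclic neighbor of ``theta``'s bin
    into that bin.  Total fiber count is conserved; returns a copy.
    """
    if rate < 0:
        raise ValueError("rearrangement rate must be >= 0")
    out = np.array(bins, dtype=float)
    n = out.size
    b = bin_of(theta, n) - 1
    for nb in ((b - 1) % n, (b + 1) % n):
        moved = min(rate, out[nb])
        out[nb] -= moved
        out[b] += moved
    return out


def select_guidance_bin(bins: np.ndarray, rng: np.random.Generator):
    """Sample a 1-based bin with probability proportional to its fiber count.

    Returns ``None`` when all bins are empty (no fiber to flock with).
    """
    bins = np.asarray(bins, dtype=float)
    total = bins.sum()
    if total <= 0:
        return None
    return int(rng.choice(bins.size, p=bins / total)) + 1


def density_feedback_scale(d, d_lo: float = 5.0, d_hi: float = 10.0):
    """Piecewise-linear scaling f(d) of matrix feedback with fiber density.

    f(d) = 0 for d <= d_lo, 1 for d >= d_hi, linear in between.  The default
    way-points f(5) = 0 and f(10) = 1 come from matching observed migratory
    persistence on thin (4-day) versus thick (7-day) matrix.
    """
    d = np.asarray(d, dtype=float)
    out = np.clip((d - d_lo) / (d_hi - d_lo), 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


class FiberGrid:
    """Dense lattice of fiber-orientation bins over a periodic domain.

    Parameters
    ----------
    grid_shape : (nx, ny)
        Number of grid points along x and y.
    domain_size : (width, height)
        Physical extent in micrometres; grid point (ix, iy) owns the
        half-open cell ``[ix*dx, (ix+1)*dx) x [iy*dy, (iy+1)*dy)``.
    n_bins : int
        Orientation bins per grid point (>= 2).
    """

    def __init__(self, grid_shape=(100, 100), domain_size=(1000.0, 1000.0), n_bins: int = 8):
        nx, ny = grid_shape
        if nx < 1 or ny < 1:
            raise ValueError("grid_shape entries must be >= 1")
        if n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        self.nx, self.ny = int(nx), int(ny)
        self.width, self.height = float(domain_size[0]), float(domain_size[1])
        self.n_bins = int(n_bins)
        self.bins = np.zeros((self.nx, self.ny, self.n_bins), dtype=float)

    @property
    def spacing(self):
        return self.width / self.nx, self.height / self.ny

    def copy(self) -> "FiberGrid":
        g = FiberGrid((self.nx, self.ny), (self.width, self.height), self.n_bins)
        g.bins = self.bins.copy()
        return g

    def point_index(self, x, y):
        """Grid indices (ix, iy) of the points containing positions (x, y).

        Positions are wrapped periodically into the domain first.
        """
        dx, dy = self.spacing
        ix = np.floor_divide(np.mod(x, self.width), dx).astype(int)
        iy = np.floor_divide(np.mod(y, self.height), dy).astype(int)
        return np.clip(ix, 0, self.nx - 1), np.clip(iy, 0, self.ny - 1)

    def total_fibers(self) -> float:
        return float(self.bins.sum())

    # ---- batch update used by the simulation step --------------------------

    def update_at(self, ix, iy, thetas, dep_rate, deg_rate, re_rate):
        """Apply deposition, degradation and rearrangement for a batch of
        cells whose heads sit at grid points ``(ix[i], iy[i])`` with (new)
        orientations ``thetas[i]``.

        Equivalent to processing cells one at a time in index order:
        deposition is additive; degradation at a point visited by k cells
        depletes each bin by ``k * deg_rate`` (floored at zero); rearrangement
        is applied sequentially for cells sharing a grid point.
        """
        ix = np.asarray(ix, dtype=int)
        iy = np.asarray(iy, dtype=int)
        thetas = np.asarray(thetas, dtype=float)
        if ix.size == 0:
            return
        b = bin_of(thetas, self.n_bins) - 1

        if dep_rate > 0:
            np.add.at(self.bins, (ix, iy, b), dep_rate)

        flat = ix * self.ny + iy
        uniq, counts = np.unique(flat, return_counts=True)
        uix, uiy = uniq // self.ny, uniq % self.ny
        if deg_rate > 0:
            self.bins[uix, uiy] = np.maximum(
                self.bins[uix, uiy] - deg_rate * counts[:, None], 0.0
            )

        if re_rate > 0:
            # points visited once: vectorized; shared points: sequential
            order = np.argsort(flat, kind="stable")
            first = np.searchsorted(flat[order], uniq)
            single = counts == 1
            if np.any(single):
                si = order[first[single]]
                bs = b[si]
                xs, ys = ix[si], iy[si]
                for nb_off in (-1, 1):
                    nb = (bs + nb_off) % self.n_bins
                    moved = np.minimum(re_rate, self.bins[xs, ys, nb])
                    self.bins[xs, ys, nb] -= moved
                    self.bins[xs, ys, bs] += moved
            for u, f0, c in zip(uniq[~single], first[~single], counts[~single]):
                for i in order[f0:f0 + c]:
                    self.bins[ix[i], iy[i]] = rearrange(
                        self.bins[ix[i], iy[i]], thetas[i], re_rate
                    )

    def select_guidance_bins(self, ix, iy, rng: np.random.Generator):
        """Gillespie bin selection for a batch of cells.

        Returns ``(bin0, d)`` where ``bin0`` is the 0-based selected bin (-1
        where every bin is empty) and ``d`` the fiber count of that bin.
        """
        sub = self.bins[ix, iy]                       # (n, n_bins)
        totals = sub.sum(axis=1)
        bin0 = np.full(totals.shape, -1, dtype=int)
        d = np.zeros(totals.shape)
        ok = totals > 0
        if np.any(ok):
            cum = np.cumsum(sub[ok], axis=1)
            u = rng.random(int(ok.sum())) * totals[ok]
            sel = (cum < u[:, None]).sum(axis=1)
            sel = np.minimum(sel, self.n_bins - 1)
            bin0[ok] = sel
            d[ok] = sub[ok, sel]
        return bin0, d

    @property
    def bin_left_bounds(self) -> np.ndarray:
        """Left bound (radians) of each bin: (b-1)*pi/n_bins for b = 1..n."""
        return np.arange(self.n_bins) * np.pi / self.n_bins
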