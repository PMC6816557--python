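"""Agent layer of the two-layer nematic flocking model.

Cells are self-propelled 4-bead rods on a continuous 2-D domain.  At every
step each cell's new heading is a weighted combination of three unit-vector
terms computed from the time-t state:

* a persistence/noise term ``(cos(theta + eta), sin(theta + eta))`` with
  ``eta ~ N(0, Var(eta))``, weight ``w_p = 1 - w_c - w_m``;
* a cell-cell guidance term, the mean heading of contacting cells after
  nematic (apolar) adjustment, weight ``w_c`` (zero when no contacts);
* a matrix guidance term, the left bound of a fiber bin sampled under the
  cell's head proportionally to fiber count, nematically adjusted, weight
  ``w_m`` (zero when no fiber underneath; optionally scaled by the
  density-feedback function f(d)).

Orientations are updated synchronously, then each cell reworks the fiber
grid point under its head (deposition, degradation, rearrangement) using its
new heading, then positions advance by ``speed * v_e`` along the new heading,
where ``v_e < 1`` is a volume-exclusion speed penalty applied when the head
bead overlaps another cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .fiber_grid import FiberGrid, density_feedback_scale, select_guidance_bin
from .params import SimulationParams

__all__ = [
    "DirectionComponents",
    "Simulation",
    "initialize",
    "nematic_representative",
    "noise_term",
    "cell_guidance_term",
    "matrix_guidance_term",
    "combine_terms",
    "wrap_angle",
]

_TWO_PI = 2.0 * np.pi


def wrap_angle(theta):
    """Wrap angles into [0, 2*pi)."""
    return np.mod(theta, _TWO_PI)


def nematic_representative(theta_ref, theta_other):
    """Apolar representative of ``theta_other`` relative to ``theta_ref``.

    Returns whichever of ``theta_other`` or ``theta_other + pi`` (wrapped to
    [0, 2*pi)) lies within a circular distance of pi/2 of ``theta_ref``; ties
    at exactly pi/2 keep ``theta_other`` unmodified.  This is the nematic
    adjustment applied to both contact-cell headings and fiber orientations:
    an antiparallel neighbour reinforces, rather than reverses, alignment.
    """
    theta_ref = np.asarray(theta_ref, dtype=float)
    theta_other = np.asarray(theta_other, dtype=float)
    d = np.abs(np.mod(theta_other - theta_ref + np.pi, _TWO_PI) - np.pi)
    out = wrap_angle(np.where(d <= np.pi / 2, theta_other, theta_other + np.pi))
    return float(out) if out.ndim == 0 else out


def noise_term(theta, noise_variance, rng: np.random.Generator):
    """Persistent-random-walk term: unit vector at ``theta + eta``."""
    eta = rng.normal(0.0, np.sqrt(noise_variance), size=np.shape(theta))
    a = np.asarray(theta, dtype=float) + eta
    return np.cos(a), np.sin(a)


def cell_guidance_term(theta_i, contact_thetas):
    """Mean nematic-adjusted heading of contacting cells, or None if none.

    The magnitude of the result is <= 1 (exactly 1 for a single contact); the
    guidance weight is independent of the number of contacts.
    """
    contact_thetas = np.atleast_1d(np.asarray(contact_thetas, dtype=float))
    if contact_thetas.size == 0:
        return None
    rep = nematic_representative(theta_i, contact_thetas)
    return float(np.mean(np.cos(rep))), float(np.mean(np.sin(rep)))


def matrix_guidance_term(theta_i, bins, rng: np.random.Generator):
    """Unit vector along a density-sampled fiber bin, or None when empty.

    Returns ``(xm, ym, d)`` with ``d`` the fiber count of the selected bin;
    the cell flocks with the left bound of that bin, nematically adjusted.
    """
    bins = np.asarray(bins, dtype=float)
    b = select_guidance_bin(bins, rng)
    if b is None:
        return None
    phi = (b - 1) * np.pi / bins.size
    rep = nematic_representative(theta_i, phi)
    return float(np.cos(rep)), float(np.sin(rep)), float(bins[b - 1])


@dataclass
class DirectionComponents:
    """The three guidance terms and their weighted combination for one cell."""

    xp: float
    yp: float
    xc: Optional[float]
    yc: Optional[float]
    xm: Optional[float]
    ym: Optional[float]
    effective_wc: float
    effective_wm: float
    xi: float = 0.0
    yi: float = 0.0


def combine_terms(theta_prev, comps: DirectionComponents, w_p):
    """Convex combination of the available terms; returns the new heading.

    Absent terms enter with zero weight and the combination is renormalized
    by the sum of the applied weights.  A numerically zero resultant keeps
    the previous heading.
    """
    norm = w_p + comps.effective_wc + comps.effective_wm
    x = w_p * comps.xp + comps.effective_wc * (comps.xc or 0.0)
    y = w_p * comps.yp + comps.effective_wc * (comps.yc or 0.0)
    x += comps.effective_wm * (comps.xm or 0.0)
    y += comps.effective_wm * (comps.ym or 0.0)
    if norm > 0:
        x, y = x / norm, y / norm
    comps.xi, comps.yi = x, y
    if np.hypot(x, y) < 1e-12:
        return wrap_angle(theta_prev)
    return wrap_angle(np.arctan2(y, x))


class Simulation:
    """Vectorized state and stepper for one run of the two-layer model."""

    def __init__(self, params: SimulationParams, rng: Optional[np.random.Generator] = None):
        self.params = params
        self.rng = rng if rng is not None else np.random.default_rng(params.rng_seed)
        # independent substreams: the noise stream must not depend on how
        # many guidance-bin selections the matrix state happens to trigger
        self._noise_rng, self._select_rng = self.rng.spawn(2)
        w, h = params.domain_size
        n = params.n_cells
        self.theta = self.rng.uniform(0.0, _TWO_PI, n)
        self.pos = np.column_stack([self.rng.uniform(0, w, n), self.rng.uniform(0, h, n)])
        self.speed = self._draw_speeds(n)
        self.pos_unwrapped = self.pos.copy()
        self.grid = FiberGrid(params.grid_shape, params.domain_size, params.n_bins)
        self.t = 0
        self._offsets = params.bead_offsets()
        self._radii = params.bead_radii()
        self._n_beads = self._offsets.size

    def _draw_speeds(self, n):
        p = self.params
        if p.speed_sd == 0:
            return np.full(n, p.speed_mean)
        s = self.rng.normal(p.speed_mean, p.speed_sd, n)
        while np.any(s < 0):  # Gaussian truncated at zero
            bad = s < 0
            s[bad] = self.rng.normal(p.speed_mean, p.speed_sd, int(bad.sum()))
        return s

    # ---- geometry ----------------------------------------------------------

    def bead_centers(self, theta=None, pos=None):
        """Bead centre positions, shape (n_cells, n_beads, 2), head first."""
        theta = self.theta if theta is None else theta
        pos = self.pos if pos is None else pos
        u = np.column_stack([np.cos(theta), np.sin(theta)])
        return pos[:, None, :] + self._offsets[None, :, None] * u[:, None, :]

    def _bead_pairs(self):
        """All bead pairs of distinct cells within contact range.

        Returns ``(cell_a, cell_b, within_contact, within_exclusion,
        bead_a, bead_b)`` arrays: contact uses the full sum of bead radii,
        exclusion the inner ``overlap_fraction`` of it.
        """
        p = self.params
        w, h = p.domain_size
        beads = self.bead_centers().reshape(-1, 2)
        rmax = 2 * self._radii.max()
        if p.boundary == "periodic":
            tree = cKDTree(np.mod(beads, (w, h)), boxsize=(w, h))
        else:
            tree = cKDTree(beads)
        pairs = tree.query_pairs(rmax, output_type="ndarray")
        if pairs.size == 0:
            z = np.zeros(0, dtype=int)
            return z, z, np.zeros(0, bool), np.zeros(0, bool), z, z
        a, b = pairs[:, 0], pairs[:, 1]
        ca, cb = a // self._n_beads, b // self._n_beads
        keep = ca != cb
        a, b, ca, cb = a[keep], b[keep], ca[keep], cb[keep]
        delta = beads[a] - beads[b]
        if p.boundary == "periodic":
            delta -= np.round(delta / (w, h)) * (w, h)
        dist = np.hypot(delta[:, 0], delta[:, 1])
        ba, bb = a % self._n_beads, b % self._n_beads
        sumr = self._radii[ba] + self._radii[bb]
        return ca, cb, dist < sumr, dist < p.overlap_fraction * sumr, ba, bb

    # ---- one synchronous step ---------------------------------------------

    def step(self):
        p = self.params
        n = p.n_cells
        if n == 0:
            self.t += 1
            return
        ca, cb, contact, excl, ba, bb = self._bead_pairs()

        # (1) new orientations from the time-t state
        xp, yp = noise_term(self.theta, p.noise_variance, self._noise_rng)

        sum_c = np.zeros((n, 2))
        n_contacts = np.zeros(n)
        if np.any(contact):
            i, j = ca[contact], cb[contact]
            # deduplicate cell pairs touching through several bead pairs
            key = np.where(i < j, i * n + j, j * n + i)
            _, first = np.unique(key, return_index=True)
            i, j = i[first], j[first]
            rep_ij = nematic_representative(self.theta[i], self.theta[j])
            rep_ji = nematic_representative(self.theta[j], self.theta[i])
            np.add.at(sum_c, i, np.column_stack([np.cos(rep_ij), np.sin(rep_ij)]))
            np.add.at(sum_c, j, np.column_stack([np.cos(rep_ji), np.sin(rep_ji)]))
            np.add.at(n_contacts, i, 1)
            np.add.at(n_contacts, j, 1)
        has_contact = n_contacts > 0
        xc = np.where(has_contact, sum_c[:, 0] / np.maximum(n_contacts, 1), 0.0)
        yc = np.where(has_contact, sum_c[:, 1] / np.maximum(n_contacts, 1), 0.0)

        u = np.column_stack([np.cos(self.theta), np.sin(self.theta)])
        head = self.pos + self._offsets[0] * u
        ix, iy = self.grid.point_index(head[:, 0], head[:, 1])
        bin0, d = self.grid.select_guidance_bins(ix, iy, self._select_rng)
        has_fiber = bin0 >= 0
        phi = np.where(has_fiber, bin0, 0) * np.pi / p.n_bins
        rep_m = nematic_representative(self.theta, phi)
        xm = np.where(has_fiber, np.cos(rep_m), 0.0)
        ym = np.where(has_fiber, np.sin(rep_m), 0.0)

        eff_wc = np.where(has_contact, p.w_c, 0.0)
        eff_wm = np.where(has_fiber, p.w_m, 0.0)
        if p.density_feedback_enabled:
            eff_wm = eff_wm * density_feedback_scale(d, p.d_lo, p.d_hi)

        w_p = p.w_p
        norm = w_p + eff_wc + eff_wm
        X = (w_p * xp + eff_wc * xc + eff_wm * xm) / np.maximum(norm, 1e-300)
        Y = (w_p * yp + eff_wc * yc + eff_wm * ym) / np.maximum(norm, 1e-300)
        degenerate = np.hypot(X, Y) < 1e-12
        theta_new = np.where(degenerate, self.theta, wrap_angle(np.arctan2(Y, X)))

        # (2) matrix updates at the head grid point, using the new heading
        self.grid.update_at(ix, iy, theta_new,
                            p.deposition_rate, p.degradation_rate, p.rearrangement_rate)

        # (3) positions: volume-exclusion slowdown if the head bead overlaps
        head_overlap = np.zeros(n, dtype=bool)
        if np.any(excl):
            head_overlap[ca[excl & (ba == 0)]] = True
            head_overlap[cb[excl & (bb == 0)]] = True
        v_e = np.where(head_overlap, p.v_e_factor, 1.0)
        disp = (self.speed * v_e)[:, None] * np.column_stack(
            [np.cos(theta_new), np.sin(theta_new)]
        )
        self.theta = theta_new
        self.pos_unwrapped = self.pos_unwrapped + disp
        self.pos = self._apply_boundary(self.pos + disp)
        self.t += 1

    def _apply_boundary(self, pos):
        w, h = self.params.domain_size
        if self.params.boundary == "periodic":
            return np.mod(pos, (w, h))
        # reflecting: fold positions back and mirror the heading
        for axis, size in enumerate((w, h)):
            x = np.mod(pos[:, axis], 2 * size)
            over = x > size
            x[over] = 2 * size - x[over]
            pos[:, axis] = x
            if np.any(over):
                if axis == 0:
                    self.theta[over] = wrap_angle(np.pi - self.theta[over])
                else:
                    self.theta[over] = wrap_angle(-self.theta[over])
        return pos

    def run(self, n_steps: Optional[int] = None, record_tracks: bool = False,
            record_every: int = 1):
        """Advance ``n_steps`` (default: the full configured duration).

        With ``record_tracks``, returns an array of unwrapped cell positions
        of shape (n_records, n_cells, 2) including the initial state.
        """
        n_steps = self.params.n_steps if n_steps is None else n_steps
        tracks = [self.pos_unwrapped.copy()] if record_tracks else None
        for k in range(n_steps):
            self.step()
            if record_tracks and (k + 1) % record_every == 0:
                tracks.append(self.pos_unwrapped.copy())
        return np.asarray(tracks) if record_tracks else None


def initialize(params: SimulationParams, rng: Optional[np.random.Generator] = None) -> Simulation:
    """Place ``n_cells`` uniformly at random with uniform random headings and
    truncated-Gaussian speeds over an all-zero fiber grid."""
    return Simulation(params, rng)
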