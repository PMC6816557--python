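"""Simulation parameters, cell-shape tables and tissue presets.

Unit conventions: lengths in micrometres, time in steps of ``dt`` minutes,
angles in radians.  ``noise_variance`` is the per-step variance of the
Gaussian angular perturbation (Var(eta)); the guidance weights ``w_c``
(cell-cell) and ``w_m`` (matrix feedback) satisfy ``w_c + w_m <= 1`` so that
the persistence weight ``w_p = 1 - w_c - w_m`` is non-negative.

The default time base is dt = 30 min (48 steps per simulated day); this
calibration makes the mean guidance-bin fiber density pass through ~5 at
day 4 and ~10 at day 7 under deposition rate 1, which is the density scale
the feedback function f(d) and the rendering cut-off (25) are defined on.
The default speed advances a cell about one fiber-grid cell per step, which
is what lets cells follow (and thereby reinforce) individual fiber tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np

__all__ = [
    "SimulationParams",
    "CELL_SHAPES",
    "TISSUE_PRESETS",
    "STEPS_PER_DAY",
    "noise_variance_from_eta",
]

#: Bead radius multipliers per shape, head first.  The default elongated cell
#: is a 4-bead chain (head r, two body beads 2r, tail r): length 12r, width
#: 4r, aspect ratio 3:1.  All shapes have equal area (10*pi*r^2).
CELL_SHAPES = {
    "elongated": (1.0, 2.0, 2.0, 1.0),
    "teardrop": (2.0, 2.0, 1.0, 1.0),
    "rounded": (np.sqrt(2.5),) * 4,
}

#: 48 steps/day at dt = 30 min.
STEPS_PER_DAY = 48


def noise_variance_from_eta(eta: float, interpretation: str = "sd") -> float:
    """Map a phenotype noise level eta to the per-step variance Var(eta).

    The sweep grids quote noise as eta in {0, 0.07, 0.14, 0.21}.  Under the
    default ``"sd"`` interpretation these are per-step standard deviations
    (variance = eta**2), which yields a graded alignment transition across
    the grid and lets matrix feedback generate short-range order for noisy
    cells; under ``"variance"`` they are used as variances directly, which
    collapses every eta > 0 phenotype into the same fully disordered state.
    """
    if interpretation == "sd":
        return float(eta) ** 2
    if interpretation == "variance":
        return float(eta)
    raise ValueError("interpretation must be 'sd' or 'variance'")


@dataclass(frozen=True)
class SimulationParams:
    """Every model constant for one simulation run."""

    noise_variance: float = 0.14 ** 2  # Var(eta), rad^2 per step (eta = 0.14)
    w_c: float = 0.03                  # cell-cell guidance weight
    w_m: float = 0.0                   # matrix feedback weight
    speed_mean: float = 10.0           # um per step: ~one grid cell per step
    speed_sd: float = 2.0
    n_cells: int = 800                 # ~40% confluence on the default domain
    domain_size: tuple = (1000.0, 1000.0)  # um
    dt: float = 30.0                   # minutes per step
    duration_days: float = 7.0
    deposition_rate: float = 1.0       # fibers per step
    degradation_rate: float = 0.0
    rearrangement_rate: float = 0.0
    density_feedback_enabled: bool = False
    d_lo: float = 5.0                  # f(d) way-points (fiber counts)
    d_hi: float = 10.0
    cell_shape: str = "elongated"
    bead_radius: float = 4.0           # r, um; projected area ~500 um^2
    overlap_fraction: float = 0.75     # "inner 75%" volume-exclusion trigger
    v_e_factor: float = 0.25           # speed multiplier on head overlap
    grid_shape: tuple = (100, 100)
    n_bins: int = 8
    boundary: str = "periodic"         # or "reflecting"
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.w_c < 0 or self.w_m < 0 or self.w_c + self.w_m > 1 + 1e-12:
            raise ValueError(
                f"need 0 <= w_c, 0 <= w_m and w_c + w_m <= 1 so that the "
                f"persistence weight w_p = 1 - w_c - w_m stays non-negative; "
                f"got w_c={self.w_c}, w_m={self.w_m}"
            )
        if self.noise_variance < 0:
            raise ValueError("noise_variance must be >= 0")
        for name in ("deposition_rate", "degradation_rate", "rearrangement_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if not self.d_lo < self.d_hi:
            raise ValueError("d_lo must be < d_hi")
        if not 0 < self.v_e_factor <= 1:
            raise ValueError("v_e_factor must be in (0, 1]")
        if not 0 < self.overlap_fraction <= 1:
            raise ValueError("overlap_fraction must be in (0, 1]")
        if self.domain_size[0] <= 0 or self.domain_size[1] <= 0:
            raise ValueError("domain_size entries must be positive")
        if self.cell_shape not in CELL_SHAPES:
            raise ValueError(
                f"unknown cell_shape {self.cell_shape!r}; "
                f"choose from {sorted(CELL_SHAPES)}"
            )
        if self.boundary not in ("periodic", "reflecting"):
            raise ValueError("boundary must be 'periodic' or 'reflecting'")
        if self.speed_mean < 0 or self.speed_sd < 0:
            raise ValueError("speed parameters must be >= 0")

    @property
    def w_p(self) -> float:
        return 1.0 - self.w_c - self.w_m

    @property
    def n_steps(self) -> int:
        return int(round(self.duration_days * 24 * 60 / self.dt))

    def bead_radii(self) -> np.ndarray:
        return self.bead_radius * np.asarray(CELL_SHAPES[self.cell_shape])

    def bead_offsets(self) -> np.ndarray:
        """Signed offsets of bead centers along the cell axis (head first),
        for a chain of touching beads recentred on the cell midpoint."""
        r = self.bead_radii()
        centers = np.concatenate([[0.0], -np.cumsum(r[:-1] + r[1:])])
        span_front, span_back = centers[0] + r[0], centers[-1] - r[-1]
        return centers - (span_front + span_back) / 2.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["domain_size"] = list(self.domain_size)
        d["grid_shape"] = list(self.grid_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParams":
        d = dict(d)
        for key in ("domain_size", "grid_shape"):
            if key in d:
                d[key] = tuple(d[key])
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)

    def evolve(self, **changes) -> "SimulationParams":
        return replace(self, **changes)


def _preset(eta, wc, wm):
    # In-vivo-mimicking runs: 200 cells (~10% confluence), slower cells and a
    # twice-as-fine fiber grid for more precise fiber positioning.
    return SimulationParams(
        noise_variance=noise_variance_from_eta(eta), w_c=wc, w_m=wm,
        n_cells=200, speed_mean=5.0, speed_sd=1.0, grid_shape=(200, 200),
    )


#: Noise / guidance / feedback triples that mimic matrix observed in mouse
#: tissues (dermis and liver need matrix feedback; stomach is pure cell-cell
#: alignment; spleen is near-independent strands).
TISSUE_PRESETS = {
    "dermis": _preset(0.1, 0.03, 0.4),
    "liver": _preset(0.1, 0.03, 0.8),
    "spleen": _preset(0.01, 0.0, 0.01),
    "stomach": _preset(0.02, 0.03, 0.0),
}
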