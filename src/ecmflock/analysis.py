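"""In-silico experiments: persistence, parameter sweeps, PCA, calibration
and the two-phase matrix-remodeling protocol.

Persistence is the directionality ratio of a migration track: net
displacement over a time window divided by the path length over that window,
in [0, 1].  Sweeps run seeded replicate simulations over parameter grids and
tabulate the five matrix metrics; PCA on the z-scored metrics summarizes the
diversity of emergent patterns.  The calibration routines recover the
per-step noise variance Var(eta) and the matrix-feedback weight w_m from
observed persistence values by least squares against simulated candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.nonparametric.smoothers_lowess import lowess

from .fiber_grid import FiberGrid
from .metrics import MetricConfig, METRIC_NAMES, compute_metric_set, field_from_grid, alignment
from .model import Simulation, initialize
from .params import SimulationParams

__all__ = [
    "persistence",
    "population_persistence",
    "smooth_track",
    "run_sweep",
    "PCASummary",
    "pca_summary",
    "calibrate_noise",
    "calibrate_feedback",
    "RemodelingResult",
    "remodeling_experiment",
    "aligned_substrate",
]


def smooth_track(positions: np.ndarray, span: float = 0.5) -> np.ndarray:
    """Local-regression (lowess) smoothing of a track's x and y against time.

    Smooths intracellular jitter before computing persistence, mirroring how
    measured trajectories are splined before analysis.
    """
    positions = np.asarray(positions, dtype=float)
    t = np.arange(len(positions))
    out = np.column_stack([
        lowess(positions[:, k], t, frac=span, return_sorted=False) for k in (0, 1)
    ])
    return out


def persistence(positions: np.ndarray, T: int, smooth: bool = False,
                span: float = 0.5, literal_denominator: bool = False) -> float:
    """Median directionality ratio of one track over sliding windows of T steps.

    Per window ending at step t: net displacement ``|r(t) - r(t-T)|`` divided
    by the path length ``sum_k |r(t-k+1) - r(t-k)|``.  A window of zero path
    length is scored 1 (a stationary cell is trivially persistent).  With
    ``literal_denominator`` the denominator is ``sum_k |r(t) - r(t-k)|``
    instead (an alternative published form; not a path length).
    """
    positions = np.asarray(positions, dtype=float)
    if len(positions) < T + 1:
        raise ValueError(f"track needs at least T+1 = {T + 1} samples")
    if smooth:
        positions = smooth_track(positions, span)
    steps = np.hypot(*np.diff(positions, axis=0).T)
    ratios = []
    for t in range(T, len(positions)):
        net = np.hypot(*(positions[t] - positions[t - T]))
        if literal_denominator:
            path = sum(np.hypot(*(positions[t] - positions[t - k])) for k in range(1, T + 1))
        else:
            path = steps[t - T:t].sum()
        ratios.append(1.0 if path == 0 else min(net / path, 1.0))
    return float(np.median(ratios))


def population_persistence(tracks: np.ndarray, T: int, **kw) -> float:
    """Mean over cells of per-cell (median-over-windows) persistence.

    ``tracks`` has shape (n_samples, n_cells, 2).
    """
    tracks = np.asarray(tracks, dtype=float)
    return float(np.mean([persistence(tracks[:, i], T, **kw)
                          for i in range(tracks.shape[1])]))


# ---- parameter sweeps -------------------------------------------------------


def _rng_for(base_seed: int, *key: int) -> np.random.Generator:
    """Deterministic substream: replicate k of condition i is independent of
    how many other conditions or replicates are run."""
    return np.random.default_rng(np.random.SeedSequence((base_seed, *key)))


def run_sweep(conditions: Sequence[dict], base_params: SimulationParams,
              reps: int = 3, base_seed: int = 0,
              metric_config: Optional[MetricConfig] = None,
              n_steps: Optional[int] = None) -> pd.DataFrame:
    """Run ``reps`` seeded replicates per condition and tabulate the metrics.

    Each condition is a dict of :class:`SimulationParams` overrides; invalid
    combinations (e.g. ``w_c + w_m > 1``) are skipped with a warning.
    Returns a long-format table with one row per run.
    """
    if not conditions:
        raise ValueError("conditions must be non-empty")
    rows = []
    for ci, cond in enumerate(conditions):
        try:
            params = base_params.evolve(**cond)
        except ValueError as exc:
            warnings.warn(f"skipping condition {cond}: {exc}")
            continue
        for rep in range(reps):
            rng = _rng_for(base_seed, ci, rep)
            sim = initialize(params, rng)
            sim.run(n_steps)
            mset = compute_metric_set(sim.grid, metric_config)
            row = {
                "noise_variance": params.noise_variance,
                "eta": round(float(np.sqrt(params.noise_variance)), 6),
                "w_c": params.w_c,
                "w_m": params.w_m,
                "deposition_rate": params.deposition_rate,
                "degradation_rate": params.degradation_rate,
                "rearrangement_rate": params.rearrangement_rate,
                "n_cells": params.n_cells,
                "rep": rep,
                "seed": base_seed,
            }
            row.update(mset.as_dict())
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class PCASummary:
    """Variance fractions and loadings of a PCA on z-scored metrics."""

    variance_ratio: np.ndarray           # per-component variance fractions
    loadings: pd.DataFrame               # metrics x components
    dropped: list = dc_field(default_factory=list)

    @property
    def first_two_variance_pct(self) -> float:
        return float(100.0 * self.variance_ratio[:2].sum())


def pca_summary(sweep_table: pd.DataFrame, n_components: Optional[int] = None) -> PCASummary:
    """PCA on the z-scored five metrics of a sweep table.

    Rows with missing metrics are dropped; constant metric columns are
    dropped with a warning.  Requires at least three complete rows.
    """
    cols = [c for c in METRIC_NAMES if c in sweep_table.columns]
    data = sweep_table[cols].dropna()
    if len(data) < 3:
        raise ValueError("need at least 3 complete metric rows for PCA")
    keep, dropped = [], []
    for c in cols:
        (dropped if data[c].std(ddof=0) == 0 else keep).append(c)
    if dropped:
        warnings.warn(f"dropping constant metric columns: {dropped}")
    X = (data[keep] - data[keep].mean()) / data[keep].std(ddof=0)
    pca = PCA(n_components=n_components)
    pca.fit(X.to_numpy())
    loadings = pd.DataFrame(
        pca.components_.T, index=keep,
        columns=[f"PC{k + 1}" for k in range(pca.components_.shape[0])],
    )
    return PCASummary(pca.explained_variance_ratio_, loadings, dropped)


# ---- persistence-based calibration -----------------------------------------


def _simulated_persistence(params: SimulationParams, windows, rng,
                           n_record_steps: int = 48, smooth: bool = False,
                           substrate: Optional[FiberGrid] = None):
    sim = initialize(params, rng)
    if substrate is not None:
        sim.grid = substrate.copy()
    tracks = sim.run(n_record_steps, record_tracks=True)
    return np.array([population_persistence(tracks, T, smooth=smooth) for T in windows])


def calibrate_noise(observed_persistence: Sequence[float],
                    candidate_grid: Sequence[float],
                    base_params: Optional[SimulationParams] = None,
                    windows: Sequence[int] = (2, 4),
                    n_cells: int = 20, base_seed: int = 0,
                    smooth: bool = False) -> float:
    """Least-squares estimate of Var(eta) from observed persistence values.

    ``observed_persistence`` holds one value per window (defaults: 2- and
    4-step windows, i.e. one and two hours at dt = 30 min), measured on
    sparse cells moving free of guidance.  Simulations of sub-confluent cells
    with ``w_c = w_m = 0`` are run for each candidate variance and the
    candidate minimizing the squared error is returned.
    """
    observed = np.asarray(observed_persistence, dtype=float)
    base = base_params or SimulationParams()
    errs = []
    for ci, var in enumerate(candidate_grid):
        params = base.evolve(noise_variance=var, w_c=0.0, w_m=0.0, n_cells=n_cells)
        sim_p = _simulated_persistence(params, windows, _rng_for(base_seed, ci),
                                       smooth=smooth)
        errs.append(float(((sim_p - observed) ** 2).sum()))
    return float(candidate_grid[int(np.argmin(errs))])


def aligned_substrate(params: SimulationParams, density: float = 25.0,
                      orientation: float = 0.0) -> FiberGrid:
    """A thick, uniformly aligned fiber grid to seed calibration runs on."""
    grid = FiberGrid(params.grid_shape, params.domain_size, params.n_bins)
    b = int(np.floor((orientation % np.pi) / (np.pi / params.n_bins)))
    grid.bins[:, :, b] = density
    return grid


def calibrate_feedback(observed_persistence: Sequence[float],
                       noise_variance: float,
                       candidate_grid: Sequence[float],
                       substrate: Optional[FiberGrid] = None,
                       base_params: Optional[SimulationParams] = None,
                       windows: Sequence[int] = (2, 4),
                       n_cells: int = 20, base_seed: int = 0) -> float:
    """Least-squares estimate of w_m for cells on a thick aligned matrix.

    As :func:`calibrate_noise`, but the noise variance is fixed and each
    candidate feedback weight is simulated on the given substrate (an
    aligned, saturated grid by default).  Matrix update rates are zeroed so
    the substrate stays fixed during the short calibration runs.
    """
    observed = np.asarray(observed_persistence, dtype=float)
    base = base_params or SimulationParams()
    if substrate is None:
        substrate = aligned_substrate(base)
    errs = []
    for ci, wm in enumerate(candidate_grid):
        params = base.evolve(
            noise_variance=noise_variance, w_c=0.0, w_m=wm, n_cells=n_cells,
            deposition_rate=0.0, degradation_rate=0.0, rearrangement_rate=0.0,
        )
        sim_p = _simulated_persistence(params, windows, _rng_for(base_seed, ci),
                                       substrate=substrate)
        errs.append(float(((sim_p - observed) ** 2).sum()))
    return float(candidate_grid[int(np.argmin(errs))])


# ---- two-phase remodeling experiment ---------------------------------------


@dataclass
class RemodelingResult:
    """Time series and endpoint comparison of a matrix-interconversion run."""

    timeseries: pd.DataFrame   # condition, rep, day, lra
    endpoints: pd.DataFrame    # condition, rep, lra at the final day
    ttest: Optional[dict] = None

    def endpoint_lra(self, condition: str) -> np.ndarray:
        df = self.endpoints
        return df.loc[df["condition"] == condition, "lra"].to_numpy()


def remodeling_experiment(phase1_params: SimulationParams,
                          phase2_conditions: dict,
                          switch_day: float, end_day: float,
                          reps: int = 25, base_seed: int = 0,
                          compare: Optional[tuple] = None,
                          metric_config: Optional[MetricConfig] = None,
                          record_days: float = 1.0) -> RemodelingResult:
    """Two-phase protocol: deposit a matrix, then re-seed altered cells on it.

    Phase 1 runs ``phase1_params`` for ``switch_day`` days; the deposited
    grid is then handed to freshly re-seeded cells under each condition in
    ``phase2_conditions`` (name -> parameter overrides) until ``end_day``.
    Long-range alignment of the matrix is recorded every ``record_days``.
    With ``compare = (name_a, name_b)``, a Welch two-tailed t-test on the
    final-day LRA of the two conditions is attached.
    """
    if not 0 < switch_day < end_day:
        raise ValueError(f"need 0 < switch_day < end_day, got {switch_day}, {end_day}")
    cfg = metric_config or MetricConfig()
    spd = int(round(24 * 60 / phase1_params.dt))  # steps per day
    record_every = max(int(round(record_days * spd)), 1)
    ts_rows, end_rows = [], []

    def grid_lra(grid):
        return alignment(field_from_grid(grid), cfg.lra_length,
                         cfg.max_focal, cfg.alignment_seed)

    for rep in range(reps):
        sim1 = initialize(phase1_params, _rng_for(base_seed, 0, rep))
        history = []
        for k in range(int(round(switch_day * spd))):
            sim1.step()
            if (k + 1) % record_every == 0:
                history.append(((k + 1) / spd, grid_lra(sim1.grid)))
        base_grid = sim1.grid
        for ci, (name, overrides) in enumerate(phase2_conditions.items()):
            params2 = phase1_params.evolve(**overrides)
            sim2 = initialize(params2, _rng_for(base_seed, 1 + ci, rep))
            sim2.grid = base_grid.copy()
            for day, lra_val in history:
                ts_rows.append({"condition": name, "rep": rep, "day": day, "lra": lra_val})
            n2 = int(round((end_day - switch_day) * spd))
            for k in range(n2):
                sim2.step()
                if (k + 1) % record_every == 0 or k == n2 - 1:
                    day = switch_day + (k + 1) / spd
                    ts_rows.append({"condition": name, "rep": rep, "day": day,
                                    "lra": grid_lra(sim2.grid)})
            end_rows.append({"condition": name, "rep": rep,
                             "lra": ts_rows[-1]["lra"]})

    result = RemodelingResult(pd.DataFrame(ts_rows), pd.DataFrame(end_rows))
    if compare is not None:
        a = result.endpoint_lra(compare[0])
        b = result.endpoint_lra(compare[1])
        t, p = stats.ttest_ind(a, b, equal_var=False)
        result.ttest = {"conditions": compare, "t": float(t), "p": float(p),
                        "mean_a": float(a.mean()), "mean_b": float(b.mean())}
    return result
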