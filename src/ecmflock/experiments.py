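"""Canonical in-silico experiment protocols.

These encode the standard parameter grids of the study conditions — the
noise / cell-cell guidance sweep (matrix feedback off), the matrix-feedback
sweep at fixed cell-cell guidance, their combination summarized by PCA, the
sub-confluent variant, and the two-phase dermis remodeling protocol — so the
command-line tools, the test suite and downstream scripts all run exactly
the same conditions.
"""

from __future__ import annotations

from typing import Optional

import pandas as pd

from .analysis import (
    PCASummary,
    RemodelingResult,
    pca_summary,
    remodeling_experiment,
    run_sweep,
)
from .metrics import MetricConfig
from .params import SimulationParams, TISSUE_PRESETS, noise_variance_from_eta

__all__ = [
    "NOISE_GRID",
    "WC_GRID",
    "WM_GRID",
    "guidance_sweep_conditions",
    "feedback_sweep_conditions",
    "combined_sweep_conditions",
    "pattern_diversity_sweep",
    "dermis_remodeling",
]

#: Noise phenotypes eta swept in the study conditions (per-step SDs).
NOISE_GRID = (0.0, 0.07, 0.14, 0.21)
#: Cell-cell guidance weights swept with matrix feedback off.
WC_GRID = (0.0, 0.03, 0.06, 0.1)
#: Matrix-feedback weights swept at fixed cell-cell guidance w_c = 0.03.
WM_GRID = (0.0, 0.04, 0.12, 0.2)


def guidance_sweep_conditions():
    """Noise x cell-cell guidance grid with matrix feedback off."""
    return [
        {"noise_variance": noise_variance_from_eta(eta), "w_c": wc, "w_m": 0.0}
        for wc in WC_GRID for eta in NOISE_GRID
    ]


def feedback_sweep_conditions(w_c: float = 0.03):
    """Noise x matrix-feedback grid at fixed cell-cell guidance."""
    return [
        {"noise_variance": noise_variance_from_eta(eta), "w_c": w_c, "w_m": wm}
        for wm in WM_GRID for eta in NOISE_GRID
    ]


def combined_sweep_conditions():
    """The full diversity exploration: both grids concatenated (32 points)."""
    return guidance_sweep_conditions() + feedback_sweep_conditions()


def pattern_diversity_sweep(base_params: Optional[SimulationParams] = None,
                            reps: int = 3, base_seed: int = 0,
                            metric_config: Optional[MetricConfig] = None,
                            conditions=None) -> tuple[pd.DataFrame, PCASummary]:
    """Run the combined noise / guidance / feedback sweep and summarize the
    five z-scored metrics by PCA.  Returns (sweep table, PCA summary)."""
    base = base_params or SimulationParams()
    table = run_sweep(conditions or combined_sweep_conditions(), base,
                      reps=reps, base_seed=base_seed, metric_config=metric_config)
    return table, pca_summary(table)


def dermis_remodeling(reps: int = 25, base_seed: int = 0,
                      n_cells: Optional[int] = None,
                      conditions: Optional[dict] = None,
                      switch_day: float = 7.0, end_day: float = 17.0,
                      metric_config: Optional[MetricConfig] = None,
                      record_days: float = 1.0) -> RemodelingResult:
    """Two-phase matrix interconversion starting from in-silico dermis.

    Phase 1 deposits a dermal (swirled) matrix for ``switch_day`` days with
    the dermis preset at deposition rate 10 and density-dependent feedback.
    Phase 2 re-seeds zero-noise cells on that matrix under varying feedback
    and remodeling conditions for ten further days (``end_day - switch_day``);
    time in the result is reported relative to the hand-off.  The day-10
    long-range alignment compares remodeling-competent against
    remodeling-incompetent cells at intermediate feedback (Welch two-tailed
    t-test).
    """
    phase1 = TISSUE_PRESETS["dermis"].evolve(density_feedback_enabled=True)
    if n_cells is not None:
        phase1 = phase1.evolve(n_cells=n_cells)
    if conditions is None:
        # phase 2: activated, persistent (zero-noise) fibroblasts depositing
        # heavily (rate 10), with or without degradation/rearrangement
        conditions = {
            "wm0": {"noise_variance": 0.0, "w_m": 0.0, "deposition_rate": 10.0,
                    "degradation_rate": 0.0, "rearrangement_rate": 0.0},
            "wm02_static": {"noise_variance": 0.0, "w_m": 0.2, "deposition_rate": 10.0,
                            "degradation_rate": 0.0, "rearrangement_rate": 0.0},
            "wm02_remodel": {"noise_variance": 0.0, "w_m": 0.2, "deposition_rate": 10.0,
                             "degradation_rate": 5.0, "rearrangement_rate": 5.0},
            "wm04": {"noise_variance": 0.0, "w_m": 0.4, "deposition_rate": 10.0,
                     "degradation_rate": 0.0, "rearrangement_rate": 0.0},
        }
    return remodeling_experiment(
        phase1, conditions, switch_day=switch_day, end_day=end_day,
        reps=reps, base_seed=base_seed,
        compare=("wm02_remodel", "wm02_static")
        if {"wm02_remodel", "wm02_static"} <= set(conditions) else None,
        metric_config=metric_config, record_days=record_days,
    )
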