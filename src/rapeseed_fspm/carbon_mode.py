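"""Carbon-budget columns for the daily simulator output.

Replays the daily simulation, ray-casting the chamber light onto the
plant's blades each day and closing the carbon books, to append the
columns gross_umol, resp_maint_umol, resp_growth_umol, dmass_mg to the
plant_daily table. The mechanistic dry-mass increment is reported
alongside the empirical curves, never fed back into leaf extension
(extension stays thermal-time driven).
"""

from __future__ import annotations

import pandas as pd

from .light_carbon import (
    CarbonBudgetParams,
    ChamberScene,
    LeafPhotosynthesisParams,
    blade_ellipses_from_state,
    daily_carbon_budget,
    default_scene,
    per_leaf_absorbed_par,
)
from .simulator import PhenologyParams, new_plant, step, update_leaf
from .thermal_time import TemperatureRegime


def carbon_columns(
    plant_daily: pd.DataFrame,
    treatment: str,
    n_days: int,
    regime: TemperatureRegime,
    phenology: PhenologyParams | None = None,
    scene: ChamberScene | None = None,
    photo: LeafPhotosynthesisParams | None = None,
    budget: CarbonBudgetParams | None = None,
    n_rays: int = 20_000,
    seed: int = 0,
) -> pd.DataFrame:
    """plant_daily with one carbon budget per simulated day appended.

    Day k's budget uses the plant structure at the end of day k; the day-0
    row carries the budget of the initial structure. Ray seeds derive
    deterministically from ``seed`` and the day index.
    """
    scene = scene or default_scene()
    phen = phenology or PhenologyParams()
    state = new_plant(treatment, phen)
    for p in state.phytomers:
        update_leaf(p, state.ts, treatment, None, phen)

    budgets = []

    def one_day(day: int) -> None:
        leaves = blade_ellipses_from_state(state)
        absorbed = per_leaf_absorbed_par(
            scene, leaves, n_rays=n_rays, seed=seed * 100_003 + day
        )
        budgets.append(daily_carbon_budget(state, absorbed, regime, photo, budget))

    one_day(0)
    for day in range(1, n_days + 1):
        step(state, regime, phen)
        one_day(day)

    out = plant_daily.copy()
    out["gross_umol"] = [b.gross_umol for b in budgets]
    out["resp_maint_umol"] = [b.resp_maint_umol for b in budgets]
    out["resp_growth_umol"] = [b.resp_growth_umol for b in budgets]
    out["dmass_mg"] = [b.dmass_mg for b in budgets]
    return out
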