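"""Nonlinear least-squares fitting of the growth-curve families.

Re-implements the fitting pipeline behind the packaged parameter tables:
normalization of longitudinal series, per-rank blade-extension logistics,
single and piecewise (double) normalized dry-mass logistics, and the
whole-plant leaf-area curve. Also provides the synthetic-series generator
used for parameter-recovery testing, a stand-in for destructive-sampling
measurement campaigns (three plants harvested every 3 days).

Fitting strategy
----------------
All families are fitted with scipy's trust-region-reflective least squares.
Each fit is started from a small deterministic set of initial guesses: the
plain heuristics (y_m a little above the observed maximum, the half-maximum
time, unit slope of either sign) plus linearized estimates obtained by
log/logit-transforming the model at a grid of candidate y_m values, which
turns each family into a linear or quadratic regression. The best final
residual sum of squares wins. There is no random initialization, so fits
are deterministic given the data.

The transition time of the double logistic is treated as a grid-searched
hyperparameter (step 0.01 on normalized time) rather than a free continuous
parameter; each branch is fitted independently on its own side, seeded with
the single-logistic solution so that the piecewise fit can never do worse
than the single fit (model nesting).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .growth import leaf_length, normalized_dry_mass, whole_plant_leaf_area
from .parameters import (
    DenormalizationAnchors,
    DoubleLogisticParams,
    LeafAreaCurveParams,
    LeafExtensionParams,
    NormalizedLogisticParams,
)

__all__ = [
    "ObservationSeries",
    "FitResult",
    "normalize_series",
    "fit_leaf_logistic",
    "fit_normalized_logistic",
    "fit_double_logistic",
    "fit_leaf_area_curve",
    "generate_synthetic_series",
]

_LSQ_KW = dict(method="trf", ftol=1e-15, xtol=1e-15, gtol=1e-15, max_nfev=4000)
_LSQ_SCAN_KW = dict(method="trf", ftol=1e-10, xtol=1e-10, gtol=1e-10, max_nfev=150)


@dataclass(frozen=True)
class ObservationSeries:
    """A longitudinal organ- or plant-level measurement series.

    ``ts`` is accumulated temperature (°Cd, or normalized time in [0, 1]
    for the normalized dry-mass families); ``y`` the measured quantity
    (cm, mg or cm²). ``ts`` must be strictly increasing.
    """

    ts: np.ndarray
    y: np.ndarray
    rank: int | None = None
    treatment: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "ts", np.asarray(self.ts, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if self.ts.shape != self.y.shape or self.ts.ndim != 1:
            raise ValueError("ts and y must be 1-d arrays of equal length")
        if len(self.ts) >= 2 and not np.all(np.diff(self.ts) > 0):
            raise ValueError("ts must be strictly increasing")

    def __len__(self) -> int:
        return len(self.ts)


@dataclass(frozen=True)
class FitResult:
    """Outcome of one least-squares fit."""

    params: object
    rss: float
    converged: bool
    n_obs: int
    message: str = ""


def normalize_series(series: ObservationSeries) -> tuple[ObservationSeries, DenormalizationAnchors]:
    """Normalize both axes by their maxima; anchors invert the mapping."""
    if len(series) < 2:
        raise ValueError("normalization needs at least two observations")
    y_max = float(np.max(series.y))
    ts_max = float(np.max(series.ts))
    if y_max <= 0.0 or ts_max <= 0.0:
        raise ValueError("normalization requires max(y) > 0 and max(ts) > 0")
    normalized = ObservationSeries(
        ts=series.ts / ts_max, y=series.y / y_max,
        rank=series.rank, treatment=series.treatment,
    )
    return normalized, DenormalizationAnchors(y_max=y_max, ts_max=ts_max)


def _run_starts(residual_fn, starts, bounds, fast: bool = False):
    """Run least squares from each start; return best (x, rss, ok).

    All starts are first run with loose, capped settings; the winner is
    polished once at tight tolerances (skipped when ``fast``).
    """
    best_x, best_rss, ok = None, np.inf, False
    for x0 in starts:
        x0 = np.clip(x0, bounds[0], bounds[1])
        if not np.all(np.isfinite(x0)):
            continue
        try:
            res = least_squares(residual_fn, x0, bounds=bounds, **_LSQ_SCAN_KW)
        except Exception:
            continue
        rss = float(2.0 * res.cost)
        if np.isfinite(rss) and rss < best_rss:
            best_x, best_rss, ok = res.x, rss, True
    if ok and not fast:
        try:
            res = least_squares(residual_fn, best_x, bounds=bounds, **_LSQ_KW)
            rss = float(2.0 * res.cost)
            if np.isfinite(rss) and rss <= best_rss:
                best_x, best_rss = res.x, rss
        except Exception:
            pass
    return best_x, best_rss, ok


# ---------------------------------------------------------------------------
# Blade-extension logistic: y = y_m / (1 + (ts/ts_0)^b)


def _leaf_model(ts, ym, ts0, b):
    return ym / (1.0 + np.exp(np.clip(b * np.log(ts / ts0), -700, 700)))


def _leaf_linearized_starts(ts, y) -> list[np.ndarray]:
    """Candidate starts from log-linearizing at a grid of y_m guesses.

    ln(y_m/y - 1) = b ln ts - b ln ts_0 is linear in ln ts.
    """
    starts = []
    ymax = float(np.max(y))
    for mult in (1.001, 1.05, 1.2, 2.0, 5.0):
        ym0 = mult * ymax
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.log(ym0 / y - 1.0)
        mask = np.isfinite(z)
        if mask.sum() < 3:
            continue
        slope, intercept = np.polyfit(np.log(ts[mask]), z[mask], 1)
        if slope == 0.0 or not np.isfinite(slope):
            continue
        ts0 = float(np.exp(-intercept / slope))
        if np.isfinite(ts0) and ts0 > 0:
            starts.append(np.array([ym0, ts0, slope]))
    return starts


def fit_leaf_logistic(series: ObservationSeries) -> FitResult:
    """Fit the per-rank blade-extension logistic.

    Needs at least 4 observations with ts > 0. A constant series cannot
    constrain the curve and is reported as non-converged (degenerate),
    never as an exception.
    """
    ts, y = series.ts, series.y
    if len(series) < 4:
        raise ValueError("fit_leaf_logistic needs at least 4 observations")
    if np.any(ts <= 0):
        raise ValueError("fit_leaf_logistic requires ts > 0")
    if np.ptp(y) == 0.0 or np.max(y) <= 0.0:
        return FitResult(None, float("nan"), False, len(series), "degenerate series")

    def residual(x):
        return _leaf_model(ts, *x) - y

    ymax = float(np.max(y))
    ts_half = float(ts[np.argmin(np.abs(y - ymax / 2.0))])
    starts = [
        np.array([1.05 * ymax, ts_half, -1.0]),
        np.array([1.05 * ymax, ts_half, 1.0]),
        np.array([1.05 * ymax, ts_half, -5.0]),
        np.array([1.05 * ymax, ts_half, 25.0]),
        *_leaf_linearized_starts(ts, y),
    ]
    bounds = (np.array([1e-9, 1e-9, -np.inf]), np.array([np.inf, np.inf, np.inf]))
    x, rss, ok = _run_starts(residual, starts, bounds)
    if not ok:
        return FitResult(None, float("nan"), False, len(series), "no start converged")
    params = LeafExtensionParams(
        rank=series.rank if series.rank is not None else -1,
        treatment=series.treatment or "?",
        y_m=float(x[0]), ts_0=float(x[1]), b=float(x[2]),
    )
    return FitResult(params, rss, True, len(series))


# ---------------------------------------------------------------------------
# Normalized dry-mass logistic: y' = y_m / (1 + exp(a t² + b t + c))


def _norm_model(t, ym, a, b, c):
    return ym / (1.0 + np.exp(np.clip(a * t * t + b * t + c, -700, 700)))


_YM_MULTIPLIERS = (1.001, 1.02, 1.05, 1.2, 2.0, 5.0, 10.0, 20.0, 50.0)


def _norm_linearized_starts(t, y, multipliers=_YM_MULTIPLIERS) -> list[np.ndarray]:
    """Quadratic-regression starts: ln(y_m/y - 1) = a t² + b t + c."""
    starts = []
    ymax = float(np.max(y))
    for mult in multipliers:
        ym0 = mult * ymax
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.log(ym0 / y - 1.0)
        mask = np.isfinite(z)
        if mask.sum() < 4:
            continue
        a0, b0, c0 = np.polyfit(t[mask], z[mask], 2)
        starts.append(np.array([ym0, a0, b0, c0]))
    return starts


def fit_normalized_logistic(series: ObservationSeries) -> FitResult:
    """Fit the single normalized dry-mass logistic (4 free parameters)."""
    t, y = series.ts, series.y
    if len(series) < 5:
        raise ValueError("fit_normalized_logistic needs at least 5 observations")
    if np.ptp(y) == 0.0 or np.max(y) <= 0.0:
        return FitResult(None, float("nan"), False, len(series), "degenerate series")

    def residual(x):
        return _norm_model(t, *x) - y

    starts = [np.array([1.05 * float(np.max(y)), 0.0, -10.0, 5.0]),
              *_norm_linearized_starts(t, y)]
    bounds = (np.array([1e-9, -np.inf, -np.inf, -np.inf]), np.full(4, np.inf))
    x, rss, ok = _run_starts(residual, starts, bounds)
    if not ok:
        return FitResult(None, float("nan"), False, len(series), "no start converged")
    params = NormalizedLogisticParams(y_m=float(x[0]), a=float(x[1]),
                                      b=float(x[2]), c=float(x[3]))
    return FitResult(params, rss, True, len(series))


def _fit_branch(
    t, y, seed_params: NormalizedLogisticParams, fast: bool = False
) -> tuple[NormalizedLogisticParams | None, float]:
    """Fit one branch of the double logistic on its own side.

    Seeded with the full-series single fit (guaranteeing nesting) plus the
    linearized starts on the branch data alone. ``fast`` skips the
    high-precision polish during the transition-point scan.
    """
    def residual(x):
        return _norm_model(t, *x) - y

    starts = [np.array([seed_params.y_m, seed_params.a, seed_params.b, seed_params.c])]
    if np.max(y) > 0 and np.ptp(y) > 0:
        multipliers = (1.001, 1.05, 2.0, 20.0) if fast else _YM_MULTIPLIERS
        starts.extend(_norm_linearized_starts(t, y, multipliers))
    bounds = (np.array([1e-9, -np.inf, -np.inf, -np.inf]), np.full(4, np.inf))
    x, rss, ok = _run_starts(residual, starts, bounds, fast=fast)
    if not ok:
        return None, np.inf
    return NormalizedLogisticParams(*map(float, x)), rss


def fit_double_logistic(series: ObservationSeries, ts_tr_step: float = 0.01) -> FitResult:
    """Fit the piecewise double logistic with a grid-searched transition.

    Candidate transitions run over the interior of the observed normalized
    time at ``ts_tr_step`` resolution; a candidate is admissible when each
    side keeps at least as many observations as the branch's four free
    parameters. Each branch is fitted by least squares on its own side and
    the candidate with the lowest total rss wins.
    """
    t, y = series.ts, series.y
    if len(series) < 9:
        raise ValueError("fit_double_logistic needs at least 9 observations")
    single = fit_normalized_logistic(series)
    if not single.converged:
        return FitResult(None, float("nan"), False, len(series), "degenerate series")

    lo = np.ceil((t[0] + 1e-12) / ts_tr_step) * ts_tr_step
    grid = [
        round(float(c), 10) for c in np.arange(lo, t[-1], ts_tr_step)
        if 0.0 < c < 1.0 and 4 <= (t < c).sum() and 4 <= (t >= c).sum()
    ]

    def scan(candidates, best_tr, best_rss):
        for ts_tr in candidates:
            below = t < ts_tr
            lower, rss_lo = _fit_branch(t[below], y[below], single.params, fast=True)
            upper, rss_hi = _fit_branch(t[~below], y[~below], single.params, fast=True)
            if lower is None or upper is None:
                continue
            if rss_lo + rss_hi < best_rss:
                best_tr, best_rss = float(ts_tr), rss_lo + rss_hi
        return best_tr, best_rss

    # coarse pass over every 5th candidate, then the full-resolution
    # neighborhood of the coarse winner
    best_tr, best_rss = scan(grid[::5], None, np.inf)
    if best_tr is not None:
        near = [c for c in grid if abs(c - best_tr) <= 5.5 * ts_tr_step and c != best_tr]
        best_tr, best_rss = scan(near, best_tr, best_rss)
    if best_tr is None:
        return FitResult(None, float("nan"), False, len(series),
                         "no admissible transition point")
    below = t < best_tr
    lower, rss_lo = _fit_branch(t[below], y[below], single.params)
    upper, rss_hi = _fit_branch(t[~below], y[~below], single.params)
    params = DoubleLogisticParams(lower=lower, upper=upper,
                                  ts_tr=round(best_tr, 10))
    return FitResult(params, min(best_rss, rss_lo + rss_hi), True, len(series))


# ---------------------------------------------------------------------------
# Whole-plant leaf area: LA = LA_0 + LA_max / (1 + exp(-b (ts - TS_m)))


def _area_model(ts, la0, lamax, tsm, b):
    return la0 + lamax / (1.0 + np.exp(np.clip(-b * (ts - tsm), -700, 700)))


def fit_leaf_area_curve(series: ObservationSeries) -> FitResult:
    """Fit the four-parameter whole-plant leaf-area logistic."""
    ts, y = series.ts, series.y
    if len(series) < 5:
        raise ValueError("fit_leaf_area_curve needs at least 5 observations")
    if np.ptp(y) == 0.0:
        return FitResult(None, float("nan"), False, len(series), "degenerate series")

    def residual(x):
        return _area_model(ts, *x) - y

    la0_0 = float(np.min(y))
    rng = float(np.ptp(y))
    tsm_0 = float(ts[np.argmin(np.abs(y - (la0_0 + rng / 2.0)))])
    starts = [np.array([la0_0, rng, tsm_0, 0.02]),
              np.array([la0_0, rng, tsm_0, 0.2])]
    # logit linearization at a grid of plateau guesses
    for mult in (1.001, 1.05, 1.2):
        lamax0 = mult * rng
        u = np.clip((y - la0_0) / lamax0, 1e-9, 1.0 - 1e-9)
        z = np.log(u / (1.0 - u))
        b0, zb = np.polyfit(ts, z, 1)
        if b0 != 0.0 and np.isfinite(b0):
            starts.append(np.array([la0_0, lamax0, -zb / b0, b0]))
    bounds = (np.array([-np.inf, 1e-9, -np.inf, -np.inf]), np.full(4, np.inf))
    x, rss, ok = _run_starts(residual, starts, bounds)
    if not ok:
        return FitResult(None, float("nan"), False, len(series), "no start converged")
    params = LeafAreaCurveParams(
        treatment=series.treatment or "?",
        LA_0=float(x[0]), LA_max=float(x[1]), TS_m=float(x[2]), b=float(x[3]),
    )
    return FitResult(params, rss, True, len(series))


# ---------------------------------------------------------------------------
# Synthetic series


def _evaluate_family(family: str, params, ts: np.ndarray) -> np.ndarray:
    if family == "leaf":
        return np.asarray(leaf_length(ts, params), dtype=float)
    if family == "drymass":
        return np.asarray(normalized_dry_mass(ts, params), dtype=float)
    if family == "drymass2":
        from .growth import double_logistic_dry_mass

        return np.asarray(double_logistic_dry_mass(ts, params), dtype=float)
    if family == "leafarea":
        return np.asarray(whole_plant_leaf_area(ts, params), dtype=float)
    raise ValueError(f"unknown curve family {family!r}")


def generate_synthetic_series(
    family: str,
    true_params,
    ts_grid: Sequence[float],
    noise_sd: float = 0.0,
    seed: int | None = None,
    rank: int | None = None,
    treatment: str | None = None,
) -> ObservationSeries:
    """Sample a growth curve on a grid with additive Gaussian noise.

    Emulates a longitudinal measurement series. Noise is additive Gaussian
    truncated at zero (lengths, masses and areas are non-negative);
    deterministic for a fixed seed. ``family`` is one of ``leaf``,
    ``drymass``, ``drymass2``, ``leafarea``.
    """
    if noise_sd < 0.0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    ts = np.asarray(ts_grid, dtype=float)
    y = _evaluate_family(family, true_params, ts)
    if noise_sd > 0.0:
        rng = np.random.default_rng(seed)
        y = np.maximum(0.0, y + rng.normal(0.0, noise_sd, size=y.shape))
    return ObservationSeries(ts=ts, y=y, rank=rank, treatment=treatment)
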