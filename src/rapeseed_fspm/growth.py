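"""Growth-curve families for blade extension, dry mass and leaf area.

Four empirical families, all functions of accumulated temperature ts (°Cd):

* per-rank blade extension, a three-parameter logistic in ts/ts_0;
* normalized dry mass, a logistic with a quadratic exponent in normalized
  time ts' = ts/ts_max;
* a piecewise "double" variant of the same with distinct branches joined at
  a transition time ts_tr (used where a single sigmoid underfits);
* whole-plant leaf area, a four-parameter logistic with initial offset.

The leaf-area curve is evaluated as LA_0 + LA_max / (1 + exp(-b (ts - TS_m))).
The source tables print the denominator as (ts - TS_m)^(-b), which is
undefined for ts <= TS_m at non-integer b and cannot yield a sigmoid with
b ≈ 0.02 per °Cd; the exponential-argument form matches the stated
exponential/linear/maturation shape and the coefficient units. The raw
printed power form is kept available for comparison.
"""

from __future__ import annotations

import numpy as np

from .parameters import (
    DenormalizationAnchors,
    DoubleLogisticParams,
    LeafAreaCurveParams,
    LeafExtensionParams,
    NormalizedLogisticParams,
)

__all__ = [
    "leaf_length",
    "normalized_dry_mass",
    "double_logistic_dry_mass",
    "branch_discontinuity",
    "dry_mass",
    "whole_plant_leaf_area",
    "leaf_area_raw_power_form",
]

_EXP_CLIP = 700.0  # exp argument clip: stays finite in float64


def _safe_exp(x):
    return np.exp(np.clip(x, -_EXP_CLIP, _EXP_CLIP))


def leaf_length(ts, p: LeafExtensionParams):
    """Blade length (cm) at accumulated temperature ``ts`` (°Cd).

    ``y = y_m / (1 + (ts/ts_0)^b)``. With b < 0 the curve rises sigmoidally
    from 0 toward y_m and equals y_m/2 exactly at ts = ts_0. The power is
    undefined at ts = 0 for negative b, so ts must be strictly positive.
    """
    ts = np.asarray(ts, dtype=float)
    if np.any(ts <= 0.0):
        raise ValueError("leaf_length requires ts > 0 (power undefined at 0)")
    ratio_pow = _safe_exp(p.b * np.log(ts / p.ts_0))
    out = p.y_m / (1.0 + ratio_pow)
    return out if out.ndim else float(out)


def normalized_dry_mass(ts_norm, p: NormalizedLogisticParams):
    """Normalized dry mass y' at normalized time ts' ∈ [0, 1].

    ``y' = y_m / (1 + exp(a ts'² + b ts' + c))``. Values outside [0, 1]
    are extrapolation and are evaluated as printed (no warning raised at
    array granularity; callers guard if needed).
    """
    t = np.asarray(ts_norm, dtype=float)
    out = p.y_m / (1.0 + _safe_exp(p.a * t * t + p.b * t + p.c))
    return out if out.ndim else float(out)


def double_logistic_dry_mass(ts_norm, p: DoubleLogisticParams):
    """Piecewise dry-mass logistic: lower branch strictly below ts_tr.

    Evaluated exactly as printed — no smoothing or continuity adjustment at
    the transition; see :func:`branch_discontinuity` for the jump size.
    """
    t = np.asarray(ts_norm, dtype=float)
    lower = normalized_dry_mass(t, p.lower)
    upper = normalized_dry_mass(t, p.upper)
    out = np.where(t < p.ts_tr, lower, upper)
    return out if out.ndim else float(out)


def branch_discontinuity(p: DoubleLogisticParams) -> float:
    """Jump magnitude |lower(ts_tr⁻) − upper(ts_tr)| of the piecewise curve.

    Both branches are continuous functions, so the left limit equals the
    lower branch evaluated at ts_tr. A diagnostic: the fitted branches are
    not constrained to meet, and any gap is reported rather than hidden.
    """
    return abs(
        float(normalized_dry_mass(p.ts_tr, p.lower))
        - float(normalized_dry_mass(p.ts_tr, p.upper))
    )


def dry_mass(
    ts,
    p: NormalizedLogisticParams | DoubleLogisticParams,
    anchors: DenormalizationAnchors,
):
    """Absolute dry mass (mg) at accumulated temperature ``ts`` (°Cd).

    Normalizes time by ``anchors.ts_max``, evaluates the normalized curve,
    and scales by ``anchors.y_max``.
    """
    t = np.asarray(ts, dtype=float) / anchors.ts_max
    if isinstance(p, DoubleLogisticParams):
        y = double_logistic_dry_mass(t, p)
    else:
        y = normalized_dry_mass(t, p)
    out = np.asarray(y) * anchors.y_max
    return out if out.ndim else float(out)


def whole_plant_leaf_area(ts, p: LeafAreaCurveParams):
    """Whole-plant leaf area (cm²) at accumulated temperature ``ts`` (°Cd).

    ``LA = LA_0 + LA_max / (1 + exp(-b (ts - TS_m)))``; strictly increasing
    for b > 0, bounded in (LA_0, LA_0 + LA_max), midpoint at TS_m.
    """
    ts = np.asarray(ts, dtype=float)
    if np.any(ts < 0.0):
        raise ValueError("whole_plant_leaf_area requires ts >= 0")
    out = p.LA_0 + p.LA_max / (1.0 + _safe_exp(-p.b * (ts - p.TS_m)))
    return out if out.ndim else float(out)


def leaf_area_raw_power_form(ts, p: LeafAreaCurveParams):
    """The leaf-area curve with the denominator as the printed power form.

    ``LA = LA_0 + LA_max / (1 + (ts - TS_m)^(-b))``. Only defined for
    ts > TS_m (negative base with a non-integer exponent otherwise);
    provided for comparison with the adopted exponential form, returns NaN
    where undefined.
    """
    ts = np.asarray(ts, dtype=float)
    with np.errstate(invalid="ignore"):
        base = ts - p.TS_m
        powered = np.where(base > 0.0, base ** (-p.b), np.nan)
    out = p.LA_0 + p.LA_max / (1.0 + powered)
    return out if out.ndim else float(out)
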