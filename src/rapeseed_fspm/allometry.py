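"""Leaf allometry: blade width, petiole length, area and dry mass from rank.

Three rank-dependent descriptors, fitted per temperature treatment:

* WLR — blade width / blade length ratio, linear in rank (narrower with rank);
* PBR — petiole length / blade length ratio, linear in rank (sign of the
  slope differs between treatments);
* LMA — leaf dry mass per blade area (kg m⁻²), exponential in rank for the
  high and medium treatments, constant for the low treatment where no
  significant rank trend exists.

Blade area is modeled as k · length · width with a leaf-ellipse shape factor
k (default 0.7, a typical dicot value); k is configuration-exposed and makes
no claim about the true blade outline.
"""

from __future__ import annotations

import math
import warnings

from .parameters import AllometrySet, ParameterStore, load_default_store

__all__ = ["wlr", "pbr", "lma", "blade_geometry", "leaf_dry_mass"]

#: Measured rank range; linear regressions beyond it are extrapolations.
RANK_GUARD = (1, 8)

#: mg per (cm² · kg m⁻²): 1 kg m⁻² = 0.1 g dm⁻² ... = 100 mg per cm².
_LMA_TO_MG_PER_CM2 = 100.0

_PBR_FLOOR = 1e-6


def _aset(treatment: str | AllometrySet, store: ParameterStore | None) -> AllometrySet:
    if isinstance(treatment, AllometrySet):
        return treatment
    return (store or load_default_store()).allometry(treatment)


def _guard(rank: int) -> None:
    if not RANK_GUARD[0] <= rank <= RANK_GUARD[1]:
        warnings.warn(
            f"rank {rank} outside measured range {RANK_GUARD}; "
            "allometric regressions are extrapolating",
            stacklevel=3,
        )


def wlr(rank: int, treatment: str | AllometrySet, store: ParameterStore | None = None) -> float:
    """Blade width-to-length ratio at a leaf rank (dimensionless)."""
    a = _aset(treatment, store)
    _guard(rank)
    return a.wlr_intercept + a.wlr_slope * rank


def pbr(rank: int, treatment: str | AllometrySet, store: ParameterStore | None = None) -> float:
    """Petiole-to-blade length ratio at a leaf rank (dimensionless).

    Clamped to a small positive value (with a warning) if the linear trend
    extrapolates below zero.
    """
    a = _aset(treatment, store)
    _guard(rank)
    value = a.pbr_intercept + a.pbr_slope * rank
    if value <= 0.0:
        warnings.warn(
            f"PBR regression gives {value:.4f} <= 0 at rank {rank}; clamping",
            stacklevel=2,
        )
        return _PBR_FLOOR
    return value


def lma(rank: int, treatment: str | AllometrySet, store: ParameterStore | None = None) -> float:
    """Leaf mass per area (kg m⁻²) at a leaf rank.

    Exponential in rank (coeff · e^(exp · rank)) for treatments with a
    significant rank trend; otherwise the treatment-mean constant.
    """
    a = _aset(treatment, store)
    if a.lma_const is not None:
        return a.lma_const
    return a.lma_coeff * math.exp(a.lma_exp * rank)


def blade_geometry(
    length: float,
    rank: int,
    treatment: str | AllometrySet,
    store: ParameterStore | None = None,
) -> tuple[float, float, float]:
    """(width cm, petiole length cm, blade area cm²) from blade length.

    width = length·WLR; petiole = length·PBR; area = k·length·width.
    """
    if length < 0.0:
        raise ValueError(f"blade length must be >= 0, got {length}")
    a = _aset(treatment, store)
    width = length * wlr(rank, a)
    petiole = length * pbr(rank, a)
    area = a.shape_factor * length * width
    return width, petiole, area


def leaf_dry_mass(
    area: float,
    rank: int,
    treatment: str | AllometrySet,
    store: ParameterStore | None = None,
) -> float:
    """Blade dry mass (mg) from blade area (cm²) via LMA.

    mass_mg = area_cm² · LMA_kg_m⁻² · 100 (unit conversion).
    """
    if area < 0.0:
        raise ValueError(f"blade area must be >= 0, got {area}")
    return area * lma(rank, _aset(treatment, store)) * _LMA_TO_MG_PER_CM2
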