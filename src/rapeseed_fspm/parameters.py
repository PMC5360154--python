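"""Packaged parameter store: growth-curve and allometry coefficients.

All coefficients ship as a plain-text CSV (``data/parameters.csv``) with
columns ``table_id, treatment, rank, parameter, value`` and are exposed here
as typed records keyed by treatment (H / M / L) and, where applicable, leaf
rank. The loader validates completeness and the store serializes back to the
identical table (round-trip fidelity is part of the test suite).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources
from typing import Iterator

import pandas as pd

__all__ = [
    "LeafExtensionParams",
    "NormalizedLogisticParams",
    "DoubleLogisticParams",
    "DenormalizationAnchors",
    "LeafAreaCurveParams",
    "AllometrySet",
    "ParameterStore",
    "load_default_store",
]

TREATMENTS = ("H", "M", "L")


class MissingParameterError(KeyError):
    """Raised when no packaged parameters exist for a rank/treatment."""


@dataclass(frozen=True)
class LeafExtensionParams:
    """Per-rank blade-extension logistic: y = y_m / (1 + (ts/ts_0)^b)."""

    rank: int
    treatment: str
    y_m: float  # maximum blade length, cm
    ts_0: float  # accumulated temperature at maximal extension rate, °Cd
    b: float  # slope exponent (negative for a rising sigmoid)


@dataclass(frozen=True)
class NormalizedLogisticParams:
    """Normalized dry-mass logistic: y' = y_m / (1 + exp(a ts'² + b ts' + c))."""

    y_m: float
    a: float
    b: float
    c: float


@dataclass(frozen=True)
class DoubleLogisticParams:
    """Piecewise dry-mass logistic: lower branch below ts_tr, upper at/above."""

    lower: NormalizedLogisticParams
    upper: NormalizedLogisticParams
    ts_tr: float  # normalized transition accumulated temperature, in (0, 1)

    def __post_init__(self) -> None:
        if not 0.0 < self.ts_tr < 1.0:
            raise ValueError(f"ts_tr must lie in (0, 1), got {self.ts_tr}")


@dataclass(frozen=True)
class DenormalizationAnchors:
    """Scale anchors mapping normalized curves back to absolute units."""

    y_max: float  # absolute dry mass at series end, mg
    ts_max: float  # accumulated temperature at series end, °Cd

    def __post_init__(self) -> None:
        if self.y_max <= 0 or self.ts_max <= 0:
            raise ValueError("denormalization anchors must be positive")


@dataclass(frozen=True)
class LeafAreaCurveParams:
    """Whole-plant leaf-area logistic parameters."""

    treatment: str
    LA_0: float  # initial leaf area, cm²
    LA_max: float  # maximum (additional) leaf area, cm²
    TS_m: float  # accumulated temperature at maximal expansion rate, °Cd
    b: float  # slope, per °Cd


@dataclass(frozen=True)
class AllometrySet:
    """Rank-dependent leaf-shape regressions for one treatment.

    WLR and PBR are linear in rank; LMA is exponential in rank for H and M
    and a constant for L (where the rank trend was not significant).
    Exactly one of (lma_coeff, lma_exp) or lma_const is set.
    """

    treatment: str
    wlr_slope: float
    wlr_intercept: float
    pbr_slope: float
    pbr_intercept: float
    lma_coeff: float | None = None  # kg m⁻²
    lma_exp: float | None = None  # per rank
    lma_const: float | None = None  # kg m⁻²
    shape_factor: float = 0.7  # blade area = k · length · width

    def __post_init__(self) -> None:
        has_exp = self.lma_coeff is not None and self.lma_exp is not None
        has_const = self.lma_const is not None
        if has_exp == has_const:
            raise ValueError(
                "exactly one of (lma_coeff, lma_exp) or lma_const must be set"
            )


def _read_packaged_csv() -> pd.DataFrame:
    text = resources.files("rapeseed_fspm").joinpath("data/parameters.csv").read_text()
    return pd.read_csv(io.StringIO(text), comment="#", dtype={"value": float})


class ParameterStore:
    """Typed access to the packaged coefficient tables.

    Parameters
    ----------
    frame : pandas.DataFrame
        Long-format table with columns table_id, treatment, rank,
        parameter, value. Defaults to the packaged store.
    """

    def __init__(self, frame: pd.DataFrame | None = None) -> None:
        self._frame = (_read_packaged_csv() if frame is None else frame.copy())
        self._validate()

    # -- access -----------------------------------------------------------

    def leaf_extension(self, rank: int, treatment: str) -> LeafExtensionParams:
        rows = self._select("leaf_extension", treatment, rank)
        if rows.empty:
            raise MissingParameterError(
                f"no blade-extension parameters for rank {rank}, treatment {treatment!r}"
            )
        d = dict(zip(rows["parameter"], rows["value"]))
        return LeafExtensionParams(
            rank=rank, treatment=treatment, y_m=d["y_m"], ts_0=d["ts_0"], b=d["b"]
        )

    def leaf_extension_ranks(self, treatment: str) -> list[int]:
        """Ranks with packaged blade-extension parameters, ascending."""
        rows = self._frame[
            (self._frame["table_id"] == "leaf_extension")
            & (self._frame["treatment"] == treatment)
        ]
        if rows.empty:
            raise MissingParameterError(f"unknown treatment {treatment!r}")
        return sorted(int(r) for r in rows["rank"].unique())

    def dry_mass_plant(self, treatment: str) -> DoubleLogisticParams:
        rows = self._select("drymass_plant", treatment, None)
        d = dict(zip(rows["parameter"], rows["value"]))
        return DoubleLogisticParams(
            lower=NormalizedLogisticParams(d["y_m_l"], d["a_l"], d["b_l"], d["c_l"]),
            upper=NormalizedLogisticParams(d["y_m_h"], d["a_h"], d["b_h"], d["c_h"]),
            ts_tr=d["ts_tr"],
        )

    def dry_mass_rank(
        self, rank: int, treatment: str
    ) -> NormalizedLogisticParams | DoubleLogisticParams:
        """Per-rank dry-mass curve; H rank 3 is the one double-logistic case."""
        rows = self._select("drymass_rank", treatment, rank)
        if rows.empty:
            raise MissingParameterError(
                f"no per-rank dry-mass parameters for rank {rank}, treatment {treatment!r}"
            )
        d = dict(zip(rows["parameter"], rows["value"]))
        lower = NormalizedLogisticParams(d["y_m"], d["a"], d["b"], d["c"])
        if "ts_tr" in d:
            upper = NormalizedLogisticParams(d["y_m_h"], d["a_h"], d["b_h"], d["c_h"])
            return DoubleLogisticParams(lower=lower, upper=upper, ts_tr=d["ts_tr"])
        return lower

    def dry_mass_ranks(self, treatment: str) -> list[int]:
        rows = self._frame[
            (self._frame["table_id"] == "drymass_rank")
            & (self._frame["treatment"] == treatment)
        ]
        return sorted(int(r) for r in rows["rank"].unique())

    def leaf_area(self, treatment: str) -> LeafAreaCurveParams:
        rows = self._select("leaf_area", treatment, None)
        d = dict(zip(rows["parameter"], rows["value"]))
        return LeafAreaCurveParams(
            treatment=treatment,
            LA_0=d["LA_0"],
            LA_max=d["LA_max"],
            TS_m=d["TS_m"],
            b=d["b"],
        )

    def allometry(self, treatment: str, shape_factor: float = 0.7) -> AllometrySet:
        wlr = dict(
            zip(*(self._select("wlr", treatment, None)[c] for c in ("parameter", "value")))
        )
        pbr = dict(
            zip(*(self._select("pbr", treatment, None)[c] for c in ("parameter", "value")))
        )
        lma = dict(
            zip(*(self._select("lma", treatment, None)[c] for c in ("parameter", "value")))
        )
        return AllometrySet(
            treatment=treatment,
            wlr_slope=wlr["slope"],
            wlr_intercept=wlr["intercept"],
            pbr_slope=pbr["slope"],
            pbr_intercept=pbr["intercept"],
            lma_coeff=lma.get("coeff"),
            lma_exp=lma.get("exp"),
            lma_const=lma.get("const"),
            shape_factor=shape_factor,
        )

    # -- round trip -------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """The store as the long-format table it was loaded from."""
        return self._frame.copy()

    def __iter__(self) -> Iterator[tuple]:
        return iter(self._frame.itertuples(index=False))

    # -- internals --------------------------------------------------------

    def _select(self, table_id: str, treatment: str, rank: int | None) -> pd.DataFrame:
        if treatment not in TREATMENTS:
            raise MissingParameterError(f"unknown treatment {treatment!r}")
        mask = (self._frame["table_id"] == table_id) & (
            self._frame["treatment"] == treatment
        )
        if rank is None:
            mask &= self._frame["rank"].isna()
        else:
            mask &= self._frame["rank"] == rank
        return self._frame[mask]

    def _validate(self) -> None:
        required = {"table_id", "treatment", "rank", "parameter", "value"}
        missing = required - set(self._frame.columns)
        if missing:
            raise ValueError(f"parameter store missing columns: {sorted(missing)}")
        for treatment in TREATMENTS:
            for table_id in ("drymass_plant", "leaf_area", "wlr", "pbr", "lma"):
                if self._select(table_id, treatment, None).empty:
                    raise ValueError(
                        f"parameter store incomplete: no {table_id} rows for {treatment}"
                    )
            if not self.leaf_extension_ranks(treatment):
                raise ValueError(
                    f"parameter store incomplete: no leaf_extension rows for {treatment}"
                )


_DEFAULT: ParameterStore | None = None


def load_default_store() -> ParameterStore:
    """The packaged parameter store (cached singleton)."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = ParameterStore()
    return _DEFAULT
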