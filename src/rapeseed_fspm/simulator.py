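"""Daily plant simulator: organogenesis, leaf extension, geometry, totals.

The plant is an ordered list of phytomers (one leaf with its petiole per
phytomer) on a single main stem. Development is driven entirely by
accumulated temperature since transfer into the growth chamber:

* a new leaf appears every phyllochron (75 °Cd by default);
* each blade extends along its rank's logistic curve, read through a
  running-maximum wrapper so lengths never shrink even where the raw fitted
  curve is non-monotone;
* blade width, petiole length, area and dry mass follow the allometric
  regressions for the treatment.

Whole-plant totals are reported two ways: "geometric" totals sum the
per-leaf allometric areas and masses; "empirical" mode additionally reports
the directly fitted whole-plant leaf-area and dry-mass curves. The two are
deliberately not forced to agree — they are independent empirical
descriptions of the same plants — and their ratio is a useful diagnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import allometry as allo
from .growth import dry_mass, leaf_length, whole_plant_leaf_area
from .parameters import (
    DenormalizationAnchors,
    MissingParameterError,
    ParameterStore,
    load_default_store,
)
from .thermal_time import PRESETS, TemperatureRegime, daily_increment

logger = logging.getLogger(__name__)

__all__ = [
    "PhenologyParams",
    "Phytomer",
    "PlantState",
    "initiate_leaves",
    "update_leaf",
    "step",
    "run",
    "export_structure",
]

#: Evaluation epsilon for ts = 0 (the extension logistic needs ts > 0).
_TS_EPS = 1e-6

#: Golden-angle spiral phyllotaxis (visualization plumbing only).
_AZIMUTH_STEP = 137.5


@dataclass(frozen=True)
class PhenologyParams:
    """Organogenesis parameters.

    phyllochron : °Cd between successive leaf appearances (default 75).
    initial_leaf_count : visible leaves at transfer (default 1).
    """

    phyllochron: float = 75.0
    initial_leaf_count: int = 1

    def __post_init__(self) -> None:
        if self.phyllochron <= 0:
            raise ValueError("phyllochron must be > 0")
        if self.initial_leaf_count < 0:
            raise ValueError("initial_leaf_count must be >= 0")


@dataclass
class Phytomer:
    """One leaf (blade + petiole) on the main stem."""

    rank: int
    ts_init: float  # accumulated temperature at initiation, °Cd
    azimuth: float  # degrees, spiral phyllotaxis
    blade_length: float = 0.0  # cm, non-decreasing over a run
    blade_width: float = 0.0  # cm
    petiole_length: float = 0.0  # cm
    blade_area: float = 0.0  # cm²
    dry_mass: float = 0.0  # mg


@dataclass
class PlantState:
    """Whole-plant state: phytomers ordered by rank plus aggregates."""

    treatment: str
    phytomers: list[Phytomer] = field(default_factory=list)
    ts: float = 0.0
    day: int = 0

    @property
    def n_leaves(self) -> int:
        return len(self.phytomers)

    @property
    def total_area(self) -> float:
        return sum(p.blade_area for p in self.phytomers)

    @property
    def total_mass(self) -> float:
        return sum(p.dry_mass for p in self.phytomers)


def new_plant(treatment: str, phenology: PhenologyParams | None = None) -> PlantState:
    """A plant at transfer: ``initial_leaf_count`` leaves, ts = 0."""
    phen = phenology or PhenologyParams()
    state = PlantState(treatment=treatment)
    for i in range(phen.initial_leaf_count):
        state.phytomers.append(
            Phytomer(rank=i + 1, ts_init=0.0, azimuth=(i * _AZIMUTH_STEP) % 360.0)
        )
    return state


def initiate_leaves(state: PlantState, ts_new: float,
                    phenology: PhenologyParams | None = None) -> PlantState:
    """Append one phytomer per phyllochron multiple crossed in (ts, ts_new].

    Leaf count therefore satisfies
    ``initial_leaf_count + floor(ts / phyllochron)`` exactly.
    """
    phen = phenology or PhenologyParams()
    if ts_new < state.ts:
        raise ValueError("ts_new must be >= current ts")
    target = phen.initial_leaf_count + int(np.floor(ts_new / phen.phyllochron + 1e-12))
    while state.n_leaves < target:
        rank = state.n_leaves + 1
        state.phytomers.append(
            Phytomer(
                rank=rank,
                ts_init=(rank - phen.initial_leaf_count) * phen.phyllochron,
                azimuth=((rank - 1) * _AZIMUTH_STEP) % 360.0,
            )
        )
    state.ts = ts_new
    return state


def _extension_params(rank: int, treatment: str, store: ParameterStore,
                      phenology: PhenologyParams):
    """Rank's extension curve, or the highest parameterized rank's, shifted.

    Ranks beyond the packaged table reuse the highest parameterized rank's
    curve, evaluated at a time shifted back by the difference in initiation
    thermal time. The fallback is logged once per rank/treatment.
    """
    ranks = store.leaf_extension_ranks(treatment)
    if rank in ranks:
        return store.leaf_extension(rank, treatment), 0.0
    r_max = max(ranks)
    shift = (rank - r_max) * phenology.phyllochron
    logger.info(
        "rank %d (%s) has no packaged extension parameters; reusing rank %d "
        "shifted by %.1f °Cd", rank, treatment, r_max, shift,
    )
    return store.leaf_extension(r_max, treatment), shift


def update_leaf(
    phytomer: Phytomer,
    ts: float,
    treatment: str,
    store: ParameterStore | None = None,
    phenology: PhenologyParams | None = None,
) -> Phytomer:
    """Update one phytomer's blade length, geometry and mass at ``ts``.

    Blade length is the running maximum of the rank's extension logistic
    (monotone wrapper: the raw curve decays for the ranks whose fitted slope
    came out positive, but a real blade never shrinks). Width, petiole,
    area and mass follow from the allometric regressions.
    """
    store = store or load_default_store()
    phen = phenology or PhenologyParams()
    params, shift = _extension_params(phytomer.rank, treatment, store, phen)
    ts_eff = max(ts - shift, _TS_EPS)
    raw = float(leaf_length(ts_eff, params))
    phytomer.blade_length = max(phytomer.blade_length, raw)
    width, petiole, area = allo.blade_geometry(
        phytomer.blade_length, phytomer.rank, treatment, store
    )
    phytomer.blade_width = width
    phytomer.petiole_length = petiole
    phytomer.blade_area = area
    phytomer.dry_mass = allo.leaf_dry_mass(area, phytomer.rank, treatment, store)
    return phytomer


def step(
    state: PlantState,
    regime: TemperatureRegime,
    phenology: PhenologyParams | None = None,
    store: ParameterStore | None = None,
) -> PlantState:
    """Advance the plant by one day under ``regime`` (in place)."""
    phen = phenology or PhenologyParams()
    ts_new = state.ts + daily_increment(regime)
    initiate_leaves(state, ts_new, phen)
    for phytomer in state.phytomers:
        update_leaf(phytomer, state.ts, state.treatment, store, phen)
    state.day += 1
    return state


def _leaf_rows(state: PlantState) -> list[dict]:
    return [
        dict(
            day=state.day, rank=p.rank, length_cm=p.blade_length,
            width_cm=p.blade_width, petiole_cm=p.petiole_length,
            area_cm2=p.blade_area, mass_mg=p.dry_mass,
        )
        for p in state.phytomers
    ]


def run(
    treatment: str,
    n_days: int,
    mode: str = "geometric",
    regime: TemperatureRegime | None = None,
    phenology: PhenologyParams | None = None,
    store: ParameterStore | None = None,
    anchors: DenormalizationAnchors | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate ``n_days`` days; return (plant_daily, leaves_daily) tables.

    ``mode`` is ``geometric`` (totals summed from per-leaf allometry) or
    ``empirical`` (adds the fitted whole-plant leaf-area and dry-mass
    curves as extra columns). Per-leaf lengths are always emitted. The
    empirical dry mass is normalized (y_max = 1) unless ``anchors`` carry
    an absolute end-of-series mass; the default time anchor is the 30-day
    accumulated temperature of the treatment.
    """
    if treatment not in PRESETS:
        raise ValueError(f"unknown treatment {treatment!r}; expected one of H, M, L")
    if mode not in ("geometric", "empirical"):
        raise ValueError(f"unknown mode {mode!r}")
    if n_days < 0:
        raise ValueError("n_days must be >= 0")
    regime = regime or PRESETS[treatment]
    phen = phenology or PhenologyParams()
    store = store or load_default_store()

    if anchors is None:
        anchors = DenormalizationAnchors(
            y_max=1.0, ts_max=30.0 * daily_increment(regime)
        )

    state = new_plant(treatment, phen)
    for p in state.phytomers:  # day-0 geometry at ts = epsilon
        update_leaf(p, state.ts, treatment, store, phen)

    plant_rows, leaf_rows = [], []

    def record() -> None:
        row = dict(
            day=state.day, ts=state.ts, n_leaves=state.n_leaves,
            total_area_cm2=state.total_area, total_mass_mg=state.total_mass,
        )
        if mode == "empirical":
            row["empirical_area_cm2"] = float(
                whole_plant_leaf_area(state.ts, store.leaf_area(treatment))
            )
            row["empirical_mass"] = float(
                dry_mass(state.ts, store.dry_mass_plant(treatment), anchors)
            )
        plant_rows.append(row)
        leaf_rows.extend(_leaf_rows(state))

    record()
    for _ in range(n_days):
        step(state, regime, phen, store)
        record()

    plant_daily = pd.DataFrame(plant_rows)
    leaves_daily = pd.DataFrame(leaf_rows)
    if mode == "empirical" and n_days > 0:
        ratio = (
            plant_daily["total_area_cm2"].iloc[-1]
            / max(plant_daily["empirical_area_cm2"].iloc[-1], 1e-12)
        )
        logger.info("geometric/empirical final leaf-area ratio (%s): %.3f",
                    treatment, ratio)
    return plant_daily, leaves_daily


# ---------------------------------------------------------------------------
# 3D structure export


def export_structure(
    state: PlantState,
    elevation_base: float = 60.0,
    elevation_step: float = -5.0,
    internode_cm: float = 0.5,
    obj_path: str | None = None,
) -> pd.DataFrame:
    """Per-phytomer 3D layout table, optionally written as an OBJ mesh.

    Visualization plumbing with no physiological claim: each petiole is a
    line segment leaving the stem at its azimuth (golden-angle spiral) and
    an elevation of ``elevation_base + elevation_step·(rank-1)`` degrees;
    the blade is a planar ellipse of the phytomer's length × width attached
    at the petiole tip. Returns a table of positions; writes a triangulated
    mesh via trimesh when ``obj_path`` is given.
    """
    rows = []
    meshes = []
    for p in state.phytomers:
        az = np.deg2rad(p.azimuth)
        el = np.deg2rad(elevation_base + elevation_step * (p.rank - 1))
        direction = np.array(
            [np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)]
        )
        base = np.array([0.0, 0.0, internode_cm * (p.rank - 1)])
        petiole_tip = base + direction * p.petiole_length
        blade_center = petiole_tip + direction * (p.blade_length / 2.0)
        tip = petiole_tip + direction * p.blade_length
        rows.append(
            dict(
                rank=p.rank, azimuth_deg=p.azimuth,
                elevation_deg=np.rad2deg(el),
                base_x=base[0], base_y=base[1], base_z=base[2],
                petiole_tip_x=petiole_tip[0], petiole_tip_y=petiole_tip[1],
                petiole_tip_z=petiole_tip[2],
                blade_tip_x=tip[0], blade_tip_y=tip[1], blade_tip_z=tip[2],
                tip_radial_cm=float(np.hypot(tip[0], tip[1])),
                length_cm=p.blade_length, width_cm=p.blade_width,
            )
        )
        if obj_path is not None and p.blade_length > 0:
            meshes.append(
                _blade_ellipse_mesh(blade_center, direction, az,
                                    p.blade_length, p.blade_width)
            )
    table = pd.DataFrame(rows)
    if obj_path is not None:
        import trimesh

        scene = (
            trimesh.util.concatenate(meshes)
            if meshes
            else trimesh.Trimesh(vertices=np.zeros((0, 3)), faces=np.zeros((0, 3), dtype=int))
        )
        scene.export(obj_path)
    return table


def _blade_ellipse_mesh(center, direction, azimuth_rad, length, width, n=16):
    """Triangulated planar ellipse for one blade."""
    import trimesh

    major = direction / np.linalg.norm(direction)
    # minor axis horizontal, perpendicular to the azimuth direction
    minor = np.array([-np.sin(azimuth_rad), np.cos(azimuth_rad), 0.0])
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    ring = (
        center[None, :]
        + np.outer(np.cos(theta) * length / 2.0, major)
        + np.outer(np.sin(theta) * width / 2.0, minor)
    )
    vertices = np.vstack([center[None, :], ring])
    faces = [[0, 1 + i, 1 + (i + 1) % n] for i in range(n)]
    return trimesh.Trimesh(vertices=vertices, faces=np.asarray(faces))
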