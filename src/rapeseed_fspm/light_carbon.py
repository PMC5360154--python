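"""Chamber light interception and a simplified C3 leaf carbon budget.

The growth chamber is reconstructed as a box with three luminous walls
(two lateral, one back) standing in for the 39 wall-mounted fluorescent
tubes of the real cabinet, with a configurable total source output
(330 μmol m⁻² s⁻¹ by default, split equally). Sensor PPFD is estimated by
Monte-Carlo integration of the view factors from cosine-emitting wall
panels, plus a uniform diffuse ambient term for light recycled by the
reflective chamber interior (integrating-sphere approximation,
``E_amb = ρ/(1-ρ) · Φ_total / A_interior``). The wall reflectance default
(0.63) is the single calibration constant, chosen once so that the two
default sensors average the measured 150 μmol m⁻² s⁻¹ when the walls total
330; everything is configuration-exposed.

Leaf-level photosynthesis is a standard C3 biochemical model: the minimum
of the Rubisco-limited and the light (electron-transport)-limited
carboxylation rate minus dark respiration, with Arrhenius temperature
responses, a fixed intercellular-to-ambient CO₂ ratio, and leaf
temperature equal to air temperature (no energy balance, no stomatal
conductance coupling). The daily carbon budget converts gross assimilation
minus maintenance and growth respiration into a dry-mass increment on a
CH₂O basis; the books balance to machine precision by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .simulator import PlantState
from .thermal_time import TemperatureRegime

__all__ = [
    "Panel",
    "ChamberScene",
    "LeafEllipse",
    "LeafPhotosynthesisParams",
    "CarbonBudgetParams",
    "CarbonBudget",
    "default_scene",
    "estimate_sensor_ppfd",
    "blade_ellipses_from_state",
    "per_leaf_absorbed_par",
    "net_assimilation",
    "daily_carbon_budget",
]

R_GAS = 8.314  # J mol⁻¹ K⁻¹
T_REF = 298.15  # K
UG_CH2O_PER_UMOL_CO2 = 30.0  # μg CH₂O fixed per μmol CO₂


@dataclass(frozen=True)
class Panel:
    """Rectangular diffuse (cosine) area emitter.

    Defined by an origin corner and two edge vectors (m); the normal is
    ``unit(u × v)`` and must point into the chamber. ``exitance`` is the
    emitted flux density, μmol m⁻² s⁻¹.
    """

    origin: tuple[float, float, float]
    u: tuple[float, float, float]
    v: tuple[float, float, float]
    exitance: float

    @property
    def area(self) -> float:
        return float(np.linalg.norm(np.cross(self.u, self.v)))

    @property
    def normal(self) -> np.ndarray:
        n = np.cross(self.u, self.v)
        return n / np.linalg.norm(n)

    @property
    def power(self) -> float:
        """Total emitted flux, μmol s⁻¹."""
        return self.exitance * self.area


@dataclass(frozen=True)
class ChamberScene:
    """Growth-chamber light scene: box, wall emitters, virtual sensors."""

    box: tuple[float, float, float] = (1.0, 0.6, 1.5)  # W × D × H, m
    panels: tuple[Panel, ...] = ()
    sensors: tuple[tuple[float, float, float], ...] = ()
    wall_reflectance: float = 0.63  # calibrated diffuse cavity reflectance

    def __post_init__(self) -> None:
        for s in self.sensors:
            if not all(0.0 <= s[i] <= self.box[i] for i in range(3)):
                raise ValueError(f"sensor {s} lies outside the chamber box")

    @property
    def total_output(self) -> float:
        """Summed panel exitance, μmol m⁻² s⁻¹."""
        return sum(p.exitance for p in self.panels)

    @property
    def total_power(self) -> float:
        """Summed emitted flux, μmol s⁻¹."""
        return sum(p.power for p in self.panels)

    @property
    def interior_area(self) -> float:
        w, d, h = self.box
        return 2.0 * (w * d + w * h + d * h)

    @property
    def ambient_ppfd(self) -> float:
        """Uniform diffuse irradiance from the reflective cavity walls."""
        rho = self.wall_reflectance
        if rho <= 0.0:
            return 0.0
        return rho / (1.0 - rho) * self.total_power / self.interior_area


def default_scene(total_output: float = 330.0) -> ChamberScene:
    """The calibrated default chamber: three luminous walls, two sensors.

    ``total_output`` is split equally between the two lateral walls and the
    back wall; the two horizontal upward-facing sensors sit above the two
    shelves. With the default 330 the sensors average 150 μmol m⁻² s⁻¹.
    """
    w, d, h = 1.0, 0.6, 1.5
    m = total_output / 3.0
    panels = (
        Panel(origin=(0.0, 0.0, 0.0), u=(0.0, d, 0.0), v=(0.0, 0.0, h), exitance=m),
        Panel(origin=(w, 0.0, 0.0), u=(0.0, 0.0, h), v=(0.0, d, 0.0), exitance=m),
        Panel(origin=(0.0, d, 0.0), u=(w, 0.0, 0.0), v=(0.0, 0.0, h), exitance=m),
    )
    sensors = ((w / 2.0, d / 2.0, 0.40), (w / 2.0, d / 2.0, 1.10))
    return ChamberScene(box=(w, d, h), panels=panels, sensors=sensors)


def estimate_sensor_ppfd(
    scene: ChamberScene, n_rays: int = 100_000, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo PPFD at each sensor, with standard errors.

    For each horizontal upward-facing sensor the direct irradiance from
    each cosine-emitting panel is the view-factor integral
    ``E = M ∫ cosθ_s cosθ_e / (π r²) dA``, estimated by uniform sampling
    of panel points (``n_rays`` split across panels by area); the diffuse
    ambient term of the scene is added. Returns (ppfd, standard_error)
    arrays of length ``len(scene.sensors)``.
    """
    if not scene.sensors:
        raise ValueError("scene has no sensors")
    rng = np.random.default_rng(seed)
    areas = np.array([p.area for p in scene.panels])
    if len(scene.panels) == 0 or areas.sum() == 0.0:
        z = np.zeros(len(scene.sensors))
        return z + scene.ambient_ppfd, z
    n_per = np.maximum((n_rays * areas / areas.sum()).astype(int), 1)

    means = np.zeros(len(scene.sensors))
    variances = np.zeros(len(scene.sensors))
    for panel, n in zip(scene.panels, n_per):
        origin = np.asarray(panel.origin)
        u = np.asarray(panel.u)
        v = np.asarray(panel.v)
        pts = origin + rng.random((n, 1)) * u + rng.random((n, 1)) * v
        for i, sensor in enumerate(scene.sensors):
            dvec = pts - np.asarray(sensor)
            r2 = np.einsum("ij,ij->i", dvec, dvec)
            r = np.sqrt(r2)
            cos_s = np.clip(dvec[:, 2] / r, 0.0, None)  # sensor faces up
            cos_e = np.clip(-(dvec @ panel.normal) / r, 0.0, None)
            samples = panel.exitance * panel.area * cos_s * cos_e / (np.pi * r2)
            means[i] += samples.mean()
            variances[i] += samples.var(ddof=1) / n
    return means + scene.ambient_ppfd, np.sqrt(variances)


# ---------------------------------------------------------------------------
# Per-leaf absorbed PAR


@dataclass(frozen=True)
class LeafEllipse:
    """A blade as a planar ellipse in chamber coordinates (m)."""

    rank: int
    center: tuple[float, float, float]
    major_axis: tuple[float, float, float]  # unit vector along blade length
    semi_major: float  # m
    semi_minor: float  # m
    absorptance: float = 0.85

    @property
    def normal(self) -> np.ndarray:
        major = np.asarray(self.major_axis, dtype=float)
        horiz = np.array([-major[1], major[0], 0.0])
        nh = np.linalg.norm(horiz)
        if nh < 1e-12:  # blade pointing straight up: any horizontal minor axis
            horiz = np.array([1.0, 0.0, 0.0])
            nh = 1.0
        n = np.cross(major, horiz / nh)
        n /= np.linalg.norm(n)
        return n if n[2] >= 0 else -n

    @property
    def area(self) -> float:
        return math.pi * self.semi_major * self.semi_minor


def blade_ellipses_from_state(
    state: PlantState,
    base_position: tuple[float, float, float] = (0.5, 0.3, 0.40),
    elevation_base: float = 60.0,
    elevation_step: float = -5.0,
    internode_cm: float = 0.5,
    absorptance: float = 0.85,
) -> list[LeafEllipse]:
    """Place a plant's blades in the chamber as ellipses (cm → m).

    Uses the same spiral-phyllotaxis layout as the structure export, with
    the plant base at ``base_position`` (default: center of the lower
    shelf).
    """
    ellipses = []
    base0 = np.asarray(base_position)
    for p in state.phytomers:
        if p.blade_length <= 0.0:
            continue
        az = np.deg2rad(p.azimuth)
        el = np.deg2rad(elevation_base + elevation_step * (p.rank - 1))
        direction = np.array(
            [np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)]
        )
        start = base0 + np.array([0.0, 0.0, internode_cm * (p.rank - 1) * 0.01])
        center = start + direction * (p.petiole_length + p.blade_length / 2.0) * 0.01
        ellipses.append(
            LeafEllipse(
                rank=p.rank,
                center=tuple(center),
                major_axis=tuple(direction),
                semi_major=p.blade_length / 2.0 * 0.01,
                semi_minor=p.blade_width / 2.0 * 0.01,
                absorptance=absorptance,
            )
        )
    return ellipses


def per_leaf_absorbed_par(
    scene: ChamberScene,
    leaves: list[LeafEllipse],
    n_rays: int = 100_000,
    seed: int | None = None,
) -> dict[int, float]:
    """Absorbed PAR per phytomer rank, μmol s⁻¹, by forward ray casting.

    Rays leave the wall panels from uniform positions with cosine-weighted
    directions, each carrying ``panel_power / n_panel_rays``. At the first
    blade intersection a fraction ``absorptance`` of the ray's weight is
    absorbed and the ray terminates (single interaction, no scattering).
    The diffuse ambient field adds ``ambient · area · absorptance`` per
    blade (upper side). Total absorption cannot exceed total emission.
    """
    absorbed: dict[int, float] = {leaf.rank: 0.0 for leaf in leaves}
    if not leaves:
        return absorbed
    rng = np.random.default_rng(seed)
    areas = np.array([p.area for p in scene.panels])
    if len(scene.panels) and areas.sum() > 0.0:
        n_per = np.maximum((n_rays * areas / areas.sum()).astype(int), 1)
        for panel, n in zip(scene.panels, n_per):
            if panel.power <= 0.0:
                continue
            origin = np.asarray(panel.origin)
            u, v = np.asarray(panel.u), np.asarray(panel.v)
            starts = origin + rng.random((n, 1)) * u + rng.random((n, 1)) * v
            dirs = _cosine_directions(panel.normal, n, rng)
            weight = panel.power / n
            hit_rank, hit_alpha = _first_hit(starts, dirs, leaves)
            for rank in absorbed:
                mask = hit_rank == rank
                absorbed[rank] += weight * float(hit_alpha[mask].sum())
    amb = scene.ambient_ppfd
    for leaf in leaves:
        absorbed[leaf.rank] += amb * leaf.area * leaf.absorptance
    return absorbed


def _cosine_directions(normal: np.ndarray, n: int, rng) -> np.ndarray:
    """Cosine-weighted hemisphere directions about ``normal``."""
    u1, u2 = rng.random(n), rng.random(n)
    r = np.sqrt(u1)
    phi = 2.0 * np.pi * u2
    local = np.stack(
        [r * np.cos(phi), r * np.sin(phi), np.sqrt(1.0 - u1)], axis=1
    )
    # orthonormal frame with z = normal
    a = np.array([1.0, 0.0, 0.0]) if abs(normal[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    t1 = np.cross(normal, a)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(normal, t1)
    return local[:, :1] * t1 + local[:, 1:2] * t2 + local[:, 2:3] * normal


def _first_hit(starts: np.ndarray, dirs: np.ndarray, leaves: list[LeafEllipse]):
    """First ellipse hit per ray: (rank array, absorptance array; -1 = miss)."""
    n = len(starts)
    best_t = np.full(n, np.inf)
    hit_rank = np.full(n, -1, dtype=int)
    hit_alpha = np.zeros(n)
    for leaf in leaves:
        center = np.asarray(leaf.center)
        normal = leaf.normal
        major = np.asarray(leaf.major_axis, dtype=float)
        minor = np.cross(normal, major)
        denom = dirs @ normal
        with np.errstate(divide="ignore", invalid="ignore"):
            t = ((center - starts) @ normal) / denom
        valid = (np.abs(denom) > 1e-12) & (t > 1e-9) & (t < best_t)
        if not valid.any():
            continue
        pts = starts[valid] + dirs[valid] * t[valid, None]
        rel = pts - center
        a_coord = rel @ major / leaf.semi_major
        b_coord = rel @ minor / leaf.semi_minor
        inside = a_coord**2 + b_coord**2 <= 1.0
        idx = np.flatnonzero(valid)[inside]
        best_t[idx] = t[idx]
        hit_rank[idx] = leaf.rank
        hit_alpha[idx] = leaf.absorptance
    return hit_rank, hit_alpha


# ---------------------------------------------------------------------------
# C3 leaf photosynthesis


@dataclass(frozen=True)
class LeafPhotosynthesisParams:
    """Leaf-level C3 photosynthesis parameters (literature defaults).

    Rates in μmol m⁻² s⁻¹ at 25 °C; Arrhenius activation energies in
    J mol⁻¹. ``ci_ratio`` is the fixed intercellular-to-ambient CO₂ ratio
    replacing a stomatal-conductance model.
    """

    Vcmax25: float = 60.0
    Jmax25: float = 120.0
    Rd25: float = 1.0
    quantum_yield: float = 0.3  # e⁻ per absorbed photon
    curvature: float = 0.9
    absorptance: float = 0.85
    ci_ratio: float = 0.7
    ca: float = 400.0  # μmol mol⁻¹ ambient CO₂
    o2: float = 210.0  # mmol mol⁻¹ oxygen
    ea_vcmax: float = 65_330.0
    ea_jmax: float = 43_540.0
    ea_rd: float = 46_390.0
    ea_kc: float = 79_430.0
    ea_ko: float = 36_380.0
    ea_gstar: float = 37_830.0
    kc25: float = 404.9  # μmol mol⁻¹
    ko25: float = 278.4  # mmol mol⁻¹
    gamma_star25: float = 42.75  # μmol mol⁻¹

    def __post_init__(self) -> None:
        for name in ("Vcmax25", "Jmax25", "Rd25", "quantum_yield", "curvature",
                     "absorptance", "ci_ratio", "ca", "o2"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be positive")
        if self.Jmax25 <= self.Vcmax25:
            import warnings

            warnings.warn("Jmax25 <= Vcmax25 is atypical for C3 leaves")


def _arrhenius(k25: float, ea: float, t_c: float) -> float:
    tk = t_c + 273.15
    return k25 * math.exp(ea * (tk - T_REF) / (R_GAS * T_REF * tk))


def dark_respiration(t_leaf: float, p: LeafPhotosynthesisParams) -> float:
    """Rd (μmol CO₂ m⁻² s⁻¹) at leaf temperature t_leaf (°C)."""
    return _arrhenius(p.Rd25, p.ea_rd, t_leaf)


def net_assimilation(
    ppfd: float, t_leaf: float, p: LeafPhotosynthesisParams | None = None
) -> float:
    """Net CO₂ assimilation A (μmol m⁻² s⁻¹) at incident PPFD and t_leaf.

    ``A = min(Wc, Wj) − Rd`` with the Rubisco-limited rate
    ``Wc = Vcmax (Ci−Γ*)/(Ci + Kc (1 + O/Ko))`` and the light-limited rate
    ``Wj = J (Ci−Γ*)/(4 Ci + 8 Γ*)``, where J solves the non-rectangular
    hyperbola ``θ J² − (I₂+Jmax) J + I₂ Jmax = 0`` with
    ``I₂ = absorptance · quantum_yield · ppfd``. Leaf temperature is taken
    equal to air temperature. Monotone non-decreasing and continuous in
    ppfd; at ppfd = 0, A = −Rd.
    """
    p = p or LeafPhotosynthesisParams()
    if ppfd < 0.0:
        raise ValueError("ppfd must be >= 0")
    vcmax = _arrhenius(p.Vcmax25, p.ea_vcmax, t_leaf)
    jmax = _arrhenius(p.Jmax25, p.ea_jmax, t_leaf)
    kc = _arrhenius(p.kc25, p.ea_kc, t_leaf)
    ko = _arrhenius(p.ko25, p.ea_ko, t_leaf)
    gstar = _arrhenius(p.gamma_star25, p.ea_gstar, t_leaf)
    rd = dark_respiration(t_leaf, p)
    ci = p.ci_ratio * p.ca

    wc = vcmax * (ci - gstar) / (ci + kc * (1.0 + p.o2 / ko))
    i2 = p.absorptance * p.quantum_yield * ppfd
    theta = p.curvature
    j = (i2 + jmax - math.sqrt((i2 + jmax) ** 2 - 4.0 * theta * i2 * jmax)) / (
        2.0 * theta
    )
    wj = j * (ci - gstar) / (4.0 * ci + 8.0 * gstar)
    return min(wc, wj) - rd


# ---------------------------------------------------------------------------
# Daily carbon budget


@dataclass(frozen=True)
class CarbonBudgetParams:
    """Whole-plant respiration and conversion coefficients.

    maintenance_rate : μmol CO₂ per mg dry mass per day at 25 °C.
    q10 : maintenance temperature response per 10 °C.
    growth_yield : fraction of the net pool converted to structure (Y_g);
        the remainder is growth respiration.
    """

    maintenance_rate: float = 0.5
    q10: float = 2.0
    growth_yield: float = 0.75

    def __post_init__(self) -> None:
        if not 0.0 < self.growth_yield <= 1.0:
            raise ValueError("growth_yield must lie in (0, 1]")
        if self.maintenance_rate < 0.0 or self.q10 <= 0.0:
            raise ValueError("maintenance_rate >= 0 and q10 > 0 required")


@dataclass(frozen=True)
class CarbonBudget:
    """One day's carbon bookkeeping, all fluxes in μmol CO₂ d⁻¹.

    Conservation identity (exact by construction):
    ``gross = dmass_mg·conversion + resp_growth + resp_maintenance``.
    """

    gross_umol: float
    resp_maint_umol: float
    resp_growth_umol: float
    dmass_mg: float

    #: μmol CO₂ fixed per mg structural dry mass (CH₂O basis)
    conversion: float = 1000.0 / UG_CH2O_PER_UMOL_CO2

    @property
    def residual(self) -> float:
        """Budget closure error, μmol d⁻¹ (zero up to float rounding)."""
        return self.gross_umol - (
            self.dmass_mg * self.conversion
            + self.resp_growth_umol
            + self.resp_maint_umol
        )


def daily_carbon_budget(
    plant: PlantState,
    absorbed_par: dict[int, float],
    regime: TemperatureRegime,
    photo: LeafPhotosynthesisParams | None = None,
    budget: CarbonBudgetParams | None = None,
) -> CarbonBudget:
    """One day's dry-mass increment from light, photosynthesis, respiration.

    Gross assimilation: each blade photosynthesizes for the photoperiod at
    the day temperature, driven by its absorbed PAR expressed per unit blade
    area (the absorption step already happened in the light model, so the
    leaf model is run with absorptance 1). Maintenance respiration is
    proportional to dry mass with a Q10 response to the daily mean
    temperature and runs all 24 h. Of the positive net pool, a fraction
    ``growth_yield`` becomes structural dry mass and the rest is growth
    respiration; a negative pool draws down mass with no growth respiration.
    """
    photo = photo or LeafPhotosynthesisParams()
    budget = budget or CarbonBudgetParams()
    day_s = regime.photoperiod_h * 3600.0

    photo_unit = replace(photo, absorptance=1.0)
    gross = 0.0
    for p in plant.phytomers:
        if p.blade_area <= 0.0:
            continue
        area_m2 = p.blade_area * 1e-4
        flux = absorbed_par.get(p.rank, 0.0)  # μmol s⁻¹ absorbed by the blade
        ppfd = flux / area_m2 if area_m2 > 0 else 0.0
        a_net = net_assimilation(ppfd, regime.t_day, photo_unit)
        a_gross = a_net + dark_respiration(regime.t_day, photo_unit)
        gross += max(a_gross, 0.0) * area_m2 * day_s

    p_h = regime.photoperiod_h
    t_mean = (regime.t_day * p_h + regime.t_night * (24.0 - p_h)) / 24.0
    maint = (
        budget.maintenance_rate
        * budget.q10 ** ((t_mean - 25.0) / 10.0)
        * plant.total_mass
    )

    net_pool = gross - maint
    if net_pool > 0.0:
        growth = budget.growth_yield * net_pool
        resp_growth = net_pool - growth
    else:
        growth = net_pool
        resp_growth = 0.0
    dmass_mg = growth * UG_CH2O_PER_UMOL_CO2 / 1000.0
    return CarbonBudget(
        gross_umol=gross,
        resp_maint_umol=maint,
        resp_growth_umol=resp_growth,
        dmass_mg=dmass_mg,
    )
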