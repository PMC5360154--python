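"""Chamber light transport and the C3 leaf carbon budget."""

import math
from dataclasses import replace

import numpy as np
import pytest

from rapeseed_fspm.light_carbon import (
    CarbonBudgetParams,
    ChamberScene,
    LeafEllipse,
    LeafPhotosynthesisParams,
    Panel,
    daily_carbon_budget,
    dark_respiration,
    default_scene,
    estimate_sensor_ppfd,
    net_assimilation,
    per_leaf_absorbed_par,
)
from rapeseed_fspm.simulator import PhenologyParams, PlantState, Phytomer
from rapeseed_fspm.thermal_time import PRESETS


class TestSensorPPFD:
    def test_calibrated_scene_reads_the_measured_flux(self):
        """Default 330 total output reproduces the measured mean of
        150 μmol m⁻² s⁻¹ within 10% at 10⁵ rays."""
        ppfd, se = estimate_sensor_ppfd(default_scene(), n_rays=100_000, seed=0)
        assert np.mean(ppfd) == pytest.approx(150.0, rel=0.10)
        assert np.all(se >= 0)

    def test_dark_chamber_reads_zero(self):
        scene = replace(default_scene(total_output=0.0), wall_reflectance=0.0)
        ppfd, _ = estimate_sensor_ppfd(scene, n_rays=2_000, seed=1)
        assert np.allclose(ppfd, 0.0)

    def test_transport_is_linear_in_source_strength(self):
        a, _ = estimate_sensor_ppfd(default_scene(330.0), n_rays=20_000, seed=3)
        b, _ = estimate_sensor_ppfd(default_scene(660.0), n_rays=20_000, seed=3)
        assert np.allclose(b, 2.0 * a, rtol=1e-9)

    def test_monte_carlo_error_shrinks_as_root_n(self):
        scene = default_scene()
        _, se1 = estimate_sensor_ppfd(scene, n_rays=10_000, seed=5)
        _, se2 = estimate_sensor_ppfd(scene, n_rays=40_000, seed=6)
        ratio = se1.mean() / se2.mean()
        assert ratio == pytest.approx(2.0, rel=0.35)

    def test_sensor_outside_box_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            replace(default_scene(), sensors=((0.5, 0.3, 9.0),))


def _overhead_scene(exitance=300.0):
    """A single downward-facing ceiling panel, black walls."""
    w, d, h = 1.0, 1.0, 1.0
    panel = Panel(origin=(0.0, 0.0, h), u=(0.0, d, 0.0), v=(w, 0.0, 0.0),
                  exitance=exitance)
    return ChamberScene(box=(w, d, h), panels=(panel,),
                        sensors=((0.5, 0.5, 0.5),), wall_reflectance=0.0)


def _disk(rank, center, radius, absorptance=1.0):
    return LeafEllipse(rank=rank, center=center, major_axis=(1.0, 0.0, 0.0),
                       semi_major=radius, semi_minor=radius,
                       absorptance=absorptance)


class TestAbsorbedPAR:
    def test_empty_plant_absorbs_nothing(self):
        assert per_leaf_absorbed_par(_overhead_scene(), [], n_rays=100) == {}

    def test_energy_conservation(self):
        scene = _overhead_scene()
        leaves = [_disk(1, (0.5, 0.5, 0.6), 0.3), _disk(2, (0.4, 0.4, 0.4), 0.3)]
        absorbed = per_leaf_absorbed_par(scene, leaves, n_rays=30_000, seed=2)
        assert sum(absorbed.values()) <= scene.total_power * (1 + 1e-9)

    def test_centered_leaf_outcollects_corner_leaf(self):
        scene = _overhead_scene()
        center = per_leaf_absorbed_par(
            scene, [_disk(1, (0.5, 0.5, 0.8), 0.1)], n_rays=60_000, seed=4
        )[1]
        corner = per_leaf_absorbed_par(
            scene, [_disk(1, (0.05, 0.05, 0.05), 0.1)], n_rays=60_000, seed=4
        )[1]
        assert center > corner

    def test_shaded_leaf_absorbs_less_than_unshaded_control(self):
        """Two parallel disks under an overhead source: the lower one,
        fully occluded, collects less than it would alone."""
        scene = _overhead_scene()
        shade = _disk(1, (0.5, 0.5, 0.8), 0.25)
        lower = _disk(2, (0.5, 0.5, 0.4), 0.2)
        shaded = per_leaf_absorbed_par(scene, [shade, lower], n_rays=60_000, seed=9)[2]
        control = per_leaf_absorbed_par(scene, [lower], n_rays=60_000, seed=9)[2]
        assert shaded < control

    def test_opaque_shade_blocks_completely(self):
        scene = _overhead_scene()
        shade = _disk(1, (0.5, 0.5, 0.8), 0.45)
        lower = _disk(2, (0.5, 0.5, 0.7), 0.05)  # well inside the umbra
        absorbed = per_leaf_absorbed_par(scene, [shade, lower], n_rays=60_000, seed=9)
        assert absorbed[2] == pytest.approx(0.0, abs=scene.total_power * 1e-4)


class TestNetAssimilation:
    def test_dark_rate_is_negative_respiration(self):
        p = LeafPhotosynthesisParams()
        assert net_assimilation(0.0, 25.0, p) == pytest.approx(
            -dark_respiration(25.0, p), rel=1e-12
        )

    def test_saturates_at_rubisco_ceiling(self):
        p = LeafPhotosynthesisParams()
        a_hi = net_assimilation(5_000.0, 25.0, p)
        a_huge = net_assimilation(50_000.0, 25.0, p)
        assert a_huge - a_hi < 0.5
        ci = p.ci_ratio * p.ca
        wc = p.Vcmax25 * (ci - p.gamma_star25) / (
            ci + p.kc25 * (1.0 + p.o2 / p.ko25)
        )
        assert a_huge <= wc - p.Rd25 + 1e-9

    def test_monotone_non_decreasing_in_light(self):
        p = LeafPhotosynthesisParams()
        grid = np.linspace(0.0, 2000.0, 200)
        values = [net_assimilation(q, 22.0, p) for q in grid]
        assert np.all(np.diff(values) >= -1e-12)

    def test_matches_independent_closed_form(self):
        """Value at the chamber's working PPFD agrees with a from-scratch
        evaluation of the same biochemistry to 10⁻⁶."""
        p = LeafPhotosynthesisParams()
        t, q = 25.0, 150.0
        # independent oracle, written out directly
        ci = p.ci_ratio * p.ca
        arr = lambda k25, ea: k25 * math.exp(
            ea * (t + 273.15 - 298.15) / (8.314 * 298.15 * (t + 273.15))
        )
        wc = arr(p.Vcmax25, p.ea_vcmax) * (ci - arr(p.gamma_star25, p.ea_gstar)) / (
            ci + arr(p.kc25, p.ea_kc) * (1 + p.o2 / arr(p.ko25, p.ea_ko))
        )
        i2 = p.absorptance * p.quantum_yield * q
        jmax = arr(p.Jmax25, p.ea_jmax)
        j = (i2 + jmax - math.sqrt((i2 + jmax) ** 2 - 4 * p.curvature * i2 * jmax)) / (
            2 * p.curvature
        )
        gs = arr(p.gamma_star25, p.ea_gstar)
        wj = j * (ci - gs) / (4 * ci + 8 * gs)
        expected = min(wc, wj) - arr(p.Rd25, p.ea_rd)
        assert net_assimilation(q, t, p) == pytest.approx(expected, abs=1e-6)

    def test_negative_light_rejected(self):
        with pytest.raises(ValueError):
            net_assimilation(-1.0, 25.0)


def _leafy_plant(areas_cm2, mass_mg=100.0):
    state = PlantState(treatment="M")
    for i, a in enumerate(areas_cm2, start=1):
        state.phytomers.append(
            Phytomer(rank=i, ts_init=0.0, azimuth=0.0, blade_length=1.0,
                     blade_area=a, dry_mass=mass_mg / len(areas_cm2))
        )
    return state


class TestCarbonBudget:
    def test_darkness_costs_maintenance(self):
        plant = _leafy_plant([50.0, 30.0])
        budget = daily_carbon_budget(plant, {1: 0.0, 2: 0.0}, PRESETS["M"])
        assert budget.dmass_mg < 0.0
        assert budget.resp_growth_umol == 0.0

    def test_books_balance_on_randomized_inputs(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            areas = rng.uniform(1.0, 80.0, size=rng.integers(1, 6))
            plant = _leafy_plant(areas, mass_mg=float(rng.uniform(1.0, 500.0)))
            absorbed = {
                i + 1: float(rng.uniform(0.0, 0.05)) for i in range(len(areas))
            }
            params = CarbonBudgetParams(
                maintenance_rate=float(rng.uniform(0.0, 1.0)),
                q10=float(rng.uniform(1.5, 2.5)),
                growth_yield=float(rng.uniform(0.5, 0.95)),
            )
            treatment = "HML"[int(rng.integers(3))]
            budget = daily_carbon_budget(plant, absorbed, PRESETS[treatment],
                                         budget=params)
            scale = max(abs(budget.gross_umol), 1.0)
            assert abs(budget.residual) / scale < 1e-9

    def test_gross_assimilation_additive_in_leaf_area(self):
        single = _leafy_plant([40.0])
        double = _leafy_plant([40.0, 40.0])
        flux = 0.02  # μmol s⁻¹ per blade, same per-area flux in both plants
        b1 = daily_carbon_budget(single, {1: flux}, PRESETS["H"])
        b2 = daily_carbon_budget(double, {1: flux, 2: flux}, PRESETS["H"])
        assert b2.gross_umol == pytest.approx(2.0 * b1.gross_umol, rel=1e-12)

    def test_budget_params_validated(self):
        with pytest.raises(ValueError):
            CarbonBudgetParams(growth_yield=0.0)


def test_carbon_columns_attach_to_simulator_output():
    import warnings

    from rapeseed_fspm.carbon_mode import carbon_columns
    from rapeseed_fspm.simulator import run

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        plant_daily, _ = run("M", 5)
        out = carbon_columns(plant_daily, "M", 5, PRESETS["M"], n_rays=3_000, seed=1)
    for col in ("gross_umol", "resp_maint_umol", "resp_growth_umol", "dmass_mg"):
        assert col in out
    assert len(out) == 6
    assert (out["gross_umol"] >= 0).all()
    assert out["gross_umol"].iloc[-1] > out["gross_umol"].iloc[0]
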