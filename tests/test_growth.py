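"""Growth-curve evaluation: blade extension, dry mass, leaf area."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rapeseed_fspm import growth
from rapeseed_fspm.parameters import (
    DenormalizationAnchors,
    DoubleLogisticParams,
    LeafAreaCurveParams,
    LeafExtensionParams,
    NormalizedLogisticParams,
)


def _ext(y_m, ts_0, b):
    return LeafExtensionParams(rank=0, treatment="?", y_m=y_m, ts_0=ts_0, b=b)


class TestLeafLength:
    def test_half_maximum_at_ts0(self, store):
        p = store.leaf_extension(3, "H")
        assert growth.leaf_length(p.ts_0, p) == pytest.approx(p.y_m / 2, rel=1e-12)

    def test_asymptote_reaches_maximum_length(self, store):
        p = store.leaf_extension(3, "H")
        assert growth.leaf_length(1e6, p) == pytest.approx(9.04, rel=0.01)

    def test_direct_evaluation(self, store):
        # 9.04 / (1 + (300/246.15)^(-1.10))
        assert growth.leaf_length(300.0, store.leaf_extension(3, "H")) == pytest.approx(
            5.01, abs=5e-3
        )

    def test_rejects_non_positive_time(self):
        with pytest.raises(ValueError):
            growth.leaf_length(0.0, _ext(5.0, 100.0, -1.0))

    def test_half_maximum_identity_for_every_sigmoid_row(self, store):
        """Every packaged row with b < 0 passes through y_m/2 at ts_0 and
        approaches y_m within 1% beyond its convergence horizon.

        The horizon ts_0·100^(1/|b|) is where (ts/ts_0)^b reaches 0.01;
        for the steep rows it lies far below 10⁶ °Cd, but the shallow
        rank-1/2 slopes (b ≈ −0.1) converge much more slowly.
        """
        for tr in "HML":
            for r in store.leaf_extension_ranks(tr):
                p = store.leaf_extension(r, tr)
                if p.b >= 0:
                    continue
                assert growth.leaf_length(p.ts_0, p) == pytest.approx(
                    p.y_m / 2, rel=1e-12
                )
                horizon = max(1e6, p.ts_0 * 100.0 ** (1.0 / abs(p.b)))
                assert growth.leaf_length(horizon, p) == pytest.approx(p.y_m, rel=0.01)

    def test_monotone_increasing_and_bounded_for_negative_b(self, store):
        p = store.leaf_extension(4, "M")
        ts = np.linspace(1.0, 2000.0, 500)
        y = growth.leaf_length(ts, p)
        assert np.all(np.diff(y) > 0)
        assert np.all(y < p.y_m)

    def test_positive_b_row_decreases(self, store):
        """The low-treatment rank-1 printed slope is positive, making the
        raw curve a decreasing step — evaluated faithfully here."""
        p = store.leaf_extension(1, "L")
        assert growth.leaf_length(100.0, p) > growth.leaf_length(400.0, p)


class TestNormalizedDryMass:
    def test_lower_branch_at_origin(self, store):
        p = store.dry_mass_plant("M")
        assert growth.normalized_dry_mass(0.0, p.lower) == pytest.approx(
            1.10 / (1 + math.exp(3.72)), rel=1e-12
        )
        assert growth.normalized_dry_mass(0.0, p.lower) == pytest.approx(0.0260, abs=5e-5)

    def test_upper_branch_at_end(self, store):
        p = store.dry_mass_plant("H")
        assert growth.normalized_dry_mass(1.0, p.upper) == pytest.approx(0.99834, abs=1e-5)

    def test_zero_shape_parameters_give_half(self):
        p = NormalizedLogisticParams(1.0, 0.0, 0.0, 0.0)
        for t in (0.0, 0.3, 1.0):
            assert growth.normalized_dry_mass(t, p) == 0.5

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        t=st.floats(0, 1),
        y_m=st.floats(0.1, 40),
        a=st.floats(-50, 50),
        b=st.floats(-50, 50),
        c=st.floats(-50, 50),
    )
    def test_bounded_in_open_interval(self, t, y_m, a, b, c):
        # upper bound closed only through float rounding when exp underflows
        y = growth.normalized_dry_mass(t, NormalizedLogisticParams(y_m, a, b, c))
        assert 0.0 < y <= y_m
        if a * t * t + b * t + c > -30.0:
            assert y < y_m

    def test_extreme_exponents_do_not_overflow(self):
        p = NormalizedLogisticParams(1.0, 1e5, 1e5, 1e5)
        assert growth.normalized_dry_mass(1.0, p) >= 0.0


class TestDoubleLogistic:
    def test_lower_branch_at_origin(self, store):
        assert growth.double_logistic_dry_mass(
            0.0, store.dry_mass_plant("H")
        ) == pytest.approx(7.58 / (1 + math.exp(6.15)), rel=1e-12)

    def test_upper_branch_at_end(self, store):
        # 1 / (1 + e^(-(-106.04 + 175.29 - 73.18))) = 1 / (1 + e^-3.93)
        assert growth.double_logistic_dry_mass(
            1.0, store.dry_mass_plant("M")
        ) == pytest.approx(1.0 / (1.0 + math.exp(-3.93)), rel=1e-12)

    def test_branch_selection_is_strict_below_transition(self, store):
        p = store.dry_mass_plant("H")
        eps = 1e-9
        below = growth.double_logistic_dry_mass(p.ts_tr - eps, p)
        at = growth.double_logistic_dry_mass(p.ts_tr, p)
        assert below == pytest.approx(growth.normalized_dry_mass(p.ts_tr - eps, p.lower))
        assert at == pytest.approx(growth.normalized_dry_mass(p.ts_tr, p.upper))

    def test_equal_branches_are_continuous(self):
        branch = NormalizedLogisticParams(1.0, 2.0, -6.0, 2.5)
        p = DoubleLogisticParams(lower=branch, upper=branch, ts_tr=0.5)
        t = np.linspace(0, 1, 201)
        assert np.allclose(
            growth.double_logistic_dry_mass(t, p), growth.normalized_dry_mass(t, branch)
        )
        assert growth.branch_discontinuity(p) == 0.0

    @pytest.mark.parametrize("treatment", ["H", "M", "L"])
    def test_discontinuity_equals_branch_gap_oracle(self, store, treatment):
        """The reported jump matches a plain-math evaluation of both
        branches at the transition."""
        p = store.dry_mass_plant(treatment)

        def plain(branch, t):
            return branch.y_m / (1 + math.exp(branch.a * t * t + branch.b * t + branch.c))

        expected = abs(plain(p.lower, p.ts_tr) - plain(p.upper, p.ts_tr))
        assert growth.branch_discontinuity(p) == pytest.approx(expected, rel=1e-12)


class TestDryMassDenormalization:
    def test_anchors_scale_the_normalized_curve(self, store):
        anchors = DenormalizationAnchors(y_max=100.0, ts_max=460.0)
        value = growth.dry_mass(460.0, store.dry_mass_plant("M"), anchors)
        assert value == pytest.approx(98.075, abs=1e-2)

    def test_identity_anchors_reduce_to_normalized_curve(self, store):
        p = store.dry_mass_rank(2, "M")
        anchors = DenormalizationAnchors(y_max=1.0, ts_max=1.0)
        t = 0.4
        assert growth.dry_mass(t, p, anchors) == growth.normalized_dry_mass(t, p)


class TestWholePlantLeafArea:
    def test_midpoint_at_maximal_rate_time(self, store):
        p = store.leaf_area("H")
        assert growth.whole_plant_leaf_area(p.TS_m, p) == pytest.approx(76.5)

    def test_initial_and_limit_values(self, store):
        p = store.leaf_area("H")
        assert growth.whole_plant_leaf_area(0.0, p) == pytest.approx(17.06, abs=5e-3)
        assert growth.whole_plant_leaf_area(1e5, p) == pytest.approx(136.0, rel=1e-9)

    def test_strictly_increasing_and_bounded(self, store):
        p = store.leaf_area("L")
        ts = np.linspace(0, 600, 400)  # strict growth before float saturation
        y = growth.whole_plant_leaf_area(ts, p)
        assert np.all(np.diff(y) > 0)
        assert np.all((y > p.LA_0) & (y < p.LA_0 + p.LA_max))

    def test_negative_time_rejected(self, store):
        with pytest.raises(ValueError):
            growth.whole_plant_leaf_area(-1.0, store.leaf_area("H"))

    def test_raw_power_form_undefined_below_midpoint(self, store):
        p = store.leaf_area("H")
        assert math.isnan(growth.leaf_area_raw_power_form(100.0, p))
        assert math.isfinite(growth.leaf_area_raw_power_form(500.0, p))
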