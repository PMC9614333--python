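import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from greyrank import (
    DengParams,
    GradeError,
    GreyPanel,
    SyntheticParams,
    absolute_grade,
    deng_grade,
    deng_point_coefficients,
    panel_deviation_extremes,
    series_integral,
    synthetic_grade,
    zero_start_image,
)
from conftest import make_series, random_panel
from oracles import absolute_grade_oracle, deng_grade_oracle

PER_PAIR = DengParams(extremes_scope="per_pair")

finite_series = st.lists(
    st.floats(min_value=-1e3, max_value=1e3, allow_nan=False),
    min_size=2,
    max_size=30,
)


class TestDeng:
    def test_point_coefficients_hand_example(self):
        # deviations [0, 0, 1] -> d_min=0, d_max=1, zeta=0.5
        coeffs = deng_point_coefficients([1, 2, 3], [1, 2, 4], PER_PAIR)
        np.testing.assert_allclose(coeffs, [1.0, 1.0, 1.0 / 3.0], atol=1e-15)

    def test_grade_hand_example(self):
        assert deng_grade([1, 2, 3], [1, 2, 4], PER_PAIR) == pytest.approx(7 / 9, abs=1e-15)

    def test_identical_series_score_one(self):
        assert deng_grade([3.0, 1.0, 4.0], [3.0, 1.0, 4.0], PER_PAIR) == 1.0

    def test_per_pair_symmetry(self, rng):
        a = rng.uniform(0, 5, 10)
        b = rng.uniform(0, 5, 10)
        assert deng_grade(a, b, PER_PAIR) == pytest.approx(deng_grade(b, a, PER_PAIR), abs=1e-15)

    def test_panel_wide_requires_extremes(self):
        with pytest.raises(GradeError, match="panel_extremes"):
            deng_grade([1, 2], [1, 3], DengParams(extremes_scope="panel_wide"))

    def test_panel_extremes_values(self, simple_panel):
        d_min, d_max = panel_deviation_extremes(simple_panel)
        devs = np.concatenate(
            [np.abs(simple_panel.reference.values - c.values) for c in simple_panel.comparatives]
        )
        assert d_min == devs.min()
        assert d_max == devs.max()

    def test_zeta_controls_contrast(self):
        # at epochs where the deviation exceeds d_min, smaller zeta
        # penalizes harder; the d_min epoch stays at coefficient 1
        sharp = deng_point_coefficients([1, 2, 3], [1, 2, 4], DengParams(zeta=0.1, extremes_scope="per_pair"))
        flat = deng_point_coefficients([1, 2, 3], [1, 2, 4], DengParams(zeta=0.9, extremes_scope="per_pair"))
        assert sharp[0] == flat[0] == 1.0
        assert sharp[2] < flat[2]

    def test_length_mismatch(self):
        with pytest.raises(GradeError, match="length mismatch"):
            deng_grade([1, 2, 3], [1, 2], PER_PAIR)

    @pytest.mark.parametrize("zeta", [0.0, 1.0, -0.5, 1.5])
    def test_zeta_out_of_range(self, zeta):
        with pytest.raises(GradeError, match="zeta"):
            DengParams(zeta=zeta)

    @given(values=finite_series, shift=st.floats(-100, 100, allow_nan=False))
    @settings(deadline=None, max_examples=50)
    def test_shifting_both_series_is_invariant(self, values, shift):
        ref = np.asarray(values)
        cmp = ref[::-1].copy()
        base = deng_grade(ref, cmp, PER_PAIR)
        moved = deng_grade(ref + shift, cmp + shift, PER_PAIR)
        assert moved == pytest.approx(base, abs=1e-9)


class TestZeroStartAndIntegral:
    def test_zero_start_examples(self):
        np.testing.assert_array_equal(zero_start_image([3.0, 5.0, 4.0]), [0.0, 2.0, 1.0])
        np.testing.assert_array_equal(zero_start_image([7.0, 7.0, 7.0]), [0.0, 0.0, 0.0])

    def test_zero_start_idempotent_and_preserves_series(self):
        s = make_series("x", [3.0, 5.0, 4.0])
        img = zero_start_image(s)
        assert img.label == "x"
        assert img.epochs == s.epochs
        np.testing.assert_array_equal(zero_start_image(img).values, img.values)

    @pytest.mark.parametrize(
        "values,expected",
        [
            ([0.0, 1.0, 2.0], 2.0),
            ([0.0, 0.0, 0.0, 0.0], 0.0),
            ([0.0, 3.0], 1.5),
            ([0.0, -2.0, 1.0], -1.5),
        ],
    )
    def test_trapezoid_integral(self, values, expected):
        assert series_integral(values) == pytest.approx(expected, abs=1e-15)

    def test_integral_requires_zero_start(self):
        with pytest.raises(GradeError, match="zero-start"):
            series_integral([1.0, 2.0])


class TestAbsoluteGrade:
    def test_hand_example(self):
        # s_ref=2, s_cmp=4, s_diff=-2 -> (1+2+4)/(1+2+4+2)
        assert absolute_grade([1, 2, 3], [1, 3, 5]) == pytest.approx(7 / 9, abs=1e-15)

    def test_identity_and_constant_shift_score_one(self, rng):
        v = rng.uniform(0, 5, 12)
        assert absolute_grade(v, v) == 1.0
        assert absolute_grade(v, v + 3.7) == pytest.approx(1.0, abs=1e-12)

    def test_components_attached(self):
        eps, comps = absolute_grade([1, 2, 3], [1, 3, 5], return_components=True)
        assert comps.s_ref == pytest.approx(2.0)
        assert comps.s_cmp == pytest.approx(4.0)
        assert comps.s_diff == pytest.approx(-2.0)
        assert eps == pytest.approx(7 / 9)

    def test_identical_series_have_zero_diff_integral(self, rng):
        v = rng.uniform(0, 5, 8)
        _, comps = absolute_grade(v, v, return_components=True)
        assert comps.s_diff == 0.0

    @given(values=finite_series, shift=st.floats(-100, 100, allow_nan=False))
    @settings(deadline=None, max_examples=50)
    def test_shift_invariance_either_series(self, values, shift):
        ref = np.asarray(values)
        cmp = np.sin(ref) + 1.0
        base = absolute_grade(ref, cmp)
        assert absolute_grade(ref + shift, cmp) == pytest.approx(base, abs=1e-9)
        assert absolute_grade(ref, cmp + shift) == pytest.approx(base, abs=1e-9)


class TestSyntheticGrade:
    def test_reported_spot_value(self):
        # equal-weight blend of a published Deng/absolute pair
        assert synthetic_grade(0.9889, 0.9935) == pytest.approx(0.9912, abs=5e-5)

    def test_theta_boundaries(self):
        assert synthetic_grade(0.7, 0.9, SyntheticParams(theta=0.0)) == 0.7
        assert synthetic_grade(0.7, 0.9, SyntheticParams(theta=1.0)) == 0.9

    def test_convex_bounds(self, rng):
        for _ in range(50):
            g, e, t = rng.uniform(0.01, 1.0, 2).tolist() + [rng.uniform(0, 1)]
            p = synthetic_grade(g, e, SyntheticParams(theta=t))
            assert min(g, e) - 1e-15 <= p <= max(g, e) + 1e-15

    def test_monotone_in_theta(self):
        thetas = np.linspace(0, 1, 11)
        increasing = [synthetic_grade(0.6, 0.9, SyntheticParams(theta=t)) for t in thetas]
        decreasing = [synthetic_grade(0.9, 0.6, SyntheticParams(theta=t)) for t in thetas]
        assert all(a < b for a, b in zip(increasing, increasing[1:]))
        assert all(a > b for a, b in zip(decreasing, decreasing[1:]))

    @pytest.mark.parametrize("theta", [-0.1, 1.1])
    def test_theta_out_of_range(self, theta):
        with pytest.raises(GradeError, match="theta"):
            SyntheticParams(theta=theta)

    @pytest.mark.parametrize("gamma,epsilon", [(0.0, 0.5), (0.5, 1.5), (-0.2, 0.5)])
    def test_grades_out_of_range_rejected(self, gamma, epsilon):
        with pytest.raises(GradeError):
            synthetic_grade(gamma, epsilon)


class TestAgainstOracle:
    """Package grades vs independent loop-based transcriptions."""

    @pytest.mark.parametrize("scope", ["panel_wide", "per_pair"])
    def test_deng_matches_oracle(self, rng, scope):
        for _ in range(60):
            panel = random_panel(rng, n_comparatives=int(rng.integers(1, 5)))
            extremes = panel_deviation_extremes(panel)
            params = DengParams(zeta=float(rng.uniform(0.05, 0.95)), extremes_scope=scope)
            comp_values = [c.values for c in panel.comparatives]
            for j, cmp in enumerate(panel.comparatives):
                got = deng_grade(
                    panel.reference, cmp, params,
                    extremes if scope == "panel_wide" else None,
                )
                want = deng_grade_oracle(
                    panel.reference.values, comp_values, j, params.zeta, scope
                )
                assert got == pytest.approx(want, abs=1e-12)
                assert 0.0 < got <= 1.0

    def test_absolute_matches_oracle(self, rng):
        for _ in range(100):
            panel = random_panel(rng, n_comparatives=1)
            got = absolute_grade(panel.reference, panel.comparatives[0])
            want = absolute_grade_oracle(
                panel.reference.values, panel.comparatives[0].values
            )
            assert got == pytest.approx(want, abs=1e-12)
            assert 0.0 < got <= 1.0
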