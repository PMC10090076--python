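import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drcbridge import (
    DoseResponseCurve,
    HarmonizationConfig,
    LL4Params,
    build_ll4_params,
    encode_drc_baseline,
    encode_drc_imputation,
    interp_lagrange,
    interp_linear,
    interp_ll4,
    log10_grid,
)
from drcbridge.harmonize import DegenerateCurveError
from drcbridge.simulate import hill_response


def make_curve(doses, responses, **kw):
    defaults = dict(drug_id="d", cell_line_id="c", study_id="s")
    defaults.update(kw)
    return DoseResponseCurve(doses=tuple(doses), responses=tuple(responses),
                             **defaults)


class TestLog10Grid:
    def test_two_decades_three_points(self):
        curve = make_curve([0.1, 10.0], [0.0, 50.0])
        grid = log10_grid(curve, HarmonizationConfig(target_length=3))
        np.testing.assert_allclose(grid, [-1.0, 0.0, 1.0])

    def test_zero_dose_replaced_by_pseudo_dose(self, printed_curve):
        grid = log10_grid(printed_curve, HarmonizationConfig())
        # 0 -> 0.1 x smallest positive dose = 0.0075
        assert grid[0] == pytest.approx(np.log10(0.0075))
        assert grid[-1] == pytest.approx(np.log10(2.0))

    def test_default_length_is_ten(self, printed_curve):
        assert len(log10_grid(printed_curve, HarmonizationConfig())) == 10

    def test_drop_policy_removes_control(self, printed_curve):
        cfg = HarmonizationConfig(zero_dose_policy="drop")
        grid = log10_grid(printed_curve, cfg)
        assert grid[0] == pytest.approx(np.log10(0.075))

    def test_degenerate_after_drop_raises(self):
        curve = make_curve([0.0, 1.0], [0.0, 10.0])
        with pytest.raises(DegenerateCurveError):
            log10_grid(curve, HarmonizationConfig(zero_dose_policy="drop"))


class TestLinearInterpolation:
    def test_midpoint_of_a_line(self):
        curve = make_curve([1.0, 100.0], [0.0, 10.0])  # log-doses 0 and 2
        assert interp_linear(curve, np.array([1.0]))[0] == pytest.approx(5.0)

    def test_passes_through_all_knots(self, printed_curve):
        cfg = HarmonizationConfig()
        from drcbridge.monotherapy import log_doses

        x, y = log_doses(printed_curve)
        np.testing.assert_allclose(interp_linear(printed_curve, x, cfg), y,
                                   atol=1e-12)

    def test_matches_segmentwise_oracle_on_printed_curve(self, printed_curve):
        """Brute-force, segment-by-segment linear evaluation oracle."""
        from drcbridge.monotherapy import log_doses

        cfg = HarmonizationConfig()
        grid = log10_grid(printed_curve, cfg)
        x, y = log_doses(printed_curve)

        def oracle(q):
            for i in range(len(x) - 1):
                if x[i] <= q <= x[i + 1]:
                    return y[i] + (q - x[i]) * (y[i + 1] - y[i]) / (x[i + 1] - x[i])
            return y[0] if q < x[0] else y[-1]

        expected = [oracle(q) for q in grid]
        np.testing.assert_allclose(interp_linear(printed_curve, grid, cfg),
                                   expected, atol=1e-12)

    def test_out_of_range_clamps_to_endpoints(self):
        curve = make_curve([0.1, 10.0], [1.0, 9.0])
        out = interp_linear(curve, np.array([-5.0, 5.0]))
        np.testing.assert_allclose(out, [1.0, 9.0])


class TestLagrangeInterpolation:
    def test_quadratic_through_three_knots(self):
        # knots (0,0),(1,1),(2,4) define y = x^2 in log-dose coordinates
        curve = make_curve([1.0, 10.0, 100.0], [0.0, 1.0, 4.0])
        assert interp_lagrange(curve, np.array([1.5]))[0] == pytest.approx(2.25)

    def test_passes_through_knots(self, printed_curve):
        from drcbridge.monotherapy import log_doses

        x, y = log_doses(printed_curve)
        np.testing.assert_allclose(interp_lagrange(printed_curve, x), y,
                                   atol=1e-9)

    def test_two_knots_reduce_to_linear(self):
        curve = make_curve([0.1, 10.0], [2.0, 8.0])
        grid = np.linspace(-1, 1, 10)
        np.testing.assert_allclose(interp_lagrange(curve, grid),
                                   interp_linear(curve, grid), atol=1e-12)

    @settings(deadline=None, max_examples=10, derandomize=True)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_matches_bruteforce_polynomial_evaluation(self, seed):
        """Product-formula oracle on random knot sets of up to 10 knots."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 11))
        doses = np.sort(10 ** rng.uniform(-2, 1, size=n))
        while np.any(np.diff(doses) <= 0):  # enforce strict increase
            doses = np.sort(10 ** rng.uniform(-2, 1, size=n))
        responses = rng.uniform(-10, 110, size=n)
        curve = make_curve(doses, responses)
        x = np.log10(doses)
        grid = np.linspace(x[0], x[-1], 10)

        def oracle(q):
            total = 0.0
            for j in range(n):
                term = responses[j]
                for k in range(n):
                    if k != j:
                        term *= (q - x[k]) / (x[j] - x[k])
                total += term
            return total

        span = responses.max() - responses.min()
        expected = np.clip([oracle(q) for q in grid],
                           responses.min() - 0.5 * span,
                           responses.max() + 0.5 * span)
        np.testing.assert_allclose(interp_lagrange(curve, grid), expected,
                                   rtol=1e-8, atol=1e-6)

    def test_clipping_bounds_runge_oscillation(self):
        doses = np.logspace(-2, 1, 10)
        responses = np.zeros(10)
        responses[::2] = 100.0  # worst-case alternation
        curve = make_curve(doses, responses)
        out = interp_lagrange(curve, np.linspace(-2, 1, 50))
        assert out.min() >= -50.0 - 1e-9
        assert out.max() <= 150.0 + 1e-9


class TestLL4:
    def test_value_at_ic50_is_anchor_midpoint(self):
        params = LL4Params(a=30.0, b=100.0, c=0.0, d=1.0)
        curve = make_curve([0.01, 100.0], [0.0, 100.0])
        out = interp_ll4(curve, np.array([np.log10(params.d)]), params)
        assert out[0] == pytest.approx(50.0)

    def test_zero_slope_gives_constant_midpoint(self):
        params = LL4Params(a=0.0, b=80.0, c=20.0, d=0.5)
        curve = make_curve([0.01, 100.0], [20.0, 80.0])
        out = interp_ll4(curve, np.linspace(-2, 2, 7), params)
        np.testing.assert_allclose(out, 50.0)

    def test_asymptote_for_large_negative_slope(self):
        # a < 0: the curve decreases with dose, approaching c = 0 at high dose
        params = LL4Params(a=-50.0, b=100.0, c=0.0, d=1.0)
        curve = make_curve([0.01, 100.0], [100.0, 0.0])
        far_right = interp_ll4(curve, np.array([10.0]), params)[0]
        far_left = interp_ll4(curve, np.array([-10.0]), params)[0]
        assert far_right == pytest.approx(0.0, abs=1e-9)
        assert far_left == pytest.approx(100.0, abs=1e-9)

    @settings(deadline=None, max_examples=1000, derandomize=True)
    @given(
        a=st.floats(-100, 100, allow_nan=False),
        b=st.floats(-10, 110, allow_nan=False),
        span=st.floats(0, 100, allow_nan=False),
        log_d=st.floats(-3, 2, allow_nan=False),
    )
    def test_midpoint_identity_property(self, a, b, span, log_d):
        """y(log10 d) = (b+c)/2 for any parameter draw."""
        c = b - span
        params = LL4Params(a=a, b=b, c=c, d=10 ** log_d)
        curve = make_curve([1e-4, 1e3], [c, b])
        out = interp_ll4(curve, np.array([log_d]), params)
        assert out[0] == pytest.approx((b + c) / 2.0, rel=1e-9, abs=1e-9)

    def test_natural_log_switch_changes_steepness_not_midpoint(self):
        params = LL4Params(a=10.0, b=100.0, c=0.0, d=1.0)
        curve = make_curve([0.01, 100.0], [0.0, 100.0])
        grid = np.array([np.log10(params.d), 1.0])
        log10_out = interp_ll4(curve, grid, params, HarmonizationConfig())
        ln_out = interp_ll4(curve, grid, params,
                            HarmonizationConfig(ll4_natural_log=True))
        assert log10_out[0] == pytest.approx(ln_out[0])  # midpoint unchanged
        assert abs(ln_out[1] - 50.0) > abs(log10_out[1] - 50.0)  # steeper


class TestBuildLL4Params:
    def test_anchors_from_monotone_curve(self):
        curve = make_curve([0.1, 1.0, 10.0], [0.0, 50.0, 100.0])
        params = build_ll4_params(curve, ic50=1.0)
        assert params.a == pytest.approx(50.0)
        assert params.b == pytest.approx(100.0)
        assert params.c == pytest.approx(0.0)
        assert params.d == pytest.approx(1.0)
        assert not params.ic50_fallback

    def test_flat_curve_zero_slope(self):
        curve = make_curve([0.1, 1.0, 10.0], [20.0, 20.0, 20.0])
        params = build_ll4_params(curve, ic50=1.0)
        assert params.a == 0.0
        assert params.b == params.c == 20.0

    def test_undefined_ic50_falls_back_to_geometric_mean(self):
        # responses never positive: half-max never crossed
        curve = make_curve([0.1, 10.0], [-5.0, -1.0])
        params = build_ll4_params(curve)
        assert params.ic50_fallback
        assert params.d == pytest.approx(np.sqrt(0.1 * 10.0))


class TestBaselineEncoding:
    def test_printed_example_padded_vectors(self, printed_curve):
        """The reference 5-dose example pads doses and responses to ten."""
        out = encode_drc_baseline(printed_curve, HarmonizationConfig())
        expected = [0, 0.075, 0.225, 0.675, 2, -1, -1, -1, -1, -1,
                    0, -0.48, -0.47, 4.32, 20.72, -1, -1, -1, -1, -1]
        np.testing.assert_array_equal(out, expected)

    def test_ten_dose_curve_has_no_padding(self):
        doses = np.linspace(0.1, 1.0, 10)
        curve = make_curve(doses, np.linspace(0, 90, 10))
        out = encode_drc_baseline(curve)
        assert -1.0 not in out[:10]
        np.testing.assert_allclose(out[:10], doses)

    @pytest.mark.parametrize("n", [2, 5, 10])
    def test_pad_count_and_fixed_output_length(self, n):
        curve = make_curve(np.linspace(0.1, 1.0, n), np.zeros(n) + 1.0)
        out = encode_drc_baseline(curve)
        assert len(out) == 20
        assert np.sum(out == -1.0) == 2 * (10 - n)

    def test_longer_than_cap_errors(self):
        curve = make_curve(np.linspace(0.1, 1.0, 5), np.zeros(5))
        with pytest.raises(ValueError, match="pad_cap"):
            encode_drc_baseline(curve, HarmonizationConfig(pad_cap=4))


class TestImputationEncoding:
    def test_single_method_equals_linear(self, printed_curve):
        cfg = HarmonizationConfig(methods=("linear",))
        out = encode_drc_imputation(printed_curve, None, cfg)
        grid = log10_grid(printed_curve, cfg)
        np.testing.assert_allclose(out, interp_linear(printed_curve, grid, cfg))
        assert len(out) == 10

    def test_two_knots_linear_and_lagrange_halves_identical(self):
        curve = make_curve([0.1, 10.0], [0.0, 60.0])
        cfg = HarmonizationConfig(methods=("linear", "lagrange"))
        out = encode_drc_imputation(curve, None, cfg)
        np.testing.assert_allclose(out[:10], out[10:], atol=1e-12)

    def test_default_three_methods_give_thirty_values(self, printed_curve):
        out = encode_drc_imputation(printed_curve)
        assert len(out) == 30
        grid = log10_grid(printed_curve, HarmonizationConfig())
        np.testing.assert_allclose(
            out[:10], interp_linear(printed_curve, grid), atol=1e-12)

    def test_design_invariance_of_imputation_vs_baseline(self):
        """Noiseless curves from one Hill function on different designs:
        imputation encodings agree, baseline encodings do not."""
        emax, lec50, slope = 90.0, -0.5, 1.2
        lo, hi = 0.01, 10.0
        doses4 = np.logspace(np.log10(lo), np.log10(hi), 4)
        doses8 = np.logspace(np.log10(lo), np.log10(hi), 8)
        c4 = make_curve(doses4, hill_response(doses4, emax, lec50, slope))
        c8 = make_curve(doses8, hill_response(doses8, emax, lec50, slope))
        cfg = HarmonizationConfig(methods=("linear",))
        imp4 = encode_drc_imputation(c4, None, cfg)
        imp8 = encode_drc_imputation(c8, None, cfg)
        # piecewise-linear resampling error only (a few % of the response
        # span for a 4-knot chord); far below the baseline-encoding gap
        imp_gap = np.max(np.abs(imp4 - imp8))
        assert imp_gap < 5.0
        base4 = encode_drc_baseline(c4)
        base8 = encode_drc_baseline(c8)
        base_gap = np.max(np.abs(base4 - base8))
        assert base_gap > 10.0 * imp_gap
        # and the resampling error shrinks as the measured grid densifies
        doses6 = np.logspace(np.log10(lo), np.log10(hi), 6)
        c6 = make_curve(doses6, hill_response(doses6, emax, lec50, slope))
        imp6 = encode_drc_imputation(c6, None, cfg)
        assert np.max(np.abs(imp6 - imp8)) < imp_gap
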