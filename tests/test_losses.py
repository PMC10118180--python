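import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from corrloss import (
    CorrelationMaps,
    Curve,
    CurveGrid,
    CurveSeries,
    LossSpec,
    arss,
    async_2t2d,
    async_2t2d_fast,
    evaluate,
    ncc,
    phase_2t2d,
    phase_series_ses,
    rss,
    ses_series,
    srss,
    two_trace_maps,
    zncc,
)

TWO_LN_EPS = 2 * np.log(1e-10)


def curve(y, x=None):
    y = np.asarray(y, dtype=float)
    return Curve(CurveGrid(np.arange(y.size, dtype=float) if x is None else x), y)


def series(y):
    y = np.asarray(y, dtype=float)
    m, n = y.shape
    return CurveSeries(CurveGrid(np.arange(n, dtype=float)), np.arange(1.0, m + 1), y)


def random_curve_pair(rng, n=20):
    return curve(rng.normal(size=n)), curve(rng.normal(size=n))


def brute_force_async_sum(s, m):
    """O(N^2) oracle: full-matrix sum of squared two-trace asynchronous
    entries, from the entrywise definition."""
    s = np.asarray(s, dtype=float)
    m = np.asarray(m, dtype=float)
    total = 0.0
    for j in range(s.size):
        for k in range(s.size):
            total += (0.5 * (s[j] * m[k] - m[j] * s[k])) ** 2
    return total


class TestLossSpec:
    def test_rejects_odd_p(self):
        with pytest.raises(ValueError):
            LossSpec(family="ASYNC_2T2D", p=3)

    def test_rejects_bad_epsilon(self):
        with pytest.raises(ValueError):
            LossSpec(epsilon=0.0)

    def test_rejects_unknown_family(self):
        with pytest.raises(ValueError):
            LossSpec(family="HUBER")


class TestRss:
    def test_identity_zero(self):
        c = curve([1.0, 2.0, 3.0])
        assert rss(c, c).value == 0.0

    def test_hand_value(self):
        assert rss(curve([1.0, 2.0]), curve([0.0, 0.0])).value == 5.0

    def test_not_scale_invariant(self):
        c = curve([1.0, 2.0, 3.0])
        scaled = curve(1.1 * c.intensities)
        assert rss(scaled, c).value > 0.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            rss(curve([1.0, 2.0]), curve([1.0, 2.0, 3.0]))


class TestSrssArss:
    def make_maps(self, phi=None, psi=None):
        n = (phi if phi is not None else psi).shape[0]
        return CorrelationMaps(
            phi if phi is not None else np.zeros((n, n)),
            psi if psi is not None else np.zeros((n, n)),
            "hybrid-series",
        )

    def test_symmetric_phi_zero(self, rng):
        a = rng.normal(size=(4, 4))
        assert srss(self.make_maps(phi=a + a.T)).value == 0.0

    def test_srss_hand_value(self):
        assert srss(self.make_maps(phi=np.array([[1.0, 2.0], [0.0, 1.0]]))).value == 4.0

    def test_antisymmetric_psi_zero(self, rng):
        a = rng.normal(size=(4, 4))
        assert arss(self.make_maps(psi=a - a.T)).value == 0.0

    def test_arss_hand_value(self):
        assert arss(self.make_maps(psi=np.array([[0.0, 1.0], [0.0, 0.0]]))).value == 1.0


class TestSesSeries:
    def test_scaled_series_hits_floor(self, corrupted_series, truth_series):
        out = ses_series(corrupted_series, truth_series)
        assert out.value == pytest.approx(TWO_LN_EPS, abs=1e-6)
        s, a = out.components
        assert s < 1e-16 and a < 1e-16

    def test_identity_hits_floor(self, truth_series):
        assert ses_series(truth_series, truth_series).value == pytest.approx(
            TWO_LN_EPS, abs=1e-9
        )

    def test_perturbed_t_is_penalized(self, corrupted_series, shift_params):
        from corrloss import generate_series

        shifted = generate_series(
            shift_params,
            corrupted_series.grid,
            corrupted_series.t_values + 0.5,
        )
        assert ses_series(corrupted_series, shifted).value > TWO_LN_EPS + 1.0


class TestAsync2t2d:
    def test_proportional_zero(self):
        s = curve([1.0, 2.0, 3.0])
        for c in (0.5, 1.0, 7.3):
            m = curve(c * s.intensities)
            assert async_2t2d(s, m).value == pytest.approx(0.0, abs=1e-24)
            # the closed form subtracts two large products; allow round-off
            assert async_2t2d_fast(s, m).value == pytest.approx(0.0, abs=1e-10)

    def test_orthogonal_pair(self):
        s, m = curve([1.0, 0.0]), curve([0.0, 1.0])
        assert async_2t2d(s, m).value == pytest.approx(0.25)
        assert async_2t2d_fast(s, m).value == pytest.approx(0.5)

    def test_odd_p_rejected(self):
        s, m = curve([1.0, 0.0]), curve([0.0, 1.0])
        with pytest.raises(ValueError):
            async_2t2d(s, m, p=3)

    def test_fast_equals_brute_force_50_points(self, rng):
        s, m = random_curve_pair(rng, n=50)
        fast = async_2t2d_fast(s, m).value
        brute = brute_force_async_sum(s.intensities, m.intensities)
        assert fast == pytest.approx(brute, rel=1e-12)

    def test_oracle_equivalence_many_pairs(self, rng):
        # fast == 2 x triangle == brute-force full sum, 100 random pairs
        for _ in range(100):
            s, m = random_curve_pair(rng, n=12)
            fast = async_2t2d_fast(s, m).value
            tri = async_2t2d(s, m).value
            brute = brute_force_async_sum(s.intensities, m.intensities)
            assert fast == pytest.approx(2.0 * tri, rel=1e-10)
            assert fast == pytest.approx(brute, rel=1e-10)


class TestPhase2t2d:
    def test_proportional_zero(self):
        s = curve([1.0, 2.0, 3.0])
        assert phase_2t2d(s, curve(4.0 * s.intensities)).value == pytest.approx(
            0.0, abs=1e-12
        )
        assert phase_2t2d(s, s).value == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_pair(self):
        s, m = curve([1.0, 0.0]), curve([0.0, 1.0])
        # single off-diagonal angle saturates at pi/2 under regularization
        assert phase_2t2d(s, m).value == pytest.approx((np.pi / 2) ** 2, rel=1e-6)


class TestPhaseSeriesSes:
    def test_identity_zero(self, truth_series):
        assert phase_series_ses(truth_series, truth_series).value == 0.0

    def test_scaled_series_zero(self, truth_series, corrupted_series):
        val = phase_series_ses(corrupted_series, truth_series).value
        assert val == pytest.approx(0.0, abs=1e-12)

    def test_shifted_t_positive(self, corrupted_series, shift_params):
        from corrloss import generate_series

        shifted = generate_series(
            shift_params, corrupted_series.grid, corrupted_series.t_values + 0.5
        )
        assert phase_series_ses(corrupted_series, shifted).value > 1e-3


class TestNcc:
    def test_proportional_is_one(self):
        s = curve([1.0, 2.0, 3.0])
        assert ncc(s, curve(3.0 * s.intensities)).value == pytest.approx(1.0)

    def test_orthogonal_is_zero(self):
        assert ncc(curve([1.0, 0.0]), curve([0.0, 1.0])).value == 0.0

    def test_hand_value(self):
        assert ncc(curve([1.0, 2.0]), curve([2.0, 1.0])).value == pytest.approx(4 / 5)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            ncc(curve([0.0, 0.0]), curve([1.0, 2.0]))

    def test_link_to_fast_async(self, rng):
        # NCC^2 = 1 - 2*fast / (sum s^2 * sum m^2): algebraic identity
        for _ in range(50):
            s, m = random_curve_pair(rng, n=15)
            lhs = ncc(s, m).value ** 2
            denom = np.dot(s.intensities, s.intensities) * np.dot(
                m.intensities, m.intensities
            )
            rhs = 1.0 - 2.0 * async_2t2d_fast(s, m).value / denom
            assert lhs == pytest.approx(rhs, rel=1e-10, abs=1e-12)


class TestZncc:
    def test_affine_is_one(self):
        s = curve([1.0, 2.0, 3.0, 5.0])
        m = curve(2.0 * s.intensities + 7.0)
        assert zncc(s, m).value == pytest.approx(1.0)

    def test_anticorrelated(self):
        assert zncc(curve([1.0, 2.0, 3.0]), curve([3.0, 2.0, 1.0])).value == (
            pytest.approx(-1.0)
        )

    def test_identity(self):
        s = curve([1.0, 2.0, 5.0])
        assert zncc(s, s).value == pytest.approx(1.0)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            zncc(curve([1.0, 1.0]), curve([1.0, 2.0]))

    def test_strict_mode_prefactor(self):
        s = curve([1.0, 2.0, 3.0])
        assert zncc(s, s, strict=True).value == pytest.approx(3 / 4)

    @given(st.floats(0.1, 10.0), st.floats(-5.0, 5.0))
    @settings(max_examples=40)
    def test_offset_invariance(self, c, o):
        s = curve([1.0, 2.0, 4.0, 8.0])
        m = curve(c * s.intensities + o)
        assert zncc(s, m).value == pytest.approx(1.0, abs=1e-9)


class TestScaleInvariance:
    SCALE_FREE = (
        "SES_SERIES",
        "ASYNC_2T2D",
        "ASYNC_2T2D_FAST",
        "PHASE_2T2D",
        "PHASE_SERIES",
        "NEG_NCC",
        "NEG_ZNCC",
    )

    @pytest.mark.parametrize("family", SCALE_FREE)
    @pytest.mark.parametrize("factor", [0.3, 1.0, 1.1, 5.0])
    def test_minimum_attained_under_scaling(self, family, factor, truth_series):
        spec = LossSpec(family=family)
        scaled = CurveSeries(
            truth_series.grid,
            truth_series.t_values,
            factor * truth_series.intensities,
        )
        if family in ("SES_SERIES", "PHASE_SERIES"):
            val = evaluate(spec, scaled, truth_series).value
            floor = TWO_LN_EPS if family == "SES_SERIES" else 0.0
            assert val == pytest.approx(floor, abs=1e-6)
        else:
            s = truth_series.curve(2)
            m = Curve(s.grid, factor * s.intensities)
            val = evaluate(spec, m, s).value
            floor = -1.0 if family in ("NEG_NCC", "NEG_ZNCC") else 0.0
            assert val == pytest.approx(floor, abs=1e-7)

    def test_rss_is_not(self, truth_series):
        s = truth_series.curve(2)
        m = Curve(s.grid, 1.1 * s.intensities)
        assert evaluate(LossSpec(family="RSS"), m, s).value > 1e-6


class TestMonotonePenalty:
    """Each per-curve loss, swept over a dense t grid against the corrupted
    third curve, is minimized at the generating t (scale-free families) or
    near 1.1x it as modified by the shift coupling (RSS)."""

    T_GRID = np.linspace(2.0, 4.0, 401)

    def sweep(self, family, corrupted_series, shift_params):
        from corrloss import cauchy_curve

        measured = corrupted_series.curve(2)  # t_true = 3
        spec = LossSpec(family=family)
        vals = [
            evaluate(
                spec, measured, cauchy_curve(shift_params, measured.grid, t)
            ).value
            for t in self.T_GRID
        ]
        return self.T_GRID[int(np.argmin(vals))]

    @pytest.mark.parametrize(
        "family", ["ASYNC_2T2D", "ASYNC_2T2D_FAST", "PHASE_2T2D", "NEG_NCC", "NEG_ZNCC"]
    )
    def test_scale_free_minimized_at_truth(
        self, family, corrupted_series, shift_params
    ):
        assert self.sweep(family, corrupted_series, shift_params) == pytest.approx(
            3.0, abs=0.01
        )

    def test_rss_minimized_near_inflated_t(self, corrupted_series, shift_params):
        # independently cross-checks the fitted value ~3.298 for t_true = 3
        assert self.sweep("RSS", corrupted_series, shift_params) == pytest.approx(
            3.298, abs=0.01
        )


class TestEvaluateDispatch:
    def test_series_family_needs_series(self, truth_series):
        c = truth_series.curve(0)
        with pytest.raises(TypeError):
            evaluate(LossSpec(family="SES_SERIES"), c, c)

    def test_curve_family_rejects_series(self, truth_series):
        with pytest.raises(TypeError):
            evaluate(LossSpec(family="NEG_NCC"), truth_series, truth_series)

    def test_rss_accepts_series(self, truth_series, corrupted_series):
        v = evaluate(LossSpec(family="RSS"), corrupted_series, truth_series)
        expected = np.sum(
            (corrupted_series.intensities - truth_series.intensities) ** 2
        )
        assert v.value == pytest.approx(expected)

    def test_mean_center_flag(self, truth_series):
        # centering removes any per-column offset shared across curves
        spec = LossSpec(family="RSS", mean_center=True)
        shifted = CurveSeries(
            truth_series.grid,
            truth_series.t_values,
            truth_series.intensities + 5.0,
        )
        assert evaluate(spec, shifted, truth_series).value == pytest.approx(0.0)

    def test_exp_transform_flag(self):
        # exponential transform turns a common additive offset into a
        # multiplicative factor, which NCC then ignores
        g = CurveGrid(np.arange(5.0))
        s = Curve(g, np.array([0.1, 0.5, 1.0, 0.5, 0.1]))
        m = Curve(g, s.intensities + 0.7)
        spec = LossSpec(family="NEG_NCC", exp_transform=True)
        assert evaluate(spec, s, m).value == pytest.approx(-1.0)
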