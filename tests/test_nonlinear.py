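import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from etqrs.nonlinear import (
    TransformParams,
    TransformedSignal,
    abs_accumulate,
    accumulate,
    exponential_transform,
    qrs_width_samples,
    square_accumulate,
)
from etqrs.preprocess import DifferencedSignal

FS = 360.0


def d_sig(values):
    return DifferencedSignal(np.asarray(values, dtype=float), FS)


def brute_force_sum(e, half_q):
    """Literal windowed sum with zero padding — the oracle."""
    n = len(e)
    out = np.zeros(n)
    for i in range(n):
        for j in range(i - half_q, i + half_q + 1):
            if 0 <= j < n:
                out[i] += e[j]
    return out


class TestParams:
    def test_q_default_at_360(self):
        assert qrs_width_samples(360.0) == 43
        p = TransformParams.for_fs(360.0)
        assert p.q == 43
        assert p.half_q == 21

    def test_q_scales_with_fs(self):
        assert qrs_width_samples(250.0) == 30

    def test_invalid(self):
        with pytest.raises(ValueError):
            TransformParams(0)
        with pytest.raises(ValueError):
            TransformParams(43, mode="cubic")


class TestExponentialTransform:
    def test_zero_maps_to_zero(self):
        p = TransformParams.for_fs(FS)
        out = exponential_transform(d_sig([0.0]), p)
        assert out.values[0] == 0.0

    def test_exact_at_one(self):
        # closed form: 1 * exp(-1) = 1/e
        p = TransformParams.for_fs(FS, mode="exact")
        out = exponential_transform(d_sig([1.0]), p)
        np.testing.assert_allclose(out.values[0], 1.0 / np.e, rtol=1e-12)

    def test_taylor_arithmetic(self):
        p = TransformParams.for_fs(FS, mode="taylor")
        out = exponential_transform(d_sig([0.1]), p)
        np.testing.assert_allclose(out.values[0], 0.09, rtol=1e-12)

    def test_polarity_removed(self):
        p = TransformParams.for_fs(FS, mode="taylor")
        neg = exponential_transform(d_sig([-0.1]), p)
        np.testing.assert_allclose(neg.values[0], 0.09, rtol=1e-12)

    @given(st.floats(-5, 5))
    @settings(max_examples=100, deadline=None)
    def test_sign_symmetry(self, x):
        for mode in ("exact", "taylor"):
            p = TransformParams.for_fs(FS, mode=mode)
            a = exponential_transform(d_sig([x]), p).values[0]
            b = exponential_transform(d_sig([-x]), p).values[0]
            assert a == b

    def test_exact_range_invariant(self, rng):
        p = TransformParams.for_fs(FS, mode="exact")
        out = exponential_transform(d_sig(rng.normal(0, 3, 1000)), p)
        assert np.all(out.values >= 0)
        assert np.all(out.values <= 1 / np.e + 1e-12)

    def test_taylor_clamped_nonnegative(self):
        p = TransformParams.for_fs(FS, mode="taylor", clamp_negative=True)
        out = exponential_transform(d_sig([2.0]), p)
        assert out.values[0] == 0.0

    def test_taylor_unclamped_goes_negative(self):
        p = TransformParams.for_fs(FS, mode="taylor", clamp_negative=False)
        out = exponential_transform(d_sig([2.0]), p)
        assert out.values[0] == pytest.approx(-2.0)

    def test_exact_maximized_at_one_monotone_below(self):
        p = TransformParams.for_fs(FS, mode="exact")
        xs = np.linspace(0, 1, 101)
        ys = exponential_transform(d_sig(xs), p).values
        assert np.all(np.diff(ys) > 0)
        big = exponential_transform(d_sig([1.5, 3.0]), p).values
        assert np.all(big < 1 / np.e)

    @given(st.floats(0.001, 0.499), st.floats(0.001, 0.499))
    @settings(max_examples=100, deadline=None)
    def test_compression_narrows_gaps(self, u, v):
        u, v = sorted((u, v))
        if v - u < 1e-9:
            return
        p = TransformParams.for_fs(FS, mode="taylor")
        tu = exponential_transform(d_sig([u]), p).values[0]
        tv = exponential_transform(d_sig([v]), p).values[0]
        assert tv - tu < v - u

    def test_exact_taylor_agree_to_first_order(self):
        # |exact - taylor| = |d|*|e^{-|d|} - 1 + |d|| <= 0.6|d|^3 on [0, 0.3]
        p_e = TransformParams.for_fs(FS, mode="exact")
        p_t = TransformParams.for_fs(FS, mode="taylor")
        xs = np.linspace(-0.3, 0.3, 601)
        ex = exponential_transform(d_sig(xs), p_e).values
        ty = exponential_transform(d_sig(xs), p_t).values
        bound = 0.6 * np.abs(xs) ** 3 + 1e-15
        assert np.all(np.abs(ex - ty) <= bound)


class TestAccumulate:
    def test_all_ones_interior(self):
        p = TransformParams(43)
        e = TransformedSignal(np.ones(200))
        s = accumulate(e, p)
        assert len(s) == 200
        np.testing.assert_allclose(s.values[21:-21], 43.0)

    def test_impulse_gives_plateau(self):
        p = TransformParams(43)
        e = np.zeros(101)
        e[50] = 1.0
        s = accumulate(TransformedSignal(e), p)
        np.testing.assert_array_equal(s.values[50 - 21 : 50 + 22], 1.0)
        assert s.values[50 - 22] == 0.0
        assert s.values[50 + 22] == 0.0

    def test_brute_force_oracle(self, rng):
        p = TransformParams(43)
        e = rng.uniform(0, 1, size=300)
        s = accumulate(TransformedSignal(e), p)
        np.testing.assert_allclose(s.values, brute_force_sum(e, 21),
                                   rtol=1e-10, atol=1e-10)

    @given(st.integers(1, 9))
    @settings(max_examples=20, deadline=None)
    def test_oracle_various_widths(self, q):
        rng = np.random.default_rng(q)
        e = rng.uniform(0, 1, size=50)
        p = TransformParams(q)
        s = accumulate(TransformedSignal(e), p)
        np.testing.assert_allclose(s.values, brute_force_sum(e, q // 2),
                                   rtol=1e-10, atol=1e-10)

    def test_linearity(self, rng):
        p = TransformParams(43)
        a = rng.uniform(0, 1, 100)
        b = rng.uniform(0, 1, 100)
        sa = accumulate(TransformedSignal(a), p).values
        sb = accumulate(TransformedSignal(b), p).values
        sab = accumulate(TransformedSignal(a + 2 * b), p).values
        np.testing.assert_allclose(sab, sa + 2 * sb, rtol=1e-10)

    def test_translation_equivariance(self, rng):
        p = TransformParams(7)
        e = np.zeros(60)
        e[10:20] = rng.uniform(0, 1, 10)
        shifted = np.roll(e, 15)
        s = accumulate(TransformedSignal(e), p).values
        s_shift = accumulate(TransformedSignal(shifted), p).values
        np.testing.assert_allclose(np.roll(s, 15)[20:50], s_shift[20:50],
                                   atol=1e-12)

    def test_feature_bounds_invariant(self, rng):
        p = TransformParams(43, mode="exact")
        d = d_sig(rng.normal(0, 1, 500))
        e = exponential_transform(d, p)
        s = accumulate(e, p)
        assert np.all(s.values >= 0)
        assert np.all(s.values <= p.q * np.max(e.values) + 1e-12)


class TestComparisonTransforms:
    def test_abs_center_value(self):
        p = TransformParams(3)  # half_q = 1
        s = abs_accumulate(d_sig([1.0, -1.0, 1.0]), p)
        assert s.values[1] == 3.0

    def test_abs_zero(self):
        p = TransformParams(43)
        s = abs_accumulate(d_sig(np.zeros(50)), p)
        np.testing.assert_array_equal(s.values, 0.0)

    def test_abs_oracle(self, rng):
        p = TransformParams(43)
        d = rng.normal(size=200)
        s = abs_accumulate(d_sig(d), p)
        np.testing.assert_allclose(s.values, brute_force_sum(np.abs(d), 21),
                                   rtol=1e-10, atol=1e-10)

    def test_square_window_sums(self):
        p = TransformParams(3)
        s = square_accumulate(d_sig([2.0, 0.0, 0.0]), p)
        np.testing.assert_allclose(s.values, [4.0, 4.0, 0.0])

    def test_square_homogeneity(self, rng):
        p = TransformParams(43)
        d = rng.normal(size=100)
        s1 = square_accumulate(d_sig(d), p).values
        s3 = square_accumulate(d_sig(3 * d), p).values
        np.testing.assert_allclose(s3, 9 * s1, rtol=1e-10)

    def test_square_oracle(self, rng):
        p = TransformParams(43)
        d = rng.normal(size=200)
        s = square_accumulate(d_sig(d), p)
        np.testing.assert_allclose(s.values, brute_force_sum(d * d, 21),
                                   rtol=1e-10, atol=1e-10)
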