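"""Unit and property tests for the pooling and attention primitives."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bilinearcnn.core_ops import (
    DimensionError,
    SEBlockParams,
    ValidationError,
    bilinear_pool,
    bilinear_pool_fast,
    l2_normalize,
    se_apply,
    se_excite,
    se_squeeze,
    signed_sqrt,
)


def bilinear_pool_reference(a, b):
    """Independent triple-loop oracle: outer products summed per location."""
    ca, h, w = a.shape
    cb = b.shape[0]
    out = np.zeros((ca, cb))
    for i in range(h):
        for j in range(w):
            for p in range(ca):
                for q in range(cb):
                    out[p, q] += a[p, i, j] * b[q, i, j]
    return out.reshape(-1)


class TestBilinearPool:
    def test_worked_two_channel_example(self):
        # a(l1)=(1,3), a(l2)=(2,4); b(l1)=(5,7), b(l2)=(6,8)
        a = np.array([[[1.0, 2.0]], [[3.0, 4.0]]])
        b = np.array([[[5.0, 6.0]], [[7.0, 8.0]]])
        result = bilinear_pool(a, b).reshape(2, 2)
        np.testing.assert_allclose(result, [[17.0, 23.0], [39.0, 53.0]])

    def test_zero_maps_give_zero_vector(self):
        out = bilinear_pool(np.zeros((3, 4, 5)), np.zeros((2, 4, 5)))
        assert out.shape == (6,)
        assert np.all(out == 0)

    def test_single_location_single_channel_squares_value(self):
        v = 3.7
        out = bilinear_pool(np.full((1, 1, 1), v), np.full((1, 1, 1), v))
        np.testing.assert_allclose(out, [v**2])

    def test_matches_triple_loop_oracle_on_random_instances(self, rng):
        for _ in range(30):
            ca, cb = rng.integers(1, 9, size=2)
            h, w = rng.integers(1, 6, size=2)
            a = rng.normal(size=(ca, h, w))
            b = rng.normal(size=(cb, h, w))
            expected = bilinear_pool_reference(a, b)
            got = bilinear_pool(a, b)
            np.testing.assert_allclose(got, expected, rtol=1e-6, atol=1e-9)

    def test_mismatched_spatial_dims_rejected(self):
        with pytest.raises(DimensionError):
            bilinear_pool(np.zeros((2, 3, 3)), np.zeros((2, 3, 4)))

    def test_non_finite_input_rejected(self):
        bad = np.full((1, 2, 2), np.nan)
        with pytest.raises(ValidationError):
            bilinear_pool(bad, np.zeros((1, 2, 2)))

    @given(st.integers(0, 2**31 - 1))
    def test_linear_in_each_argument(self, seed):
        r = np.random.default_rng(seed)
        a = r.normal(size=(3, 2, 2))
        b = r.normal(size=(4, 2, 2))
        alpha = float(r.normal())
        np.testing.assert_allclose(
            bilinear_pool(alpha * a, b), alpha * bilinear_pool(a, b),
            rtol=1e-9, atol=1e-9,
        )
        np.testing.assert_allclose(
            bilinear_pool(a, alpha * b), alpha * bilinear_pool(a, b),
            rtol=1e-9, atol=1e-9,
        )


class TestBilinearPoolFast:
    def test_single_location_outer_product(self):
        f = np.array([2.0, 3.0]).reshape(2, 1, 1)
        np.testing.assert_allclose(
            bilinear_pool_fast(f).reshape(2, 2), [[4.0, 6.0], [6.0, 9.0]]
        )

    def test_equals_two_stream_with_same_map(self, rng):
        f = rng.normal(size=(5, 3, 4))
        np.testing.assert_array_equal(
            bilinear_pool_fast(f), bilinear_pool(f, f)
        )

    def test_reshaped_matrix_symmetric_psd(self, rng):
        f = rng.normal(size=(6, 4, 4))
        m = bilinear_pool_fast(f).reshape(6, 6)
        np.testing.assert_allclose(m, m.T, rtol=1e-12)
        eigvals = np.linalg.eigvalsh(m)
        assert eigvals.min() >= -1e-9 * max(1.0, eigvals.max())

    @given(st.integers(0, 2**31 - 1))
    def test_orderless_under_spatial_permutation(self, seed):
        r = np.random.default_rng(seed)
        f = r.normal(size=(4, 3, 3))
        perm = r.permutation(9)
        shuffled = f.reshape(4, 9)[:, perm].reshape(4, 3, 3)
        np.testing.assert_allclose(
            bilinear_pool_fast(f), bilinear_pool_fast(shuffled),
            rtol=1e-6, atol=1e-9,
        )


class TestNormalizationChain:
    def test_signed_sqrt_analytic_values(self):
        np.testing.assert_array_equal(
            signed_sqrt([4.0, -9.0, 0.0]), [2.0, -3.0, 0.0]
        )
        np.testing.assert_array_equal(signed_sqrt([1.0]), [1.0])
        np.testing.assert_allclose(signed_sqrt(signed_sqrt([16.0])), [2.0])

    def test_signed_sqrt_preserves_sign_pattern(self, rng):
        v = rng.normal(size=50)
        assert np.array_equal(np.sign(signed_sqrt(v)), np.sign(v))

    def test_l2_normalize_cases(self):
        np.testing.assert_allclose(l2_normalize([3.0, 4.0]), [0.6, 0.8])
        unit = np.array([0.0, 1.0])
        np.testing.assert_allclose(l2_normalize(unit), unit)
        zero = np.zeros(4)
        out = l2_normalize(zero)
        assert np.all(np.isfinite(out)) and np.all(out == 0)

    def test_chain_produces_unit_norm(self, rng):
        for _ in range(200):
            v = rng.normal(size=rng.integers(1, 64)) * 10.0 ** rng.integers(-3, 4)
            n = np.linalg.norm(l2_normalize(signed_sqrt(v)))
            if np.linalg.norm(v) >= 1e-12:
                assert abs(n - 1.0) < 1e-6


def se_excite_reference(s, w1, w2):
    """Scalar-loop evaluation of sigmoid(W2 @ relu(W1 @ s))."""
    hidden = []
    for row in w1:
        acc = sum(float(a) * float(b) for a, b in zip(row, s))
        hidden.append(max(acc, 0.0))
    out = []
    for row in w2:
        acc = sum(float(a) * float(b) for a, b in zip(row, hidden))
        out.append(1.0 / (1.0 + np.exp(-acc)))
    return np.array(out)


class TestSEBlock:
    def test_squeeze_is_channel_mean(self):
        np.testing.assert_allclose(se_squeeze(np.full((3, 5, 7), 5.0)),
                                   [5.0, 5.0, 5.0])
        fmap = np.array([[[1.0, 2.0], [3.0, 4.0]]])
        np.testing.assert_allclose(se_squeeze(fmap), [2.5])
        assert np.all(se_squeeze(np.zeros((2, 3, 3))) == 0)

    def test_zero_weights_gate_at_half(self, rng):
        c, r = 8, 4
        params = SEBlockParams(np.zeros((c // r, c)), np.zeros((c, c // r)), r)
        np.testing.assert_allclose(se_excite(rng.normal(size=c), params),
                                   np.full(c, 0.5))
        params2 = SEBlockParams(rng.normal(size=(c // r, c)),
                                rng.normal(size=(c, c // r)), r)
        np.testing.assert_allclose(se_excite(np.zeros(c), params2),
                                   np.full(c, 0.5))

    def test_excite_matches_scalar_oracle(self, rng):
        for _ in range(20):
            r = int(rng.choice([1, 2, 4]))
            c = r * int(rng.integers(1, 5))
            w1 = rng.normal(size=(c // r, c))
            w2 = rng.normal(size=(c, c // r))
            s = rng.normal(size=c)
            got = se_excite(s, SEBlockParams(w1, w2, r))
            np.testing.assert_allclose(got, se_excite_reference(s, w1, w2),
                                       atol=1e-10)

    def test_excite_output_strictly_inside_unit_interval(self, rng):
        c, r = 16, 4
        params = SEBlockParams(0.3 * rng.normal(size=(c // r, c)),
                               0.3 * rng.normal(size=(c, c // r)), r)
        e = se_excite(rng.normal(size=c), params)
        assert np.all(e > 0) and np.all(e < 1)

    def test_apply_scales_channels(self, rng):
        fmap = rng.normal(size=(2, 3, 3))
        np.testing.assert_array_equal(se_apply(fmap, [1.0, 1.0]), fmap)
        assert np.all(se_apply(fmap, [0.0, 0.0]) == 0)
        out = se_apply(fmap, [2.0, 0.5])
        np.testing.assert_allclose(out[0], 2 * fmap[0])
        np.testing.assert_allclose(out[1], 0.5 * fmap[1])

    def test_shape_mismatches_rejected(self, rng):
        with pytest.raises(DimensionError):
            SEBlockParams(np.zeros((2, 8)), np.zeros((8, 3)), 4)
        with pytest.raises(DimensionError):
            se_apply(rng.normal(size=(2, 3, 3)), [1.0, 1.0, 1.0])
        params = SEBlockParams(np.zeros((2, 8)), np.zeros((8, 2)), 4)
        with pytest.raises(DimensionError):
            se_excite(np.zeros(5), params)
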