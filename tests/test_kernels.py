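import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mediabo.kernels import (
    JITTER,
    KernelParams,
    categorical_overlap,
    gram,
    matern,
    matern_bessel,
    matern_from_distance,
    mixed_kernel,
    ohe_baseline,
)


class TestMatern:
    def test_zero_distance_is_one(self):
        x = np.array([[0.3, 0.7]])
        assert matern(x, x, np.array([1.0, 1.0]), 1.5)[0, 0] == pytest.approx(1.0)

    @pytest.mark.parametrize("nu, theta, d", [(1.5, 1.0, 1.0), (2.5, 2.0, 2.0)])
    def test_closed_form_values(self, nu, theta, d):
        # frozen from the nu=1.5 / nu=2.5 closed forms at scaled distance d/theta
        r = d / theta
        if nu == 1.5:
            expected = (1 + np.sqrt(3) * r) * np.exp(-np.sqrt(3) * r)
        else:
            expected = (1 + np.sqrt(5) * r + 5 * r**2 / 3) * np.exp(-np.sqrt(5) * r)
        got = matern(np.array([[0.0]]), np.array([[d]]), np.array([theta]), nu)[0, 0]
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(matern_bessel(d, theta, nu), abs=1e-8)

    @pytest.mark.parametrize("nu", [1.5, 2.5])
    def test_closed_form_matches_bessel_oracle_on_grid(self, nu):
        """Closed forms agree with the Gamma/Bessel definition to 1e-8."""
        for d in np.linspace(0.01, 5.0, 40):
            assert matern_from_distance(d, nu) == pytest.approx(
                matern_bessel(d, 1.0, nu), abs=1e-8
            )

    def test_strictly_decreasing_in_distance(self):
        ds = np.linspace(0.0, 3.0, 50)
        vals = matern_from_distance(ds, 2.5)
        assert np.all(np.diff(vals) < 0)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            matern(np.array([[0.0, 1.0]]), np.array([[0.0]]), np.array([1.0, 1.0]), 1.5)


class TestCategoricalOverlap:
    def test_single_variable_match_and_mismatch(self):
        assert categorical_overlap([[0]], [[0]], 1.0)[0, 0] == 1.0
        assert categorical_overlap([[0]], [[1]], 1.0)[0, 0] == 0.0

    def test_partial_overlap_scales_by_c(self):
        assert categorical_overlap([[0, 1]], [[0, 2]], 0.8)[0, 0] == pytest.approx(0.4)

    def test_self_similarity_equals_sigma(self):
        h = np.array([[0, 3, 1]])
        assert categorical_overlap(h, h, 0.7)[0, 0] == pytest.approx(0.7)

    def test_monotone_in_mismatches(self):
        a = np.array([[0, 0, 0]])
        vals = [categorical_overlap(a, [[0, 0, 0]], 1.0)[0, 0],
                categorical_overlap(a, [[1, 0, 0]], 1.0)[0, 0],
                categorical_overlap(a, [[1, 1, 0]], 1.0)[0, 0],
                categorical_overlap(a, [[1, 1, 1]], 1.0)[0, 0]]
        assert vals == sorted(vals, reverse=True)

    def test_c_zero_is_undefined(self):
        with pytest.raises(ValueError):
            categorical_overlap(np.zeros((1, 0)), np.zeros((1, 0)), 1.0, c=0)


class TestMixedKernel:
    def params(self, alpha, sigma=1.0):
        return KernelParams(theta=np.array([1.0]), nu=2.5, sigma_cat=sigma, alpha=alpha)

    def test_alpha_extremes_give_product_and_sum(self):
        x, h = np.array([[0.0]]), np.array([[0]])
        x2, h2 = np.array([[0.5]]), np.array([[0]])
        kc = matern(x, x2, np.array([1.0]), 2.5)[0, 0]
        assert mixed_kernel(x, h, x2, h2, self.params(1.0))[0, 0] == pytest.approx(kc)
        assert mixed_kernel(x, h, x2, h2, self.params(0.0))[0, 0] == pytest.approx(1.0 + kc)

    def test_midpoint_arithmetic(self):
        # k_cat = k_cont = 1 at identical points: 0.5*1 + 0.5*2 = 1.5
        x, h = np.array([[0.2]]), np.array([[1]])
        assert mixed_kernel(x, h, x, h, self.params(0.5))[0, 0] == pytest.approx(1.5)

    @given(st.floats(0.0, 1.0))
    @settings(max_examples=30, deadline=None)
    def test_bracketed_by_product_and_sum(self, alpha):
        x, h = np.array([[0.1]]), np.array([[0]])
        x2, h2 = np.array([[0.9]]), np.array([[0]])
        prod = mixed_kernel(x, h, x2, h2, self.params(1.0))[0, 0]
        tot = mixed_kernel(x, h, x2, h2, self.params(0.0))[0, 0]
        mid = mixed_kernel(x, h, x2, h2, self.params(alpha))[0, 0]
        assert min(prod, tot) - 1e-12 <= mid <= max(prod, tot) + 1e-12

    def test_symmetry(self, rng):
        x = rng.uniform(size=(6, 2))
        h = rng.integers(0, 3, size=(6, 2))
        p = KernelParams(theta=np.array([0.4, 0.8]), sigma_cat=0.6, alpha=0.3)
        K = mixed_kernel(x, h, x, h, p)
        assert np.allclose(K, K.T, atol=1e-12)


class TestGram:
    def test_single_continuous_point(self):
        K = gram(np.array([[0.5]]), np.zeros((1, 0), dtype=int),
                 KernelParams(theta=np.array([1.0])))
        assert K.shape == (1, 1) and K[0, 0] == pytest.approx(1.0, abs=1e-6)

    def test_random_mixed_design_is_psd(self, rng):
        x = rng.uniform(size=(50, 3))
        h = rng.integers(0, 5, size=(50, 2))
        p = KernelParams(theta=np.array([0.3, 0.5, 0.7]), sigma_cat=1.2, alpha=0.4)
        K = gram(x, h, p)
        assert np.min(np.linalg.eigvalsh(K)) >= -1e-8

    def test_noise_inflates_diagonal_only(self, rng):
        x = rng.uniform(size=(5, 1))
        h = np.zeros((5, 0), dtype=int)
        p = KernelParams(theta=np.array([1.0]), noise_variance=0.25)
        K0 = gram(x, h, p, include_noise=False)
        K1 = gram(x, h, p, include_noise=True)
        assert np.allclose(np.diag(K1) - np.diag(K0), 0.25)
        off = ~np.eye(5, dtype=bool)
        assert np.allclose(K0[off], K1[off])


class TestOHEBaseline:
    NCAT = (4,)

    def test_identical_points_are_one(self):
        x, h = np.array([[0.1, 0.2]]), np.array([[2]])
        theta = np.ones(2 + 4)
        assert ohe_baseline(x, h, x, h, theta, 2.5, self.NCAT)[0, 0] == pytest.approx(1.0)

    def test_category_flip_is_sqrt2_distance(self):
        x = np.array([[0.3, 0.6]])
        theta = np.ones(6)
        got = ohe_baseline(x, [[0]], x, [[3]], theta, 2.5, self.NCAT)[0, 0]
        assert got == pytest.approx(matern_from_distance(np.sqrt(2.0), 2.5), abs=1e-12)

    def test_category_order_irrelevant(self):
        x = np.array([[0.5, 0.5]])
        theta = np.ones(6)
        a = ohe_baseline(x, [[0]], x, [[1]], theta, 2.5, self.NCAT)[0, 0]
        b = ohe_baseline(x, [[2]], x, [[3]], theta, 2.5, self.NCAT)[0, 0]
        assert a == pytest.approx(b, abs=1e-12)


class TestParams:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            KernelParams(theta=np.array([-1.0]))
        with pytest.raises(ValueError):
            KernelParams(theta=np.array([1.0]), alpha=1.5)
        with pytest.raises(ValueError):
            KernelParams(theta=np.array([1.0]), nu=0.5)
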