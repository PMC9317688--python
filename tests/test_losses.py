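"""Loss functions: frozen hand-computed values, invariances, analytic gradients."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from colposeg import losses
from colposeg.losses import (
    AffinityParams,
    confidence_score,
    cross_entropy_grad,
    cross_entropy_loss,
    ct_loss,
    ct_loss_grad,
    pseudo_mask,
    reconstruction_grad,
    reconstruction_loss,
    soft_ncut_grad,
    soft_ncut_loss,
    total_variation_grad,
    total_variation_loss,
)


def brute_force_ncut(img, resp, p: AffinityParams):
    """Independent O(P^2) double-sum over all pixel pairs (same conventions)."""
    f = p.pool_factor
    h, w, _ = img.shape

    def pool(a):
        return a.reshape(h // f, f, w // f, f, a.shape[-1]).mean(axis=(1, 3))

    F = pool(np.asarray(img, float)) * 255.0
    R = pool(np.asarray(resp, float))
    hp, wp, k = R.shape
    coords = [(i, j) for i in range(hp) for j in range(wp)]
    total = 0.0
    for kk in range(k):
        num = den = 0.0
        for (i1, j1) in coords:
            for (i2, j2) in coords:
                d2 = (i1 - i2) ** 2 + (j1 - j2) ** 2
                if d2 > p.radius ** 2:
                    continue
                wgt = (np.exp(-((F[i1, j1] - F[i2, j2]) ** 2).sum() / p.sigma_intensity ** 2)
                       * np.exp(-d2 / p.sigma_spatial ** 2))
                num += wgt * R[i1, j1, kk] * R[i2, j2, kk]
                den += wgt * R[i1, j1, kk]
        total += num / den
    return k - total


class TestPseudoMask:
    def test_argmax_and_tie_break(self):
        resp = np.array([[[0.8, 0.2], [0.5, 0.5]],
                         [[0.1, 0.9], [0.3, 0.7]]])
        assert pseudo_mask(resp).tolist() == [[0, 0], [1, 1]]

    def test_one_hot_recovers_channel(self, rng):
        labels = rng.integers(0, 3, size=(6, 5))
        resp = np.eye(3)[labels]
        assert np.array_equal(pseudo_mask(resp), labels)


class TestCrossEntropy:
    def test_one_hot_matching_is_zero(self):
        resp = np.eye(2)[np.zeros((4, 4), int)]
        assert cross_entropy_loss(resp, np.zeros((4, 4), int)) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_two_class_is_log2(self):
        resp = np.full((3, 3, 2), 0.5)
        assert cross_entropy_loss(resp, np.zeros((3, 3), int)) == pytest.approx(np.log(2), abs=1e-9)

    def test_single_pixel_hand_value(self):
        resp = np.array([[[0.8, 0.2]]])
        assert cross_entropy_loss(resp, np.array([[0]])) == pytest.approx(-np.log(0.8), abs=1e-9)

    def test_sum_reduction_scales_by_pixel_count(self, rng, make_response):
        resp = make_response(rng, 5, 7, 3)
        c = pseudo_mask(resp)
        assert cross_entropy_loss(resp, c, "sum") == pytest.approx(
            35 * cross_entropy_loss(resp, c, "mean"), rel=1e-12)

    def test_zero_probability_is_clamped_finite(self):
        resp = np.zeros((2, 2, 2))
        resp[..., 1] = 1.0
        val = cross_entropy_loss(resp, np.zeros((2, 2), int))
        assert np.isfinite(val) and val == pytest.approx(-np.log(1e-8), rel=1e-6)


class TestTotalVariation:
    def test_constant_map_is_zero(self):
        assert total_variation_loss(np.full((4, 4, 2), 0.5)) == 0.0

    def test_2x2_hand_enumeration(self):
        resp = np.array([[0.0, 1.0], [0.0, 1.0]])[..., None]
        assert total_variation_loss(resp) == pytest.approx(2.0, abs=1e-12)
        # strict bounds drop the second-row horizontal and second-column
        # vertical pairs: only |1-0| in row 0 remains
        assert total_variation_loss(resp, strict_bounds=True) == pytest.approx(1.0, abs=1e-12)

    def test_channel_permutation_invariance(self, rng, make_response):
        resp = make_response(rng, 6, 6, 3)
        assert total_variation_loss(resp[..., [2, 0, 1]]) == pytest.approx(
            total_variation_loss(resp), rel=1e-12)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_mirror_invariance(self, seed):
        r = np.random.default_rng(seed).random((5, 6, 2))
        v = total_variation_loss(r)
        assert total_variation_loss(r[::-1]) == pytest.approx(v, rel=1e-10)
        assert total_variation_loss(r[:, ::-1]) == pytest.approx(v, rel=1e-10)


class TestCTLoss:
    def test_zero_on_constant_one_hot(self):
        resp = np.eye(2)[np.ones((4, 4), int)]
        assert ct_loss(resp, np.ones((4, 4), int)) == 0.0

    def test_additivity_and_tv_weight_zero(self, rng, make_response):
        resp = make_response(rng, 5, 5, 2)
        c = pseudo_mask(resp)
        expected = cross_entropy_loss(resp, c) + 2.5 * total_variation_loss(resp)
        assert ct_loss(resp, c, tv_weight=2.5) == pytest.approx(expected, rel=1e-12)
        assert ct_loss(resp, c, tv_weight=0.0) == pytest.approx(
            cross_entropy_loss(resp, c), rel=1e-12)


class TestReconstruction:
    def test_identical_is_zero(self, rng):
        x = rng.random((4, 4, 3))
        assert reconstruction_loss(x, x) == 0.0

    def test_constant_offset(self):
        assert reconstruction_loss(np.zeros((3, 3, 3)), np.full((3, 3, 3), 0.5)) == \
            pytest.approx(0.25, abs=1e-12)

    def test_two_element_hand_value(self):
        assert reconstruction_loss(np.array([0.0, 1.0]), np.array([0.5, 0.5])) == \
            pytest.approx(0.25, abs=1e-12)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            reconstruction_loss(np.zeros((2, 2, 3)), np.zeros((2, 3, 3)))


class TestConfidence:
    def test_uniform_is_inverse_k(self):
        for k in (2, 3, 4, 5):
            assert confidence_score(np.full((6, 6, k), 1.0 / k)) == pytest.approx(1.0 / k, abs=0)

    def test_one_hot_is_one(self, rng):
        resp = np.eye(3)[rng.integers(0, 3, (5, 5))]
        assert confidence_score(resp) == 1.0

    def test_two_pixel_hand_mean(self):
        resp = np.array([[[0.9, 0.1], [0.6, 0.4]]])
        assert confidence_score(resp) == pytest.approx(0.75, abs=1e-12)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1), st.floats(1.0, 5.0))
    def test_monotone_under_sharpening(self, seed, power):
        r = np.random.default_rng(seed).random((4, 4, 3)) + 1e-3
        r /= r.sum(-1, keepdims=True)
        sharp = r ** power
        sharp /= sharp.sum(-1, keepdims=True)
        assert confidence_score(sharp) >= confidence_score(r) - 1e-12


class TestSoftNCut:
    def test_single_class_is_zero(self, rng):
        img = rng.random((4, 4, 3))
        resp = np.ones((4, 4, 1))
        assert soft_ncut_loss(img, resp, AffinityParams(radius=2, pool_factor=1)) == \
            pytest.approx(0.0, abs=1e-12)

    def test_uniform_closed_form(self, rng):
        img = rng.random((8, 8, 3))
        for k in (2, 3):
            resp = np.full((8, 8, k), 1.0 / k)
            val = soft_ncut_loss(img, resp, AffinityParams(radius=3, pool_factor=2))
            assert val == pytest.approx(k - 1, abs=1e-9)

    def test_matches_brute_force_oracle(self, rng, make_response):
        p = AffinityParams(radius=3, pool_factor=1)
        for _ in range(5):
            img = rng.random((6, 6, 3))
            resp = make_response(rng, 6, 6, 2)
            assert soft_ncut_loss(img, resp, p) == pytest.approx(
                brute_force_ncut(img, resp, p), abs=1e-6)

    def test_bounded_in_zero_k(self, rng, make_response):
        p = AffinityParams(radius=2, pool_factor=2)
        for k in (2, 3):
            img = rng.random((8, 8, 3))
            resp = make_response(rng, 8, 8, k)
            assert 0.0 <= soft_ncut_loss(img, resp, p) <= k

    def test_degenerate_class_warns(self, rng):
        img = rng.random((4, 4, 3))
        resp = np.zeros((4, 4, 2))
        resp[..., 0] = 1.0
        with pytest.warns(UserWarning, match="zero soft assignment"):
            soft_ncut_loss(img, resp, AffinityParams(radius=2, pool_factor=1))


class TestGradients:
    """Analytic loss gradients agree with central finite differences."""

    @staticmethod
    def fd_check(fn, grad, x, rng, n_probe=25, eps=1e-6, tol=1e-5):
        for _ in range(n_probe):
            idx = tuple(rng.integers(0, s) for s in x.shape)
            xp = x.copy()
            xp[idx] += eps
            vp = fn(xp)
            xp[idx] -= 2 * eps
            vm = fn(xp)
            num = (vp - vm) / (2 * eps)
            assert num == pytest.approx(grad[idx], rel=tol, abs=1e-7)

    def test_cross_entropy_grad(self, rng, make_response):
        resp = make_response(rng, 4, 5, 3)
        c = pseudo_mask(resp)
        self.fd_check(lambda r: cross_entropy_loss(r, c),
                      cross_entropy_grad(resp, c), resp, rng)

    @pytest.mark.parametrize("kw", [dict(reduction="sum"), dict(reduction="mean"),
                                    dict(reduction="sum", strict_bounds=True)])
    def test_total_variation_grad(self, rng, make_response, kw):
        resp = make_response(rng, 4, 5, 2)
        self.fd_check(lambda r: total_variation_loss(r, **kw),
                      total_variation_grad(resp, **kw), resp, rng)

    def test_ct_grad(self, rng, make_response):
        resp = make_response(rng, 4, 4, 2)
        c = pseudo_mask(resp)
        self.fd_check(lambda r: ct_loss(r, c, tv_weight=0.5, tv_reduction="mean"),
                      ct_loss_grad(resp, c, tv_weight=0.5, tv_reduction="mean"), resp, rng)

    def test_reconstruction_grad(self, rng):
        x = rng.random((3, 4, 3))
        y = rng.random((3, 4, 3))
        self.fd_check(lambda r: reconstruction_loss(x, r),
                      reconstruction_grad(x, y), y, rng)

    def test_soft_ncut_grad(self, rng, make_response):
        img = rng.random((6, 6, 3))
        resp = make_response(rng, 6, 6, 2)
        p = AffinityParams(radius=2, pool_factor=2)
        self.fd_check(lambda r: soft_ncut_loss(img, r, p),
                      soft_ncut_grad(img, resp, p), resp, rng, tol=1e-4)
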