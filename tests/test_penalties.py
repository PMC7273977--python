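"""Weight maps and quadratic-penalty fields against brute-force oracles."""

import numpy as np
import pytest

from bootrecon.penalties import (
    bowsher_weights,
    compute_nu,
    make_context,
    penalty_gradient,
    penalty_value,
    smoothed_image,
    uniform_weights,
)


def brute_penalty(theta, wm):
    """Double-loop evaluation of 1/4 sum_j sum_l w_jl (theta_j-theta_l)^2."""
    ny, nx = theta.shape
    total = 0.0
    for y in range(ny):
        for x in range(nx):
            for i, (dy, dx) in enumerate(wm.offsets):
                yy, xx = y + dy, x + dx
                if 0 <= yy < ny and 0 <= xx < nx:
                    total += 0.25 * wm.weights[i, y, x] * (theta[y, x] - theta[yy, xx]) ** 2
    return total


def brute_smoothed(theta, wm):
    ny, nx = theta.shape
    out = theta.copy()
    for y in range(ny):
        for x in range(nx):
            sw = num = 0.0
            for i, (dy, dx) in enumerate(wm.offsets):
                yy, xx = y + dy, x + dx
                if 0 <= yy < ny and 0 <= xx < nx:
                    w = wm.weights[i, y, x]
                    sw += w
                    num += w * (theta[yy, xx] + theta[y, x])
            if sw > 0:
                out[y, x] = num / (2 * sw)
    return out


class TestUniformWeights:
    def test_interior_sum_25_for_5x5(self):
        wm = uniform_weights((12, 12), stencil=5)
        assert wm.sum_w()[6, 6] == 25

    def test_corner_sum_9_for_5x5(self):
        wm = uniform_weights((12, 12), stencil=5)
        assert wm.sum_w()[0, 0] == 9  # only the 3x3 in-image overlap

    def test_interior_sum_9_for_3x3(self):
        wm = uniform_weights((12, 12), stencil=3)
        assert wm.sum_w()[6, 6] == 9

    def test_even_stencil_rejected(self):
        with pytest.raises(ValueError):
            uniform_weights((8, 8), stencil=4)


class TestBowsherWeights:
    def test_interior_selects_exactly_B(self):
        rng = np.random.default_rng(0)
        guide = rng.random((12, 12))
        wm = bowsher_weights(guide, stencil=5, B=10)
        counts = (wm.weights > 0).sum(axis=0)
        assert np.all(counts[2:-2, 2:-2] == 10)

    def test_border_keeps_min_B_available(self):
        rng = np.random.default_rng(1)
        wm = bowsher_weights(rng.random((8, 8)), stencil=5, B=10)
        counts = (wm.weights > 0).sum(axis=0)
        assert counts[0, 0] == 8  # corner: 3x3 overlap minus the centre
        # everywhere: exactly min(B, available neighbours)
        avail = uniform_weights((8, 8), stencil=5, include_centre=False).sum_w()
        np.testing.assert_array_equal(counts, np.minimum(10, avail))

    def test_constant_guide_tie_break_by_offset_order(self):
        wm = bowsher_weights(np.ones((9, 9)), stencil=5, B=10)
        chosen = np.flatnonzero(wm.weights[:, 4, 4] > 0)
        np.testing.assert_array_equal(chosen, np.arange(10))

    def test_edge_not_crossed(self):
        """Two-region guide: selected neighbours stay within the region
        whenever enough same-region candidates exist (brute-force check)."""
        guide = np.zeros((6, 6))
        guide[:, 3:] = 100.0
        wm = bowsher_weights(guide, stencil=3, B=2)
        for y in range(6):
            for x in range(6):
                for i, (dy, dx) in enumerate(wm.offsets):
                    if wm.weights[i, y, x] > 0:
                        assert guide[y + dy, x + dx] == guide[y, x]

    def test_symmetrised_is_symmetric(self):
        rng = np.random.default_rng(2)
        wm = bowsher_weights(rng.random((7, 7)), stencil=3, B=3, symmetrise=True)
        lut = {tuple(o): i for i, o in enumerate(wm.offsets)}
        for i, (dy, dx) in enumerate(wm.offsets):
            j = lut[(-dy, -dx)]
            for y in range(7):
                for x in range(7):
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < 7 and 0 <= xx < 7:
                        assert wm.weights[i, y, x] == wm.weights[j, yy, xx]

    def test_invalid_B_rejected(self):
        with pytest.raises(ValueError):
            bowsher_weights(np.ones((8, 8)), stencil=3, B=9)  # 3x3 has 8 neighbours


class TestPenaltyValue:
    def test_constant_image_is_zero(self):
        wm = uniform_weights((8, 8))
        assert penalty_value(np.full((8, 8), 3.7), wm) == 0

    def test_two_pixel_hand_value(self):
        """Pair weighted both ways: R = ((a-b)^2 + (b-a)^2)/4 = (a-b)^2/2."""
        wm = uniform_weights((1, 2), stencil=3, include_centre=False)
        theta = np.array([[2.0, 5.0]])
        assert penalty_value(theta, wm) == pytest.approx((2.0 - 5.0) ** 2 / 2, abs=1e-14)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        theta = rng.random((8, 8))
        for wm in (uniform_weights((8, 8)), bowsher_weights(rng.random((8, 8)), 5, 10)):
            assert penalty_value(theta, wm) == pytest.approx(
                brute_penalty(theta, wm), abs=1e-12
            )

    def test_gradient_matches_finite_difference(self):
        """Needed for KKT checks; holds for directed Bowsher weights too."""
        rng = np.random.default_rng(4)
        theta = rng.random((8, 8)) + 0.5
        eps = 1e-6
        for wm in (uniform_weights((8, 8)), bowsher_weights(rng.random((8, 8)), 5, 10)):
            grad = penalty_gradient(theta, wm)
            for y, x in [(0, 0), (3, 4), (7, 7), (5, 1)]:
                tp, tm = theta.copy(), theta.copy()
                tp[y, x] += eps
                tm[y, x] -= eps
                fd = (penalty_value(tp, wm) - penalty_value(tm, wm)) / (2 * eps)
                assert grad[y, x] == pytest.approx(fd, rel=1e-6, abs=1e-9)


class TestNu:
    def test_uniform_interior_value(self):
        wm = uniform_weights((12, 12), stencil=5)
        nu = compute_nu(wm, np.full((12, 12), 5.0))
        assert nu[6, 6] == pytest.approx(25 / 5)

    def test_doubling_sens_halves_nu(self):
        wm = uniform_weights((8, 8))
        sens = np.full((8, 8), 3.0)
        np.testing.assert_allclose(compute_nu(wm, sens), 2 * compute_nu(wm, 2 * sens))

    def test_zero_sensitivity_masked(self):
        wm = uniform_weights((8, 8))
        sens = np.ones((8, 8))
        sens[0, 0] = 0.0
        nu = compute_nu(wm, sens)
        assert nu[0, 0] == 0
        assert np.all(np.isfinite(nu))


class TestSmoothedImage:
    def test_preserves_constants(self):
        wm = uniform_weights((8, 8))
        np.testing.assert_allclose(smoothed_image(np.full((8, 8), 2.5), wm), 2.5)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        theta = rng.random((8, 8))
        for wm in (uniform_weights((8, 8)), bowsher_weights(rng.random((8, 8)), 5, 10)):
            np.testing.assert_allclose(
                smoothed_image(theta, wm), brute_smoothed(theta, wm), atol=1e-12
            )

    def test_bounded_by_input_range(self):
        rng = np.random.default_rng(6)
        theta = rng.random((10, 10)) * 7
        out = smoothed_image(theta, uniform_weights((10, 10)))
        assert out.min() >= theta.min() - 1e-12
        assert out.max() <= theta.max() + 1e-12

    def test_zero_weight_sum_passthrough(self):
        wm = uniform_weights((4, 4), stencil=3)
        wm.weights[:] = 0.0
        theta = np.arange(16.0).reshape(4, 4)
        np.testing.assert_array_equal(smoothed_image(theta, wm), theta)


def test_context_fields_consistent():
    rng = np.random.default_rng(7)
    wm = uniform_weights((8, 8))
    sens = rng.random((8, 8)) + 0.5
    ctx = make_context(wm, sens)
    np.testing.assert_allclose(ctx.nu[ctx.support], ctx.sum_w[ctx.support] / sens[ctx.support])
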