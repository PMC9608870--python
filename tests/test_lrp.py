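"""Relevance propagation rules, conservation, and cortical back-projection."""

import numpy as np
import pytest

from conftest import make_space
from cortexlrp import cnn, lrp
from cortexlrp.projection import project_hemisphere, rasterize


LRP0 = lrp.LRPRuleParams("lrp0")


class TestPropagateDense:
    def test_single_unit_identity(self):
        R = lrp.propagate_dense(
            np.array([[3.5]]), np.array([[1.0]]), np.zeros(1), np.array([[1.0]]), LRP0
        )
        assert R[0, 0] == pytest.approx(3.5)

    def test_two_to_one_lrp0_splits_by_contribution(self):
        # a=(1,1), w=(3,1), no bias: z = 4, shares 3/4 and 1/4 of R=4
        R = lrp.propagate_dense(
            np.array([[4.0]]), np.array([[3.0], [1.0]]), np.zeros(1),
            np.array([[1.0, 1.0]]), LRP0,
        )
        assert np.allclose(R, [[3.0, 1.0]])

    def test_large_gamma_suppresses_negative_contributions(self):
        weights = np.array([[3.0], [-1.0]])
        a = np.array([[1.0, 1.0]])
        R = lrp.propagate_dense(
            np.array([[2.0]]), weights, np.zeros(1), a,
            lrp.LRPRuleParams("gamma", gamma=1e9),
        )
        assert R[0, 1] == pytest.approx(0.0, abs=1e-6)
        assert R[0, 0] == pytest.approx(2.0, rel=1e-6)

    def test_epsilon_rule_shrinks_relevance_monotonically(self):
        weights = np.array([[2.0], [1.0]])
        a = np.array([[1.0, 1.0]])
        totals = []
        for eps in (0.01, 1.0, 100.0, 1e6):
            R = lrp.propagate_dense(
                np.array([[1.0]]), weights, np.zeros(1), a,
                lrp.LRPRuleParams("epsilon", eps=eps),
            )
            totals.append(np.abs(R).sum())
        assert all(a > b for a, b in zip(totals, totals[1:]))
        assert totals[-1] < 1e-5

    def test_zero_denominator_falls_back_with_warning(self):
        weights = np.array([[1.0], [-1.0]])
        a = np.array([[1.0, 1.0]])  # z = 0
        with pytest.warns(UserWarning, match="zero denominator"):
            R = lrp.propagate_dense(np.array([[1.0]]), weights, np.zeros(1), a, LRP0)
        assert np.all(np.isfinite(R))

    def test_two_layer_toy_matches_hand_computation(self):
        # input a=(1,2); layer1 W=[[1,-1],[0.5,1]] relu; layer2 w=(1,1)
        rng = np.random.default_rng(0)
        d1 = cnn.Dense(2, 2, "relu", 0.0, rng)
        d2 = cnn.Dense(2, 1, "sigmoid", 0.0, rng)
        d1.W[...] = [[1.0, -1.0], [0.5, 1.0]]
        d1.b[...] = 0.0
        d2.W[...] = [[1.0], [1.0]]
        d2.b[...] = 0.0
        model = cnn.CNNModel([cnn.Flatten(), d1, d2], input_shape=(1, 2))
        x = np.array([[[1.0, 2.0]]])

        # all-LRP0: hand result R = (0, 3), total = logit = 3
        composite = {"dense": LRP0, "block1": LRP0, "block2": LRP0}
        R = lrp.explain(model, x[0], composite)
        assert np.allclose(R, [[0.0, 3.0]])

        # epsilon(1.0) on both layers: hand result (0.125, 1.25)
        eps = lrp.LRPRuleParams("epsilon", eps=1.0)
        composite = {"dense": eps, "block1": eps, "block2": eps}
        R = lrp.explain(model, x[0], composite)
        assert np.allclose(R, [[0.125, 1.25]])


class TestPropagateConv:
    def unrolled_oracle(self, conv, x, R_next, params):
        """Dense propagation on the explicitly unrolled convolution matrix."""
        n, c, h, w = x.shape
        _, ho, wo = conv.out_shape((c, h, w))
        f = conv.out_channels
        in_dim, out_dim = c * h * w, f * ho * wo
        M = np.zeros((in_dim, out_dim))
        for j in range(in_dim):
            basis = np.zeros(in_dim)
            basis[j] = 1.0
            cols = cnn.im2col(basis.reshape(1, c, h, w), conv.kernel)
            M[j] = (cols @ conv.W).transpose(0, 2, 1).reshape(-1)
        bias = np.repeat(conv.b, ho * wo)
        return lrp.propagate_dense(
            R_next.reshape(1, -1), M, bias, x.reshape(1, -1), params
        ).reshape(x.shape)

    @pytest.mark.parametrize("rule", [
        lrp.LRPRuleParams("lrp0"),
        lrp.LRPRuleParams("epsilon", eps=0.05),
        lrp.LRPRuleParams("gamma", gamma=0.4),
    ])
    def test_matches_unrolled_dense_propagation(self, rule, rng):
        for trial in range(5):
            conv = cnn.Conv2D(2, 3, 3, rng)
            conv.b[...] = rng.normal(size=3) if rule.rule != "lrp0" else 0.0
            x = rng.normal(size=(1, 2, 5, 5))
            conv.forward(x, train=False)
            R_next = rng.normal(size=(1, 3, 3, 3))
            got = lrp.propagate_conv(R_next, conv, rule)
            want = self.unrolled_oracle(conv, x, R_next, rule)
            assert np.allclose(got, want, atol=1e-10)

    def test_one_by_one_identity_kernel_passes_relevance_through(self, rng):
        conv = cnn.Conv2D(1, 1, 1, rng)
        conv.W[...] = [[1.0]]
        conv.b[...] = 0.0
        x = np.abs(rng.normal(size=(1, 1, 4, 4))) + 0.1
        conv.forward(x, train=False)
        R_next = rng.normal(size=(1, 1, 4, 4))
        R = lrp.propagate_conv(R_next, conv, LRP0)
        assert np.allclose(R, R_next)

    def test_lrp0_conserves_total_relevance_without_bias(self, rng):
        conv = cnn.Conv2D(2, 4, 3, rng)
        conv.W[...] = np.abs(conv.W)
        conv.b[...] = 0.0
        x = np.abs(rng.normal(size=(2, 2, 6, 6)))
        conv.forward(x, train=False)
        R_next = np.abs(rng.normal(size=(2, 4, 4, 4)))
        R = lrp.propagate_conv(R_next, conv, LRP0)
        assert R.sum() == pytest.approx(R_next.sum(), rel=1e-9)

    def test_shape_mismatch_raises(self, rng):
        conv = cnn.Conv2D(1, 2, 3, rng)
        conv.forward(rng.normal(size=(1, 1, 5, 5)), train=False)
        with pytest.raises(ValueError):
            lrp.propagate_conv(rng.normal(size=(1, 2, 4, 4)), conv, LRP0)


class TestPropagatePool:
    def test_winner_takes_all_relevance(self):
        pool = cnn.MaxPool2D(2)
        x = np.array([[[[5.0, 1.0], [2.0, 3.0]]]])
        pool.forward(x, train=False)
        R = lrp.propagate_pool(np.array([[[[7.0]]]]), pool)
        assert np.allclose(R, [[[[7.0, 0.0], [0.0, 0.0]]]])

    def test_tie_goes_to_first_in_row_major_order(self):
        pool = cnn.MaxPool2D(2)
        x = np.array([[[[4.0, 4.0], [4.0, 4.0]]]])
        pool.forward(x, train=False)
        R = lrp.propagate_pool(np.array([[[[1.0]]]]), pool)
        assert np.allclose(R, [[[[1.0, 0.0], [0.0, 0.0]]]])

    def test_pooling_conserves_total_relevance(self, rng):
        pool = cnn.MaxPool2D(2)
        x = rng.normal(size=(2, 3, 6, 6))
        pool.forward(x, train=False)
        R_next = rng.normal(size=(2, 3, 3, 3))
        assert lrp.propagate_pool(R_next, pool).sum() == pytest.approx(R_next.sum())

    def test_missing_switches_raise(self):
        pool = cnn.MaxPool2D(2)
        with pytest.raises(ValueError):
            lrp.propagate_pool(np.ones((1, 1, 2, 2)), pool)


class TestExplain:
    def bias_free_model(self, seed=0):
        model = cnn.build_model((16, 16), (2, 4), (8, 4), seed=seed)
        for layer in model.trainable():
            layer.b[...] = 0.0
        return model

    def test_all_lrp0_conserves_output_preactivation(self, rng):
        model = self.bias_free_model()
        composite = {"dense": LRP0, "block1": LRP0, "block2": LRP0}
        x = rng.normal(size=(4, 16, 16))
        R = lrp.explain(model, x, composite)
        p = model.forward(x)
        logit = model.logits()
        expected = np.where(p >= 0.5, logit, -logit)
        assert np.allclose(R.sum(axis=(1, 2)), expected, rtol=1e-6)

    def test_random_small_dense_networks_conserve(self, rng):
        # bias-free LRP-0 conservation across 100 random architectures
        composite = {"dense": LRP0, "block1": LRP0, "block2": LRP0}
        for _ in range(100):
            n_in = int(rng.integers(2, 10))
            n_h = int(rng.integers(2, 8))
            d1 = cnn.Dense(n_in, n_h, "relu", 0.0, rng)
            d2 = cnn.Dense(n_h, 1, "sigmoid", 0.0, rng)
            d1.b[...] = 0.0
            d2.b[...] = 0.0
            model = cnn.CNNModel([cnn.Flatten(), d1, d2], input_shape=(1, n_in))
            x = rng.normal(size=(1, n_in))
            R = lrp.explain(model, x[None][0], composite)
            p = model.forward(x[None][0])
            logit = model.logits()[0]
            expected = logit if p[0] >= 0.5 else -logit
            assert R.sum() == pytest.approx(expected, rel=1e-6)

    def test_composite_default_produces_finite_maps(self, rng):
        model = cnn.build_model((16, 16), (2, 4), (8, 4), seed=2)
        R = lrp.explain(model, rng.normal(size=(2, 16, 16)))
        assert R.shape == (2, 16, 16)
        assert np.all(np.isfinite(R))


class TestPixelToVertex:
    def make_maps(self, n=50, grid=16):
        lat = np.tile(np.linspace(-1.2, 1.2, n // 2), 2)
        lon = np.tile(np.linspace(-1.4, 1.4, n // 2), 2)
        hemi = np.array(["left"] * (n // 2) + ["right"] * (n // 2))
        space = make_space(lat, lon, hemisphere=hemi)
        maps = []
        for h in ("left", "right"):
            coords = project_hemisphere(space, h)
            _, pmap = rasterize(coords, np.zeros(n // 2), grid)
            maps.append(pmap)
        return space, maps[0], maps[1]

    def test_equipartition_within_shared_pixels(self, rng):
        _, left, right = self.make_maps()
        g = left.grid_size
        R = np.abs(rng.normal(size=(g, 2 * g)))
        vert = lrp.pixel_to_vertex(R, left, right)
        for pmap, off in ((left, 0), (right, g)):
            counts = pmap.counts()
            for v, r, c in zip(pmap.vertex_index, pmap.rows, pmap.cols):
                assert vert[v] == pytest.approx(R[r, c + off] / counts[r, c])

    def test_conservation_of_nonempty_pixel_relevance(self, rng):
        _, left, right = self.make_maps()
        g = left.grid_size
        R = rng.normal(size=(g, 2 * g))
        vert = lrp.pixel_to_vertex(R, left, right)
        expected = R[:, :g][left.counts() > 0].sum() + R[:, g:][right.counts() > 0].sum()
        assert vert.sum() == pytest.approx(expected)

    def test_grid_mismatch_raises(self, rng):
        _, left, right = self.make_maps()
        with pytest.raises(ValueError):
            lrp.pixel_to_vertex(rng.normal(size=(8, 16)), left, right)


class TestAggregateHeatmaps:
    def rmap(self, value, correct=True, subject=0):
        return lrp.RelevanceMap(
            pixel=np.full((4, 8), float(value)),
            vertex=np.full(10, float(value)),
            subject_id=subject,
            true_label=1,
            predicted_label=1 if correct else 0,
        )

    def test_identical_maps_average_to_themselves(self):
        agg = lrp.aggregate_heatmaps([self.rmap(2.0), self.rmap(2.0)])
        assert np.allclose(agg.pixel, 2.0)

    def test_incorrect_trials_are_excluded(self):
        agg = lrp.aggregate_heatmaps([self.rmap(1.0), self.rmap(99.0, correct=False)])
        assert np.allclose(agg.pixel, 1.0)

    def test_opposite_maps_cancel(self):
        agg = lrp.aggregate_heatmaps([self.rmap(3.0), self.rmap(-3.0)])
        assert np.allclose(agg.pixel, 0.0)

    def test_per_subject_scope_groups_by_subject(self):
        maps = [self.rmap(1.0, subject=0), self.rmap(5.0, subject=1)]
        by_subject = lrp.aggregate_heatmaps(maps, scope="per_subject")
        assert np.allclose(by_subject[0].pixel, 1.0)
        assert np.allclose(by_subject[1].pixel, 5.0)

    def test_no_correct_trials_raises(self):
        with pytest.raises(ValueError):
            lrp.aggregate_heatmaps([self.rmap(1.0, correct=False)])
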