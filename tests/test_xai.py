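"""Explainability: Grad-CAM analytic oracle, LIME exact recovery,
projection statistics and the failure panel."""

import numpy as np
import pytest

from lsetnet import (
    build_lsetnet,
    extract_embeddings,
    failure_panel,
    grad_cam,
    heatmap_stats,
    kl_divergence,
    lime_explain,
    project_tsne,
    tiny_config,
)


@pytest.fixture(scope="module")
def model():
    return build_lsetnet(tiny_config(image_size=32), seed=0)


@pytest.fixture(scope="module")
def image(rng_seed=0):
    return np.random.default_rng(rng_seed).standard_normal((32, 32, 3)).astype(np.float32)


class TestGradCam:
    def test_linear_model_oracle(self, model, image):
        """For y_c = sum_k w_k mean(A_k) the map equals ReLU(sum w_k A_k)/max.

        Built by zeroing everything after the target stage except a
        linear read-out, using the model's own activations as ground
        truth.
        """
        # craft a linear head on the extra_conv activations by direct math:
        model.forward(image)
        acts = model.activations["extra_conv"][0]  # (H, W, K)
        h, w, k = acts.shape
        rng = np.random.default_rng(3)
        wk = rng.standard_normal(k)

        class LinearReadout:
            """y_c = sum_k w_k mean(A^k): gradient dy/dA_kij = w_k / (H W)."""
            activations = {}
            grad_activations = {}
            config = model.config

            def forward(self, x, training=False):
                self.activations = {"extra_conv": acts[None]}
                val = (acts.mean(axis=(0, 1)) * wk).sum()
                return np.array([[val, 0.0]])

            def backward(self, seed):
                g = np.broadcast_to(wk / (h * w), acts.shape) * seed[0, 0]
                self.grad_activations = {"extra_conv": g[None]}

        exp = grad_cam(LinearReadout(), image, target_class=0)
        expect = np.maximum((acts * (wk / (h * w))).sum(axis=-1), 0.0)
        if expect.max() > 0:
            expect = expect / expect.max()
        assert np.allclose(exp.map, expect, atol=1e-6)

    def test_real_model_map_properties(self, model, image):
        exp = grad_cam(model, image, target_class=2, upsample_to=32)
        assert exp.map.min() >= 0.0
        assert exp.map.max() <= 1.0 + 1e-9
        assert exp.overlay.shape == (32, 32)

    def test_all_nonpositive_gradients_give_zero_map(self, model, image):
        model.forward(image[None])
        acts = model.activations["extra_conv"]

        class NegGrad:
            activations = {"extra_conv": acts}
            grad_activations = {}
            config = model.config

            def forward(self, x, training=False):
                self.activations = {"extra_conv": np.abs(acts)}
                return np.zeros((1, 2))

            def backward(self, seed):
                self.grad_activations = {"extra_conv": -np.ones_like(acts)}

        exp = grad_cam(NegGrad(), image, 0)
        assert np.all(exp.map == 0.0)
        assert exp.mean_intensity == 0.0 and exp.top5_mean == 0.0

    def test_invariant_to_positive_logit_rescaling(self, model, image):
        # a stage with spatial extent, so normalization has structure to keep
        a = grad_cam(model, image, 1, target_layer="res2").map
        # rescaling the head's last layer scales all gradients positively
        for key in ("W", "b"):
            model.head.fc2.params[key] *= 4.0
        b = grad_cam(model, image, 1, target_layer="res2").map
        for key in ("W", "b"):
            model.head.fc2.params[key] /= 4.0
        assert np.allclose(a, b, atol=1e-4)


class TestHeatmapStats:
    def test_single_hot_100px(self):
        m = np.zeros(100)
        m[0] = 1.0
        mean, top5 = heatmap_stats(m.reshape(10, 10))
        assert mean == pytest.approx(0.01)
        assert top5 == pytest.approx(0.2)  # top ceil(5) values: 1,0,0,0,0

    def test_constant_half(self):
        mean, top5 = heatmap_stats(np.full((7, 7), 0.5))
        assert mean == top5 == pytest.approx(0.5)

    def test_top5_at_least_mean(self, rng):
        m = rng.random((13, 13))
        mean, top5 = heatmap_stats(m)
        assert top5 >= mean


class TestLime:
    def _segments(self):
        seg = np.zeros((8, 8), dtype=int)
        seg[:, 4:] = 1
        seg[4:, :] += 2  # four quadrant segments 0..3
        return seg

    def test_exact_linear_recovery_full_enumeration(self):
        seg = self._segments()
        img = np.random.default_rng(0).integers(0, 255, (8, 8, 3), dtype=np.uint8)

        def predict(x):
            z = [float(np.array_equal(x[seg == i], img[seg == i])) for i in range(4)]
            return np.array([2.0 + 3.0 * z[0] - 1.0 * z[1] + 0.5 * z[2]])

        exp = lime_explain(predict, img, segments=seg, ridge=0.0,
                           enumerate_all=True, target_class=0)
        assert exp.intercept == pytest.approx(2.0, abs=1e-8)
        assert np.allclose(exp.weights, [3.0, -1.0, 0.5, 0.0], atol=1e-8)
        assert exp.fidelity == pytest.approx(1.0)

    def test_constant_black_box(self):
        seg = self._segments()
        img = np.full((8, 8, 3), 90, np.uint8)
        exp = lime_explain(lambda x: np.array([0.75]), img, segments=seg,
                           ridge=0.0, enumerate_all=True, target_class=0)
        assert np.allclose(exp.weights, 0.0, atol=1e-10)
        assert exp.intercept == pytest.approx(0.75)

    def test_sampled_recovery_high_fidelity(self):
        seg = self._segments()
        img = np.random.default_rng(1).integers(0, 255, (8, 8, 3), dtype=np.uint8)

        def predict(x):
            z = [float(np.array_equal(x[seg == i], img[seg == i])) for i in range(4)]
            return np.array([1.0 + 2.0 * z[0] - 0.5 * z[3]])

        exp = lime_explain(predict, img, n_samples=200, ridge=1e-6, seed=0,
                           segments=seg, target_class=0)
        assert exp.fidelity > 0.99

    def test_seeded_determinism_and_top5_format(self, model):
        from lsetnet import GeneratorConfig, generate_arrays

        img = generate_arrays(GeneratorConfig(image_size=32, n_per_class=1, seed=1))[0][0]

        def predict(x):
            return model.predict_proba((x.astype(np.float32) / 255.0 - 0.5))[0]

        a = lime_explain(predict, img, n_segments=20, n_samples=50, seed=4)
        b = lime_explain(predict, img, n_segments=20, n_samples=50, seed=4)
        assert np.array_equal(a.weights, b.weights)
        assert len(a.top_segments) == 5
        mags = [abs(w) for _, w in a.top_segments]
        assert mags == sorted(mags, reverse=True)

    def test_too_few_segments_fatal(self):
        with pytest.raises(ValueError):
            lime_explain(lambda x: np.array([0.0]), np.zeros((8, 8, 3), np.uint8),
                         n_segments=1)


class TestProjection:
    def test_kl_of_identical_distributions_is_zero(self, rng):
        p = rng.random((5, 5))
        np.fill_diagonal(p, 0)
        p /= p.sum()
        assert kl_divergence(p, p) == pytest.approx(0.0, abs=1e-12)
        q = p.copy()
        q[0, 1] *= 2
        q /= q.sum()
        assert kl_divergence(p, q) > 0

    def test_separated_gaussians_high_silhouette(self, rng):
        centers = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0]])
        feats = np.concatenate([c + 0.1 * rng.standard_normal((100, 3)) for c in centers])
        labels = np.repeat([0, 1, 2], 100)
        res = project_tsne(feats, labels, perplexity=30, seed=0, n_iter=500)
        # the embedding expands clusters internally, so even perfectly
        # separated inputs sit near 0.83 at these settings
        assert res.silhouette > 0.75
        assert res.objective >= 0.0

    def test_per_class_centroid_and_spread_definitions(self, rng):
        feats = rng.standard_normal((120, 4))
        labels = np.repeat([0, 1], 60)
        res = project_tsne(feats, labels, perplexity=15, seed=1, n_iter=260)
        sel = labels == 0
        assert res.centroids[0] == pytest.approx(tuple(res.coords[sel].mean(axis=0)))
        assert res.spreads[0] == pytest.approx(tuple(res.coords[sel].std(axis=0)))

    def test_duplicated_cluster_silhouette_nonpositive(self, rng):
        feats = rng.standard_normal((120, 3)) * 0.1
        labels = np.repeat([0, 1], 60)  # one blob, two labels
        res = project_tsne(feats, labels, perplexity=20, seed=2, n_iter=260)
        assert res.silhouette <= 0.05

    def test_too_few_samples_fatal(self, rng):
        with pytest.raises(ValueError):
            project_tsne(rng.random((10, 3)), np.zeros(10), perplexity=30)


class TestEmbeddings:
    def test_shape_and_duplicates(self, model, rng):
        x = rng.standard_normal((4, 32, 32, 3)).astype(np.float32)
        x[1] = x[0]
        emb = extract_embeddings(model, x)
        assert emb.shape == (4, model.config.d_model)
        assert np.array_equal(emb[0], emb[1])

    def test_embeddings_move_after_a_training_step(self, rng):
        from lsetnet import RunConfig, train

        m = build_lsetnet(tiny_config(image_size=32, stem_width=4), seed=1)
        x = rng.standard_normal((12, 32, 32, 3)).astype(np.float32)
        y = np.arange(12)
        before = extract_embeddings(m, x)
        train(m, (x, y), (x, y), RunConfig(image_size=32, batch_size=12,
                                           max_epochs=1, seed=0))
        after = extract_embeddings(m, x)
        assert not np.allclose(before, after, atol=1e-6)


class TestFailurePanel:
    def test_perfect_model_empty_panel(self, model, rng):
        x = rng.standard_normal((5, 32, 32, 3)).astype(np.float32)
        y = model.predict_proba(x).argmax(axis=1)
        classes = [str(i) for i in range(12)]
        assert failure_panel(model, x, y, classes) == []

    def test_injected_flip_gives_one_entry_with_consistent_probability(self, model, rng):
        x = rng.standard_normal((5, 32, 32, 3)).astype(np.float32)
        probs = model.predict_proba(x)
        y = probs.argmax(axis=1).copy()
        y[2] = (y[2] + 1) % 12
        classes = [str(i) for i in range(12)]
        panel = failure_panel(model, x, y, classes)
        assert len(panel) == 1
        case = panel[0]
        assert case.image_index == 2
        assert case.predicted_probability == pytest.approx(probs[2].max(), abs=1e-6)
        assert np.allclose(case.class_probabilities, probs[2], atol=1e-6)
        assert case.explanation is not None
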