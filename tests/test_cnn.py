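import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mozznet.cnn import (
    ModelConfig,
    ScoreVector,
    build_model,
    classify,
    count_parameters,
    load_model,
    quantize_scores,
    save_model,
    softmax_cross_entropy,
    train,
)

# deployed accounting: layer -> (tensor h, w, c), weights, biases
EXPECTED_LAYERS = {
    "Input": ((49, 40, 1), 0, 0),
    "C1": ((45, 36, 8), 160, 8),
    "S1": ((23, 18, 8), 0, 0),
    "C2": ((19, 15, 8), 1280, 8),
    "S2": ((10, 8, 8), 0, 0),
    "C3": ((6, 5, 8), 1280, 8),
    "FC": ((64, 1, 1), 15360, 64),
    "Output": ((3, 1, 1), 192, 3),
}


class TestArchitecture:
    def test_every_layer_matches_deployed_accounting(self):
        reports, n_w, n_b, total = count_parameters(build_model())
        assert len(reports) == len(EXPECTED_LAYERS)
        for r in reports:
            size, w, b = EXPECTED_LAYERS[r.name]
            assert (tuple(r.tensor_size), r.n_weights, r.n_biases) == (size, w, b), r.name
        assert (n_w, n_b, total) == (18_272, 91, 18_363)

    def test_forward_output_dimension(self, rng):
        model = build_model()
        logits = model.forward(rng.integers(0, 256, (2, 49, 40)).astype(np.uint8))
        assert logits.shape == (2, 3)

    def test_wrong_input_shape_rejected(self):
        with pytest.raises(ValueError):
            build_model().forward(np.zeros((1, 48, 40)))

    def test_collapsed_layer_named_in_error(self):
        with pytest.raises(ValueError, match="C"):
            ModelConfig(input_h=6, input_w=6).shape_chain()

    def test_gradients_match_finite_differences(self):
        """Backprop through conv/pool/crop/fc agrees with numeric gradients."""
        cfg = ModelConfig(
            input_h=11, input_w=10, kernel_h=2, kernel_w=2, c1_crop_cols=1,
            conv_channels=2, fc_units=5, dropout_rate=0.0, seed=3, init_std=0.1,
        )
        model = build_model(cfg)
        rng = np.random.default_rng(0)
        x = rng.integers(0, 256, (2, 11, 10)).astype(np.uint8)
        y = np.array([0, 2])
        logits = model.forward(x, train=True, rng=rng)
        _, dlogits = softmax_cross_entropy(logits, y)
        grads = model.backward(dlogits)

        eps = 1e-6
        for key in ("w1", "b2", "w3", "w_fc", "b_out"):
            flat = model.params[key].ravel()
            for idx in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp, _ = softmax_cross_entropy(model.forward(x), y)
                flat[idx] = orig - eps
                lm, _ = softmax_cross_entropy(model.forward(x), y)
                flat[idx] = orig
                numeric = (lp - lm) / (2 * eps)
                assert abs(numeric - grads[key].ravel()[idx]) < 1e-6


class TestScoreQuantization:
    def test_symmetric_logits_spread_at_most_one(self):
        s = quantize_scores(np.zeros(3))
        assert s.as_array().sum() == 256
        assert s.as_array().max() - s.as_array().min() <= 1

    def test_saturated_logit_takes_everything(self):
        assert quantize_scores(np.array([-1e9, -1e9, 50.0])) == ScoreVector(0, 0, 256)

    def test_matches_independent_largest_remainder_computation(self):
        # softmax(1,2,3)*256 = (23.0478, 62.6505, 170.3017); one leftover
        # unit goes to the largest fractional part (the middle class)
        assert quantize_scores(np.array([1.0, 2.0, 3.0])) == ScoreVector(23, 63, 170)

    @given(st.lists(st.floats(-50, 50), min_size=3, max_size=3))
    @settings(max_examples=300, deadline=None)
    def test_sum_is_always_exactly_256(self, logits):
        s = quantize_scores(np.array(logits))
        assert s.as_array().sum() == 256 and s.as_array().min() >= 0

    def test_invalid_score_vector_rejected(self):
        with pytest.raises(ValueError):
            ScoreVector(100, 100, 100)

    def test_argmax_ties_resolve_away_from_mosquito(self):
        assert ScoreVector(86, 85, 85).argmax() == 0
        assert ScoreVector(85, 86, 85).argmax() == 1


def _toy_problem():
    """Trivially separable 3-class toy: a bright half-plane per class.

    (Constant-per-class images are deliberately avoided: with near-zero
    biases a ReLU net maps two all-constant classes onto positive scalar
    multiples of one representation vector, which share an argmax.)
    """
    cfg = ModelConfig(
        input_h=12, input_w=10, kernel_h=2, kernel_w=2, c1_crop_cols=0,
        conv_channels=4, fc_units=8, batch_size=30, seed=5,
    )
    rng = np.random.default_rng(1)
    images, labels = [], []
    for c in range(3):
        for _ in range(20):
            img = np.full((12, 10), 40.0)
            if c == 0:
                img[:, :5] = 160.0
            elif c == 1:
                img[:, 5:] = 160.0
            else:
                img[:6, :] = 160.0
            img += rng.normal(0, 3, img.shape)
            images.append(np.clip(img, 0, 255).astype(np.uint8))
            labels.append(c)
    return cfg, np.stack(images), np.array(labels)


class TestTraining:
    def test_zero_steps_leaves_weights_unchanged(self):
        cfg, images, labels = _toy_problem()
        model = build_model(cfg)
        before = model.snapshot()
        model, trace, _ = train(model, images, labels, steps=0)
        assert trace == []
        assert all(np.array_equal(before[k], model.params[k]) for k in before)

    def test_single_class_dataset_rejected(self):
        cfg, images, _ = _toy_problem()
        with pytest.raises(ValueError):
            train(build_model(cfg), images, np.zeros(len(images), dtype=int), steps=1)

    def test_empty_dataset_rejected(self):
        cfg, _, _ = _toy_problem()
        with pytest.raises(ValueError):
            train(build_model(cfg), np.zeros((0, 12, 10)), np.zeros(0, dtype=int))

    def test_separable_toy_reaches_perfect_accuracy(self):
        cfg, images, labels = _toy_problem()
        model, trace, checkpoints = train(build_model(cfg), images, labels, steps=500)
        logits = model.forward(images)
        assert np.mean(np.argmax(logits, axis=1) == labels) == 1.0
        assert len(checkpoints) == 5  # every 100 steps
        # loss trend is decreasing on a separable problem
        losses = [r["loss"] for r in trace]
        assert np.mean(losses[-50:]) < np.mean(losses[:50])

    def test_training_is_deterministic_under_seed(self):
        cfg, images, labels = _toy_problem()
        m1, t1, _ = train(build_model(cfg), images, labels, steps=30)
        m2, t2, _ = train(build_model(cfg), images, labels, steps=30)
        assert t1 == t2
        assert all(np.array_equal(m1.params[k], m2.params[k]) for k in m1.params)

    def test_inference_is_dropout_free_and_repeatable(self):
        cfg, images, labels = _toy_problem()
        model, _, _ = train(build_model(cfg), images, labels, steps=20)
        a = model.forward(images[:3])
        b = model.forward(images[:3])
        assert np.array_equal(a, b)

    def test_untrained_model_refuses_to_classify(self):
        cfg, _, _ = _toy_problem()
        with pytest.raises(RuntimeError):
            classify(build_model(cfg), np.zeros((12, 10), dtype=np.uint8))

    def test_save_load_round_trip(self, tmp_path):
        cfg, images, labels = _toy_problem()
        model, _, _ = train(build_model(cfg), images, labels, steps=20)
        save_model(model, tmp_path / "m.npz")
        back = load_model(tmp_path / "m.npz")
        assert np.array_equal(back.forward(images[:5]), model.forward(images[:5]))
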