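"""3D convolutional architecture: geometry, parameter counts, training."""

import numpy as np
import pytest

import cardiokin as ck
from cardiokin.model import build_network, count_parameters, total_parameters

REFERENCE_SHAPES = {
    "conv3d": (12, 128, 128, 64),
    "conv3d_1": (6, 64, 64, 128),
    "conv3d_2": (3, 32, 32, 256),
    "conv3d_3": (2, 16, 16, 256),
    "conv3d_4": (1, 4, 4, 256),
    "dense": (1024,),
    "dense_1": (1024,),
    "dense_2": (2,),
}

REFERENCE_PARAMS = {
    "conv3d_1": 221_312,
    "conv3d_2": 884_992,
    "conv3d_3": 1_769_728,
    "conv3d_4": 1_769_728,
    "dense_1": 1_049_600,
    "dense_2": 2_050,
}


class TestArchitecture:
    def test_shape_chain_matches_reference(self):
        spec = ck.build_architecture(in_channels=1, n_classes=2)
        shapes = spec.output_shapes()
        for name, expected in REFERENCE_SHAPES.items():
            assert shapes[name] == expected, name

    def test_parameter_counts_match_reference(self):
        spec = ck.build_architecture(in_channels=1, n_classes=2)
        for name, expected in REFERENCE_PARAMS.items():
            assert count_parameters(spec, name) == expected, name

    def test_first_conv_parameters_scale_with_input_channels(self):
        for c in (1, 3):
            spec = ck.build_architecture(in_channels=c, n_classes=2)
            assert count_parameters(spec, "conv3d") == 27 * c * 64 + 64

    def test_shapes_independent_of_input_channels(self):
        s1 = ck.build_architecture(1, 2).output_shapes()
        s3 = ck.build_architecture(3, 2).output_shapes()
        assert s1 == s3

    def test_multiclass_head(self):
        spec = ck.build_architecture(1, n_classes=5)
        assert spec.output_shapes()["dense_2"] == (5,)
        assert count_parameters(spec, "dense_2") == 1024 * 5 + 5

    def test_invalid_configuration_rejected(self):
        with pytest.raises(ValueError):
            ck.build_architecture(0, 2)
        with pytest.raises(ValueError):
            ck.build_architecture(1, 1)
        with pytest.raises(KeyError):
            count_parameters(ck.build_architecture(1, 2), "conv3d_9")

    def test_total_parameters_finite_and_positive(self):
        spec = ck.build_architecture(1, 2)
        assert total_parameters(spec) > 9_000_000

    def test_forward_shape_on_reduced_geometry(self):
        spec = ck.build_architecture(1, 2, input_shape=(12, 48, 48),
                                     filters=(4, 8, 8, 8, 8), dense_units=32)
        shapes = spec.output_shapes()
        assert shapes["conv3d_4"] == (1, 2, 2, 8)
        net = build_network(spec, seed=0)
        out = net.forward(np.zeros((12, 48, 48, 1)))
        assert out.shape == (2,)


class TestTraining:
    def test_separable_phantoms_reach_perfect_training_accuracy(self, toy_training):
        stacks, model = toy_training
        preds = [model.classes[int(np.argmax(ck.predict(model, s)))]
                 for s in stacks]
        assert all(p == s.label for p, s in zip(preds, stacks))

    def test_loss_decreases_on_separable_task(self, toy_training):
        _, model = toy_training
        assert model.loss_history[-1] < model.loss_history[0]
        assert np.isfinite(model.loss_history).all()

    def test_training_is_deterministic(self, toy_training):
        stacks, model = toy_training
        again = ck.train_binary(stacks, config=ck.TrainConfig(epochs=2),
                                seed=5, spec=model.spec)
        twice = ck.train_binary(stacks, config=ck.TrainConfig(epochs=2),
                                seed=5, spec=model.spec)
        assert again.loss_history == twice.loss_history
        for p, q in zip(again.network.parameters, twice.network.parameters):
            np.testing.assert_array_equal(p, q)

    def test_single_class_input_rejected(self, toy_training):
        stacks, _ = toy_training
        n_only = [s for s in stacks if s.label == "N"]
        with pytest.raises(ValueError, match="classes"):
            ck.train_binary(n_only)


class TestPrediction:
    def test_probabilities_form_a_simplex(self, toy_training):
        stacks, model = toy_training
        p = ck.predict(model, stacks[0])
        assert np.all(p >= 0)
        assert p.sum() == pytest.approx(1.0, abs=1e-6)

    def test_zero_stack_gives_valid_probabilities(self, toy_training):
        stacks, model = toy_training
        zero = np.zeros(stacks[0].shape)
        p = ck.predict(model, zero)
        assert np.isfinite(p).all()
        assert p.sum() == pytest.approx(1.0, abs=1e-6)

    def test_shape_mismatch_rejected(self, toy_training):
        _, model = toy_training
        with pytest.raises(ValueError, match="shape"):
            ck.predict(model, np.zeros((12, 8, 8, 1)))


class TestEmbedding:
    def test_embedding_is_nonnegative_and_sized(self, toy_training):
        stacks, model = toy_training
        emb = ck.extract_embedding(model, stacks[0])
        assert emb.values.shape == (model.spec.layer("dense_1").units,)
        assert np.all(emb.values >= 0)          # post-ReLU
        assert np.isfinite(emb.values).all()
        assert emb.source_layer == "dense_1"

    def test_embedding_is_deterministic(self, toy_training):
        stacks, model = toy_training
        a = ck.extract_embedding(model, stacks[0]).values
        b = ck.extract_embedding(model, stacks[0]).values
        np.testing.assert_array_equal(a, b)

    def test_unknown_layer_rejected(self, toy_training):
        stacks, model = toy_training
        with pytest.raises(ValueError, match="layer"):
            ck.extract_embedding(model, stacks[0], layer="conv3d_2")

    def test_classes_separate_in_embedding_space(self, toy_training):
        stacks, model = toy_training
        embs = {"N": [], "DCM": []}
        for s in stacks:
            embs[s.label].append(ck.extract_embedding(model, s).values)
        def dist(a, b):
            return np.linalg.norm(np.asarray(a) - np.asarray(b))
        within, between = [], []
        for lab, group in embs.items():
            for i in range(len(group)):
                for j in range(i + 1, len(group)):
                    within.append(dist(group[i], group[j]))
        for a in embs["N"]:
            for b in embs["DCM"]:
                between.append(dist(a, b))
        assert np.mean(between) > np.mean(within)
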