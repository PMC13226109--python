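"""Fusion-network contracts: dimension chain, gating, training, CV hygiene."""

import numpy as np
import pytest

from sleepfusion.config import ModelConfig
from sleepfusion.model import (
    EpochInputs, FittedModel, MultiStreamSleepStager, class_weights,
    patientwise_cv, train,
)


@pytest.fixture(scope="module")
def net():
    return MultiStreamSleepStager(ModelConfig())


@pytest.fixture(scope="module")
def batch(rng=None):
    gen = np.random.default_rng(8)
    return (
        gen.normal(size=(5, 8, 3000)),
        gen.normal(size=(5, 8, 32, 32)),
        gen.normal(size=(5, 65)),
    )


class TestDimensionChain:
    def test_embeddings_are_64d(self, net, batch):
        raw, spec, _ = batch
        assert net.forward_1d(raw).shape == (5, 64)
        assert net.forward_2d(spec).shape == (5, 64)
        assert net.forward_1d(raw[0]).shape == (64,)

    def test_fused_is_193d(self, net, batch):
        raw, spec, feat = batch
        fused = net.fuse(net.forward_1d(raw), net.forward_2d(spec), feat)
        assert fused.shape == (5, 193)

    def test_dimension_chain_asserted_at_construction(self):
        with pytest.raises(ValueError, match="193"):
            ModelConfig(handcrafted_dim=60)

    @pytest.mark.parametrize("shape", [(5, 7, 3000), (5, 8, 2999)])
    def test_bad_raw_shape_rejected(self, net, shape):
        with pytest.raises(ValueError):
            net.forward_1d(np.zeros(shape))

    def test_bad_spec_shape_rejected(self, net):
        with pytest.raises(ValueError):
            net.forward_2d(np.zeros((5, 8, 32, 16)))

    def test_eval_mode_deterministic(self, net, batch):
        raw, *_ = batch
        np.testing.assert_array_equal(net.forward_1d(raw), net.forward_1d(raw))


class TestFusionGate:
    def test_identity_gate_returns_concatenation(self, batch):
        net = MultiStreamSleepStager(ModelConfig())
        raw, spec, feat = batch
        e1, e2 = net.forward_1d(raw), net.forward_2d(spec)
        # force the gate MLP output layer to produce huge logits -> g ~ 1
        gate_out = net.gate.net.modules[2]
        gate_out.W.value[...] = 0.0
        gate_out.b.value[...] = 50.0
        fused = net.fuse(e1, e2, feat)
        z = np.concatenate([e1, e2, feat.astype(np.float32)], axis=1)
        np.testing.assert_allclose(fused, z, rtol=1e-5, atol=1e-5)

    def test_zero_gate_returns_zero(self, batch):
        net = MultiStreamSleepStager(ModelConfig())
        raw, spec, feat = batch
        gate_out = net.gate.net.modules[2]
        gate_out.W.value[...] = 0.0
        gate_out.b.value[...] = -50.0
        fused = net.fuse(net.forward_1d(raw), net.forward_2d(spec), feat)
        np.testing.assert_allclose(fused, 0.0, atol=1e-12)

    def test_gate_values_in_open_interval(self, net, batch):
        raw, spec, feat = batch
        net.fuse(net.forward_1d(raw), net.forward_2d(spec), feat)
        g = net.gate.last_gate
        assert (g > 0).all() and (g < 1).all()

    def test_dim_mismatch_rejected(self, net):
        with pytest.raises(ValueError, match="64/64/65"):
            net.fuse(np.zeros((2, 64)), np.zeros((2, 64)), np.zeros((2, 60)))


class TestClassify:
    def test_probability_simplex(self, net, rng):
        pred = net.classify(rng.normal(size=(40, 193)))
        assert (pred.probabilities >= 0).all()
        np.testing.assert_allclose(pred.probabilities.sum(axis=1), 1.0, atol=1e-6)

    def test_argmax_tie_breaks_to_lowest_index(self):
        from sleepfusion.model import StagePrediction

        pred = StagePrediction.from_probabilities(np.array([[1 / 3, 1 / 3, 1 / 3]]))
        assert pred.labels[0] == 0


class TestClassWeights:
    def test_formula(self):
        np.testing.assert_allclose(
            class_weights((600, 300, 100)), [0.5556, 1.1111, 3.3333], atol=1e-4
        )

    def test_balanced_counts_unit_weights(self):
        np.testing.assert_allclose(class_weights((100, 100, 100)), 1.0)

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            class_weights((0, 1, 1))


def _separable_inputs(n_per_class=40, seed=0):
    """Trivially separable toy problem: class signature in every stream."""
    gen = np.random.default_rng(seed)
    raws, specs, feats, labels, subjects = [], [], [], [], []
    for c in range(3):
        n = n_per_class
        raw = gen.normal(0, 0.5, size=(n, 8, 3000)) + c * 2.0
        spec = gen.normal(0, 0.5, size=(n, 8, 32, 32)) - c * 2.0
        feat = gen.normal(0, 0.5, size=(n, 65))
        feat[:, c] += 5.0
        raws.append(raw)
        specs.append(spec)
        feats.append(feat)
        labels.append(np.full(n, c))
        subjects.append(np.array([f"s{c}-{i % 5}" for i in range(n)]))
    return (
        EpochInputs(
            raw=np.concatenate(raws),
            spec=np.concatenate(specs),
            feat=np.concatenate(feats),
        ),
        np.concatenate(labels),
        np.concatenate(subjects),
    )


class TestTraining:
    def test_overfits_separable_data(self):
        inputs, labels, subjects = _separable_inputs(40)
        cfg = ModelConfig(max_epochs=12, early_stop_patience=12, batch_size=32,
                          seed=1)
        fitted = train(inputs, labels, subjects, cfg)
        pred = fitted.predict(inputs)
        acc = (pred.labels == labels).mean()
        assert acc >= 0.99

    def test_same_seed_same_result(self):
        inputs, labels, subjects = _separable_inputs(10, seed=3)
        cfg = ModelConfig(max_epochs=2, early_stop_patience=2, batch_size=16, seed=5)
        h1 = train(inputs, labels, subjects, cfg).history
        h2 = train(inputs, labels, subjects, cfg).history
        assert h1[-1]["val_macro_f1"] == h2[-1]["val_macro_f1"]
        assert h1[-1]["val_loss"] == h2[-1]["val_loss"]

    def test_empty_validation_rejected(self):
        inputs, labels, subjects = _separable_inputs(5, seed=4)
        with pytest.raises(ValueError, match="validation"):
            train(inputs, labels, subjects, ModelConfig(max_epochs=1),
                  val_subjects=[])

    def test_checkpoint_round_trip(self, tmp_path):
        inputs, labels, subjects = _separable_inputs(8, seed=6)
        cfg = ModelConfig(max_epochs=1, early_stop_patience=1, batch_size=16, seed=2)
        fitted = train(inputs, labels, subjects, cfg)
        path = tmp_path / "ckpt.npz"
        fitted.save(path)
        loaded = FittedModel.load(path)
        p1 = fitted.predict(inputs).probabilities
        p2 = loaded.predict(inputs).probabilities
        np.testing.assert_allclose(p1, p2, atol=1e-6)


class TestPatientwiseCV:
    def _dataset(self, n_subjects=5, n_epochs=12, seed=0):
        gen = np.random.default_rng(seed)
        data = {}
        for s in range(n_subjects):
            labels = gen.integers(0, 3, n_epochs)
            feat = gen.normal(size=(n_epochs, 65))
            feat[np.arange(n_epochs), labels] += 5.0
            data[f"sub{s}"] = (
                EpochInputs(
                    raw=gen.normal(size=(n_epochs, 8, 3000)),
                    spec=gen.normal(size=(n_epochs, 8, 32, 32)),
                    feat=feat,
                ),
                labels,
            )
        return data

    def test_partition_and_leakage_guard(self):
        data = self._dataset(10)
        cfg = ModelConfig(max_epochs=1, early_stop_patience=1, batch_size=16)
        pooled, assignment = patientwise_cv(data, k=5, cfg=cfg, seed=0)
        tested = [s for fold in assignment.test_subjects for s in fold]
        assert sorted(tested) == sorted(data.keys())
        assert all(len(f) == 2 for f in assignment.test_subjects)
        for k in range(5):
            assert not set(assignment.dev_subjects[k]) & set(
                assignment.test_subjects[k]
            )
        assignment.validate()  # hard assertion
        assert len(pooled["reference"]) == 10 * 12

    def test_every_epoch_predicted_once(self):
        data = self._dataset(5)
        cfg = ModelConfig(max_epochs=1, early_stop_patience=1, batch_size=16)
        pooled, _ = patientwise_cv(data, k=5, cfg=cfg, seed=1)
        pairs = set(zip(pooled["subject"], pooled["epoch_index"]))
        assert len(pairs) == len(pooled["subject"]) == 5 * 12

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            patientwise_cv(self._dataset(3), k=5)
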