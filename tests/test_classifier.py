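import numpy as np
import pytest

from metabrand.classifier import (
    ClassifierConfig,
    LstmClassifier,
    build_classifier,
    clinical_embedding,
    encode_clinical,
    fit,
    predict_proba,
    wide_deep_fuse,
)
from metabrand.cohort import BinnedMetadata
from metabrand.features import FeatureSequence


def small_config(**kw):
    base = dict(recurrent_units=16, dense_units=8, input_dim=32, timesteps=20,
                learning_rate=1e-2, epochs=15, batch_size=8, seed=0)
    base.update(kw)
    return ClassifierConfig(**base)


def separated_data(rng, n=40, timesteps=20, dim=32, offset=1.0):
    X = rng.standard_normal((n, timesteps, dim)).astype(np.float32) * 0.3
    half = n // 2
    X[:half, :, : dim // 4] += offset
    y = ["aMCI"] * half + ["Control"] * (n - half)
    return X, y


class TestArchitecture:
    def test_default_config_matches_layer_stack(self):
        cfg = ClassifierConfig()
        assert (cfg.recurrent_units, cfg.dense_units, cfg.output_units) == (2048, 512, 2)
        assert cfg.recurrent_dropout_rate == cfg.post_dense_dropout == 0.5
        assert cfg.dense_activation == "sigmoid" and cfg.output_activation == "softmax"

    def test_seeded_init_is_reproducible(self):
        a = build_classifier(small_config())
        b = build_classifier(small_config())
        for k, v in a.parameters().items():
            assert np.array_equal(v, b.parameters()[k])
        c = build_classifier(small_config(seed=1))
        assert not np.array_equal(a.Wx, c.Wx)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            ClassifierConfig(recurrent_units=0)
        with pytest.raises(ValueError):
            ClassifierConfig(recurrent_dropout_rate=1.5)

    def test_accepts_feature_sequence_and_outputs_two_probs(self, rng):
        cfg = ClassifierConfig(recurrent_units=8, dense_units=4)
        model = build_classifier(cfg)
        seq = FeatureSequence(matrix=rng.random((80, 2048)).astype(np.float32))
        probs = predict_proba(model, seq)
        assert probs.shape == (2,)
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)


class TestPredict:
    def test_softmax_simplex_property(self, rng):
        model = build_classifier(small_config())
        X = rng.standard_normal((7, 20, 32)).astype(np.float32) * 10
        probs = model.predict_proba(X)
        assert probs.shape == (7, 2)
        assert (probs >= 0).all()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_untrained_model_is_reproducible(self, rng):
        X = rng.standard_normal((3, 20, 32)).astype(np.float32)
        a = build_classifier(small_config()).predict_proba(X)
        b = build_classifier(small_config()).predict_proba(X)
        np.testing.assert_array_equal(a, b)

    def test_batch_order_preserved(self, rng):
        model = build_classifier(small_config())
        X = rng.standard_normal((5, 20, 32)).astype(np.float32)
        batch = model.predict_proba(X)
        singles = np.stack([model.predict_proba(X[i][None])[0] for i in range(5)])
        np.testing.assert_allclose(batch, singles, atol=1e-6)

    def test_shape_mismatch_rejected(self, rng):
        model = build_classifier(small_config())
        with pytest.raises(ValueError):
            model.predict_proba(rng.random((5, 19, 32)).astype(np.float32))


class TestFit:
    def test_learns_strongly_separated_data(self, rng):
        X, y = separated_data(rng)
        model = build_classifier(small_config(epochs=30))
        fit(model, X, y)
        assert model.history.acc[-1] >= 0.95

    def test_loss_mostly_non_increasing_on_separable_data(self, rng):
        X, y = separated_data(rng)
        model = build_classifier(small_config(epochs=30))
        fit(model, X, y)
        losses = model.history.loss
        upticks = sum(b > a * 1.0 for a, b in zip(losses, losses[1:]))
        assert upticks <= 0.05 * len(losses) + 1

    def test_permutation_control_stays_near_chance(self):
        """Shuffled labels give held-out accuracy ~ 0.5 over 5 seeds."""
        accs = []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            X = rng.standard_normal((48, 20, 32)).astype(np.float32)
            y = np.array(["aMCI"] * 24 + ["Control"] * 24)
            rng.shuffle(y)
            model = build_classifier(small_config(seed=seed, epochs=10))
            fit(model, X[:32], list(y[:32]))
            _, acc = model.evaluate(X[32:], (y[32:] == "aMCI").astype(int))
            accs.append(acc)
        assert abs(float(np.mean(accs)) - 0.5) <= 0.15

    def test_single_class_rejected(self, rng):
        X = rng.random((6, 20, 32)).astype(np.float32)
        with pytest.raises(ValueError, match="per class"):
            fit(build_classifier(small_config()), X, ["aMCI"] * 6)

    def test_empty_training_set_rejected(self):
        X = np.zeros((0, 20, 32), dtype=np.float32)
        with pytest.raises(ValueError):
            fit(build_classifier(small_config()), X, [])

    def test_fit_is_deterministic_given_seed(self, rng):
        X, y = separated_data(rng, n=16)
        a = fit(build_classifier(small_config(epochs=3)), X, y)
        b = fit(build_classifier(small_config(epochs=3)), X, y)
        for k in a.parameters():
            np.testing.assert_array_equal(a.parameters()[k], b.parameters()[k])

    def test_early_stopping_restores_best(self, rng):
        X, y = separated_data(rng, n=24)
        Xv, yv = separated_data(np.random.default_rng(5), n=8)
        model = build_classifier(small_config(epochs=40, early_stopping_patience=3))
        fit(model, X, y, validation=(Xv, yv))
        assert len(model.history.epoch) <= 40
        assert len(model.history.val_loss) == len(model.history.epoch)


def test_save_load_roundtrip(tmp_path, rng):
    X, y = separated_data(rng, n=16)
    model = fit(build_classifier(small_config(epochs=3)), X, y)
    model.save(tmp_path / "model")
    back = LstmClassifier.load(tmp_path / "model")
    np.testing.assert_allclose(
        model.predict_proba(X), back.predict_proba(X), atol=1e-6
    )
    assert (tmp_path / "model" / "history.csv").exists()


class TestClinicalEncoding:
    def test_one_hot_block_positions(self):
        meta = BinnedMetadata("66-75", "Female", "11-13", "Married", "Negative")
        vec = encode_clinical(meta)
        assert vec.shape == (15,)
        assert vec.sum() == 5
        # block offsets 0, 4, 6, 9, 13; positions (2, 0, 1, 0, 1)
        assert list(np.nonzero(vec)[0]) == [2, 4, 7, 9, 14]

    def test_one_variable_change_is_hamming_two(self):
        a = encode_clinical(BinnedMetadata("66-75", "Female", "11-13", "Married", "Negative"))
        b = encode_clinical(BinnedMetadata("66-75", "Male", "11-13", "Married", "Negative"))
        assert int((a != b).sum()) == 2


class TestWideDeep:
    def _seq(self, rng):
        return FeatureSequence(matrix=rng.random((80, 2048)).astype(np.float32))

    def test_all_ones_embedding_is_identity(self, rng):
        seq = self._seq(rng)
        fused = wide_deep_fuse(seq, np.zeros(15), embedding=np.ones(2048))
        np.testing.assert_array_equal(fused.matrix, seq.matrix)
        assert fused.input_mode == "widedeep"

    def test_zero_embedding_annihilates(self, rng):
        fused = wide_deep_fuse(self._seq(rng), np.zeros(15), embedding=np.zeros(2048))
        assert not fused.matrix.any()

    def test_deterministic_given_seed(self, rng):
        seq = self._seq(rng)
        clinical = encode_clinical(
            BinnedMetadata("56-65", "Male", ">=14", "Single", "Positive")
        )
        a = wide_deep_fuse(seq, clinical, projection_seed=3)
        b = wide_deep_fuse(seq, clinical, projection_seed=3)
        np.testing.assert_array_equal(a.matrix, b.matrix)
        c = wide_deep_fuse(seq, clinical, projection_seed=4)
        assert not np.array_equal(a.matrix, c.matrix)

    def test_embedding_dimension_checked(self, rng):
        with pytest.raises(ValueError):
            clinical_embedding(np.zeros(14))
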