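"""Model variants, training behaviour and replica-averaged prediction."""

import numpy as np
import pytest

from cyclicppb.featmap import build_feature_map, replica_count
from cyclicppb.model import (
    ModelConfig,
    build_model,
    load_checkpoint,
    predict,
    save_checkpoint,
    train,
)
from cyclicppb.nn import Conv1dSame


def _toy_maps(n_peptides=10, d=3, seed=0):
    """Tiny synthetic regression task: label is a linear map of the inputs."""
    rng = np.random.default_rng(seed)
    maps, labels = [], []
    w = rng.normal(size=d)
    for i in range(n_peptides):
        n = int(rng.integers(5, 10))
        v = rng.normal(size=(n, d))
        maps.append(build_feature_map(v, peptide_id=f"t{i}"))
        labels.append(float(np.clip(70 + 8 * (v @ w).mean(), 50, 95)))
    return maps, np.array(labels)


class TestBuildModel:
    def test_baseline_has_no_cyclic_layers(self):
        net = build_model(ModelConfig(variant="baseline"))
        convs = [l for l in net.layers if isinstance(l, Conv1dSame)]
        assert convs and all(not c.cyclic for c in convs)

    def test_cyclicconv_augmented_has_cyclic_layers_and_augment_flag(self):
        cfg = ModelConfig(variant="cyclicconv_augmented")
        net = build_model(cfg)
        convs = [l for l in net.layers if isinstance(l, Conv1dSame)]
        assert convs and all(c.cyclic for c in convs)
        assert cfg.augmented

    def test_same_seed_builds_identical_parameters(self):
        a = build_model(ModelConfig(seed=7))
        b = build_model(ModelConfig(seed=7))
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa, pb)

    def test_inconsistent_shape_rejected_at_config_time(self):
        with pytest.raises(ValueError):
            ModelConfig(n_descriptors=0)
        with pytest.raises(ValueError):
            ModelConfig(kernel_size=4)
        with pytest.raises(ValueError):
            ModelConfig(variant="nonesuch")


class TestTrain:
    def test_overfits_a_tiny_dataset_to_sub_percent_mae(self):
        """Capacity sanity: a small net memorizes 10 peptides (3 seeds)."""
        maps, labels = _toy_maps()
        for seed in (0, 1, 2):
            cfg = ModelConfig(
                variant="baseline", conv_channels=(16, 16), fc_widths=(32, 8),
                epochs=500, patience=500, val_fraction=0.0, batch_size=10,
                lr=3e-3, seed=seed,
            )
            net = build_model(cfg)
            train(net, maps, labels, cfg)
            preds = [predict(net, m, augment_input=False).y_hat for m in maps]
            mae = np.mean(np.abs(np.array(preds) - labels))
            assert mae < 1.0, f"seed {seed}: training MAE {mae:.2f}"

    def test_zero_learning_rate_leaves_parameters_unchanged(self):
        maps, labels = _toy_maps(6)
        cfg = ModelConfig(variant="baseline", epochs=3, lr=0.0, batch_size=16,
                          val_fraction=0.0, seed=3)
        net = build_model(cfg)
        before = [p.copy() for p in net.parameters()]
        history = train(net, maps, labels, cfg)
        for p, b in zip(net.parameters(), before):
            np.testing.assert_array_equal(p, b)
        assert np.allclose(history["train_loss"], history["train_loss"][0])

    def test_same_seed_gives_identical_history(self):
        maps, labels = _toy_maps(8)
        cfg = ModelConfig(variant="augmented", epochs=4, seed=11)
        h1 = train(build_model(cfg), maps, labels, cfg)
        h2 = train(build_model(cfg), maps, labels, cfg)
        assert h1["train_loss"] == h2["train_loss"]
        assert h1["val_loss"] == h2["val_loss"]

    def test_mismatched_labels_raise(self):
        maps, labels = _toy_maps(4)
        cfg = ModelConfig(epochs=1)
        with pytest.raises(ValueError):
            train(build_model(cfg), maps, labels[:-1], cfg)


class TestPredict:
    def _trained(self, seed=0):
        maps, labels = _toy_maps(8, seed=seed)
        cfg = ModelConfig(variant="augmented", epochs=5, seed=seed)
        net = build_model(cfg)
        train(net, maps, labels, cfg)
        return net, maps

    def test_replica_count_in_prediction(self):
        net, maps = self._trained()
        res = predict(net, maps[0], augment_input=True)
        assert len(res.replica_predictions) == replica_count(maps[0].n)
        res1 = predict(net, maps[0], augment_input=False)
        assert len(res1.replica_predictions) == 1

    def test_prediction_is_clamped(self):
        net, maps = self._trained()
        res = predict(net, maps[0])
        assert 50.0 <= res.y_hat <= 95.0
        assert res.y_hat == float(np.clip(res.y_hat_raw, 50.0, 95.0))

    def test_rotation_of_the_presented_ring_does_not_change_prediction(self):
        net, maps = self._trained(seed=4)
        fm = maps[0]
        v = fm.ring_vectors()
        for shift in (1, 3):
            rotated = build_feature_map(np.roll(v, shift, axis=0), peptide_id="r")
            a = predict(net, fm, augment_input=True)
            b = predict(net, rotated, augment_input=True)
            assert a.y_hat == b.y_hat  # exact, not approximate

    def test_shape_mismatch_names_both_sides(self):
        net, _ = self._trained()
        bad = build_feature_map(np.zeros((5, 2)))
        with pytest.raises(ValueError, match="model expects"):
            predict(net, bad)


class TestGridSearch:
    def test_picks_the_configuration_with_lowest_validation_loss(self):
        from cyclicppb.model import grid_search

        maps, labels = _toy_maps(8)
        base = ModelConfig(variant="baseline", epochs=3, seed=0)
        best, trace = grid_search(
            maps, labels, base, {"lr": [0.0, 1e-3], "kernel_size": [3]}
        )
        assert len(trace) == 2
        assert best.lr == min(trace, key=lambda t: t["best_val_loss"])["lr"]


class TestCheckpoint:
    def test_roundtrip_preserves_predictions(self, tmp_path):
        maps, labels = _toy_maps(6)
        cfg = ModelConfig(variant="cyclicconv", epochs=3, seed=1)
        net = build_model(cfg)
        train(net, maps, labels, cfg)
        save_checkpoint(tmp_path / "model", net, cfg)
        loaded, cfg2, _ = load_checkpoint(tmp_path / "model")
        for m in maps[:3]:
            assert predict(net, m).y_hat == predict(loaded, m).y_hat
        assert cfg2 == cfg
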