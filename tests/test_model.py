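import numpy as np
import pytest

from lcsod.autodiff import Tensor
from lcsod.errors import ConfigurationError
from lcsod.matching import detection_loss
from lcsod.model import (
    ModelConfig,
    RelationDetector,
    build_model,
    load_checkpoint,
    predict,
    save_checkpoint,
)
from lcsod.relation import RelationParams
from lcsod.synthetic import easy_scenes, generate_scene_dataset
from lcsod.training import TrainConfig, _targets_per_image, train


@pytest.fixture(scope="module")
def tiny_scene():
    ds = generate_scene_dataset(easy_scenes(n_images=6, seed=3))
    images = np.stack([ds.images[i] for i in sorted(ds.images)])
    return ds, images


@pytest.fixture(scope="module")
def mini_model():
    return build_model(ModelConfig.mini(n_classes=3), seed=0)


class TestConfig:
    def test_divisibility_enforced(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(n_classes=3, d_model=65, n_heads=8)

    def test_counts_must_be_positive(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(n_classes=0)

    def test_full_scale_preset_matches_published_shape(self):
        cfg = ModelConfig.full_scale(n_classes=6)
        assert cfg.n_matching_queries == 900
        assert cfg.n_hybrid_candidates == 1500
        assert cfg.k == 6
        assert cfg.d_model == 256 and cfg.n_heads == 8
        assert cfg.n_encoder_layers == 6 and cfg.n_decoder_layers == 6


class TestBuildAndForward:
    def test_same_seed_bitwise_identical_parameters(self):
        a = build_model(ModelConfig.mini(3), seed=11)
        b = build_model(ModelConfig.mini(3), seed=11)
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa.data, pb.data)

    def test_forward_shapes_and_streams(self, tiny_scene, mini_model):
        _, images = tiny_scene
        out = mini_model.forward_train(images[:2])
        cfg = mini_model.config
        assert len(out["matching"]) == cfg.n_decoder_layers
        assert len(out["hybrid"]) == cfg.n_decoder_layers
        last = out["matching"][-1]
        assert last.queries.shape == (2, cfg.n_matching_queries, cfg.d_model)
        assert last.boxes.shape == (2, cfg.n_matching_queries, 4)
        assert last.class_logits.shape == (2, cfg.n_matching_queries,
                                           cfg.n_classes + 1)
        hyb = out["hybrid"][-1]
        assert hyb.boxes.shape == (2, cfg.n_hybrid_candidates, 4)

    def test_boxes_in_unit_cube_and_finite(self, tiny_scene, mini_model):
        _, images = tiny_scene
        out = mini_model.forward_train(images[:3])
        for stream in ("matching", "hybrid"):
            for layer in out[stream]:
                assert np.all(layer.boxes.data >= 0.0)
                assert np.all(layer.boxes.data <= 1.0)
                assert np.all(np.isfinite(layer.class_logits.data))

    def test_forward_deterministic(self, tiny_scene, mini_model):
        _, images = tiny_scene
        a = mini_model.forward_inference(images[:2])
        b = mini_model.forward_inference(images[:2])
        assert np.array_equal(a.boxes.data, b.boxes.data)
        assert np.array_equal(a.class_logits.data, b.class_logits.data)

    def test_empty_batch(self, mini_model):
        out = mini_model.forward_train(np.zeros((0, 64, 64, 3)))
        assert out["matching"] == [] and out["hybrid"] == []


class TestDecodeLayer:
    def test_row_constant_relation_equals_plain_stream(self, tiny_scene):
        """With W = 0 the relation bias is row-constant, so the matching
        computation collapses onto the hybrid (plain) one."""
        _, images = tiny_scene
        model = build_model(ModelConfig.mini(3), seed=4)
        model.relation_W.data[:] = 0.0
        model.relation_A.data[:] = 0.7
        memory = model.encode(images[:2]).detach()
        rng = np.random.default_rng(0)
        q = Tensor(rng.normal(size=(2, 8, model.config.d_model)))
        boxes = np.tile(np.array([0.4, 0.5, 0.2, 0.3]), (2, 8, 1))
        biased = model.decode_layer(0, q, memory, boxes, boxes,
                                    relation_biased=True)
        plain = model.decode_layer(0, q, memory, boxes, boxes,
                                   relation_biased=False)
        assert np.allclose(biased.queries.data, plain.queries.data, atol=1e-10)
        assert np.allclose(biased.boxes.data, plain.boxes.data, atol=1e-10)

    def test_gradient_flows_to_relation_parameters(self, tiny_scene):
        ds, images = tiny_scene
        model = build_model(ModelConfig.mini(3), seed=4)
        targets = _targets_per_image(ds.annotations)
        out = model.forward_train(images[:1])
        cls_idx, boxes = targets[sorted(ds.images)[0]]
        layers = [(lo.class_logits[0], lo.boxes[0]) for lo in out["matching"]]
        total, _ = detection_loss(layers, cls_idx, boxes, 3)
        model.zero_grad()
        total.backward()
        assert model.relation_W.grad is not None
        assert np.abs(model.relation_W.grad).max() > 0.0

    def test_relation_gradient_matches_finite_difference(self, tiny_scene):
        ds, images = tiny_scene
        model = build_model(ModelConfig.mini(3), seed=4)
        i = (5, 2)

        def loss_at(w_value: float) -> float:
            model.relation_W.data[i] = w_value
            out = model.forward_inference(images[:1])
            return float((out.boxes.data ** 2).sum()
                         + (out.class_logits.data ** 2).sum())

        base = model.relation_W.data[i]
        # analytic gradient of the same scalar objective
        out = model.forward_inference(images[:1])
        obj = (out.boxes ** 2).sum() + (out.class_logits ** 2).sum()
        model.zero_grad()
        obj.backward()
        analytic = model.relation_W.grad[i]
        eps = 1e-5
        numeric = (loss_at(base + eps) - loss_at(base - eps)) / (2 * eps)
        model.relation_W.data[i] = base
        assert analytic == pytest.approx(numeric, rel=1e-3, abs=1e-7)


class TestPredict:
    def test_empty_image_list(self, mini_model):
        preds = predict(mini_model, [], [])
        assert len(preds) == 0

    def test_record_count_bounded(self, tiny_scene, mini_model):
        _, images = tiny_scene
        for keep in (3, 300):
            preds = predict(mini_model, images[:2], [1, 2], score_keep=keep)
            bound = min(keep, mini_model.config.n_matching_queries)
            for recs in preds.by_image().values():
                assert len(recs) <= bound

    def test_scores_in_unit_interval(self, tiny_scene, mini_model):
        _, images = tiny_scene
        preds = predict(mini_model, images[:2], [1, 2])
        assert all(0.0 <= r.score <= 1.0 for r in preds.records)


class TestCheckpoint:
    def test_round_trip_preserves_outputs(self, tiny_scene, mini_model, tmp_path):
        _, images = tiny_scene
        path = tmp_path / "model.npz"
        save_checkpoint(mini_model, path)
        again = load_checkpoint(path)
        a = mini_model.forward_inference(images[:2])
        b = again.forward_inference(images[:2])
        assert np.array_equal(a.boxes.data, b.boxes.data)
        assert np.array_equal(a.class_logits.data, b.class_logits.data)


class TestTrainingStep:
    def test_one_epoch_reduces_loss(self, tiny_scene):
        ds, _ = tiny_scene
        model = build_model(ModelConfig.mini(3), seed=1)
        rows = train(model, ds.images, ds.annotations,
                     TrainConfig(epochs=3, batch_size=3, seed=1))
        assert rows[-1]["loss"] < rows[0]["loss"]
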