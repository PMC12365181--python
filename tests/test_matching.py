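import numpy as np
import pytest

from conftest import hungarian_oracle
from lcsod.autodiff import Tensor
from lcsod.coco import BoundingBox
from lcsod.errors import DegenerateBoxError, ValidationError
from lcsod.matching import (
    CostWeights,
    assign,
    cxcywh_to_corners,
    detection_loss,
    giou_aligned_t,
    hungarian_match,
    iou,
    match_cost,
    pairwise_giou_corners,
)


class TestIoU:
    def test_identical_boxes(self):
        box = BoundingBox(3, 4, 10, 12)
        assert iou(box, box) == pytest.approx(1.0)

    def test_disjoint_boxes(self):
        assert iou(BoundingBox(0, 0, 2, 2), BoundingBox(10, 10, 2, 2)) == 0.0

    def test_worked_example_one_third(self):
        assert iou(np.array([0, 0, 2, 2]), np.array([1, 0, 2, 2])) \
            == pytest.approx(1 / 3)

    def test_degenerate_box_rejected(self):
        with pytest.raises(DegenerateBoxError):
            iou(np.array([0, 0, 0, 2]), np.array([1, 0, 2, 2]))


class TestGiou:
    def test_bounded_and_identity(self, rng):
        a = cxcywh_to_corners(np.hstack([rng.uniform(-5, 5, (20, 2)),
                                         rng.uniform(0.5, 4, (20, 2))]))
        b = cxcywh_to_corners(np.hstack([rng.uniform(-5, 5, (20, 2)),
                                         rng.uniform(0.5, 4, (20, 2))]))
        g = pairwise_giou_corners(a, b)
        assert np.all(g > -1.0) and np.all(g <= 1.0 + 1e-12)
        assert np.allclose(np.diag(pairwise_giou_corners(a, a)), 1.0)

    def test_differentiable_matches_pairwise(self, rng):
        pred = np.hstack([rng.uniform(-2, 2, (6, 2)), rng.uniform(0.5, 3, (6, 2))])
        gt = np.hstack([rng.uniform(-2, 2, (6, 2)), rng.uniform(0.5, 3, (6, 2))])
        aligned = giou_aligned_t(Tensor(pred), gt).data
        full = pairwise_giou_corners(cxcywh_to_corners(pred), cxcywh_to_corners(gt))
        assert np.allclose(aligned, np.diag(full), atol=1e-12)


class TestHungarian:
    def test_two_by_two_example(self):
        result = hungarian_match(np.array([[1.0, 2.0], [2.0, 1.0]]))
        assert result.pairs == [(0, 0), (1, 1)]
        assert result.total_cost == pytest.approx(2.0)

    def test_rectangular_single_column(self):
        result = hungarian_match(np.array([[3.0], [1.0], [2.0]]))
        assert result.pairs == [(1, 0)]

    def test_nan_rejected(self):
        with pytest.raises(ValidationError):
            hungarian_match(np.array([[1.0, np.nan], [2.0, 1.0]]))

    def test_matches_permutation_oracle(self, rng):
        for _ in range(60):
            n = int(rng.integers(1, 7))
            m = int(rng.integers(1, 7))
            cost = rng.normal(size=(n, m)) * 10
            result = hungarian_match(cost)
            assert result.total_cost == pytest.approx(hungarian_oracle(cost),
                                                      abs=1e-9)

    def test_one_to_one_never_duplicates(self, rng):
        cost = rng.normal(size=(8, 5))
        result = hungarian_match(cost)
        queries = [q for q, _ in result.pairs]
        gts = [g for _, g in result.pairs]
        assert len(set(queries)) == len(queries)
        assert len(set(gts)) == len(gts)


class TestMatchCost:
    def test_perfect_prediction_has_zero_cost(self):
        gt_boxes = np.array([[0.5, 0.5, 0.2, 0.3]])
        probs = np.array([[1.0, 0.0]])
        cost = match_cost(probs, gt_boxes, np.array([0]), gt_boxes)
        assert cost[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_l1_only_ignores_class(self, rng):
        boxes = np.array([[0.4, 0.4, 0.2, 0.2]])
        probs = rng.uniform(size=(1, 3))
        cost = match_cost(probs, boxes, np.array([1]), boxes,
                          CostWeights(cls=0.0, l1=1.0, giou=0.0))
        assert cost[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_min_cost_assignment_matches_oracle(self, rng):
        probs = rng.uniform(size=(5, 3))
        pred = np.hstack([rng.uniform(0.2, 0.8, (5, 2)), rng.uniform(0.05, 0.3, (5, 2))])
        gt_cls = rng.integers(0, 3, size=4)
        gt = np.hstack([rng.uniform(0.2, 0.8, (4, 2)), rng.uniform(0.05, 0.3, (4, 2))])
        cost = match_cost(probs, pred, gt_cls, gt)
        assert hungarian_match(cost).total_cost == pytest.approx(
            hungarian_oracle(cost), abs=1e-9)


class TestOneToK:
    def test_repeat_counts(self, rng):
        probs = rng.uniform(size=(10, 3))
        pred = np.hstack([rng.uniform(0.2, 0.8, (10, 2)), rng.uniform(0.05, 0.3, (10, 2))])
        gt = np.hstack([rng.uniform(0.2, 0.8, (2, 2)), rng.uniform(0.05, 0.3, (2, 2))])
        result = assign(probs, pred, np.array([0, 1]), gt, mode="one-to-k", k=2)
        assert result.n_matched == 4
        gt_counts = np.bincount(result.gt_indices(), minlength=2)
        assert list(gt_counts) == [2, 2]
        queries = result.query_indices()
        assert len(set(queries)) == len(queries)

    def test_k_exceeding_queries_warns_and_shrinks(self, rng):
        probs = rng.uniform(size=(5, 2))
        pred = np.hstack([rng.uniform(0.2, 0.8, (5, 2)), rng.uniform(0.05, 0.3, (5, 2))])
        gt = pred[:2].copy()
        with pytest.warns(UserWarning, match="one-to-K"):
            result = assign(probs, pred, np.array([0, 1]), gt, mode="one-to-k", k=6)
        assert result.n_matched == 4  # K shrinks to 2 repeats x 2 gts


def _perfect_layer(gt_cls, gt_boxes, n_queries, n_classes):
    logits = np.full((n_queries, n_classes + 1), -20.0)
    logits[:, n_classes] = 20.0
    boxes = np.full((n_queries, 4), 0.5)
    boxes[:, 2:] = 0.1
    for i, (c, b) in enumerate(zip(gt_cls, gt_boxes)):
        logits[i] = -20.0
        logits[i, c] = 20.0
        boxes[i] = b
    return logits, boxes


class TestDetectionLoss:
    def test_perfect_predictions_zero_box_loss(self):
        gt_cls = np.array([0, 1])
        gt_boxes = np.array([[0.3, 0.3, 0.2, 0.2], [0.7, 0.6, 0.1, 0.3]])
        layer = _perfect_layer(gt_cls, gt_boxes, 6, 3)
        _, info = detection_loss([layer], gt_cls, gt_boxes, n_classes=3)
        assert info["components"]["l1"] == pytest.approx(0.0, abs=1e-9)
        assert info["components"]["giou"] == pytest.approx(0.0, abs=1e-9)

    def test_layer_sum(self):
        gt_cls = np.array([0])
        gt_boxes = np.array([[0.4, 0.4, 0.3, 0.3]])
        rng = np.random.default_rng(3)
        logits = rng.normal(size=(5, 4))
        boxes = np.hstack([rng.uniform(0.3, 0.7, (5, 2)), rng.uniform(0.05, 0.3, (5, 2))])
        single, _ = detection_loss([(logits, boxes)], gt_cls, gt_boxes, 3)
        triple, _ = detection_loss([(logits, boxes)] * 3, gt_cls, gt_boxes, 3)
        assert triple.item() == pytest.approx(3 * single.item(), rel=1e-12)

    def test_hybrid_mode_matches_k_times_gt(self, rng):
        gt_cls = np.array([0, 2])
        gt_boxes = np.array([[0.3, 0.3, 0.2, 0.2], [0.6, 0.6, 0.2, 0.2]])
        logits = rng.normal(size=(40, 4))
        boxes = np.hstack([rng.uniform(0.2, 0.8, (40, 2)), rng.uniform(0.05, 0.3, (40, 2))])
        _, info = detection_loss([(logits, boxes)], gt_cls, gt_boxes, 3,
                                 mode="one-to-k", k=6)
        assert info["assignments"][0].n_matched == 12

    def test_loss_nonnegative(self, rng):
        gt_cls = np.array([1])
        gt_boxes = np.array([[0.5, 0.5, 0.2, 0.2]])
        for _ in range(10):
            logits = rng.normal(size=(4, 3)) * 3
            boxes = np.hstack([rng.uniform(0.2, 0.8, (4, 2)),
                               rng.uniform(0.05, 0.4, (4, 2))])
            total, _ = detection_loss([(logits, boxes)], gt_cls, gt_boxes, 2)
            assert total.item() >= 0.0

    def test_no_ground_truth_classifies_background(self):
        logits = np.zeros((3, 4))
        boxes = np.full((3, 4), 0.5)
        total, info = detection_loss([(logits, boxes)], np.array([], int),
                                     np.zeros((0, 4)), 3)
        assert info["assignments"][0].n_matched == 0
        assert total.item() > 0  # background focal term remains
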