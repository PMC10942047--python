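"""Preprocessing, augmentation, loss, CV protocol, metrics and Grad-CAM."""

import math
from itertools import product

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from readerprob.classifier import (
    AugmentationPolicy,
    SmallCNN,
    auc_rank,
    augment,
    compute_metrics,
    grad_cam,
    make_cv_plan,
    multi_target_loss,
    sample_augmentation_params,
)
from readerprob.classifier.preprocess import preprocess
from readerprob.synthetic import ImageConfig, apex_mask


# ------------------------------------------------------------- preprocessing

def test_preprocess_crop_and_resize():
    img = np.random.default_rng(0).random((320, 300))
    out = preprocess(img, crop_side=300, out_side=64)
    assert out.shape == (64, 64)
    # centered crop: a 300x300 window from rows 10..310
    direct = preprocess(img[10:310, :], crop_side=300, out_side=64)
    np.testing.assert_allclose(out, direct)


def test_preprocess_constant_image_stays_constant():
    img = np.full((128, 128), 0.7)
    out = preprocess(img, crop_side=128, out_side=64)
    np.testing.assert_allclose(out, 0.7, atol=1e-12)


def test_preprocess_integer_scaling_and_errors():
    img = np.full((100, 100), 255, dtype=np.uint8)
    out = preprocess(img, crop_side=100, out_side=50)
    np.testing.assert_allclose(out, 1.0, atol=1e-12)
    with pytest.raises(ValueError):
        preprocess(np.zeros((64, 64)), crop_side=100, out_side=50)


# -------------------------------------------------------------- augmentation

@pytest.mark.parametrize("side,expected", [(256, 13), (64, 3), (100, 5)])
def test_max_shift_rounding(side, expected):
    assert AugmentationPolicy().max_shift(side) == expected


def test_augmentation_bounds_over_many_draws():
    rng = np.random.default_rng(7)
    policy = AugmentationPolicy()
    for _ in range(10_000):
        angle, dx, dy = sample_augmentation_params(policy, 256, rng)
        assert -5 < angle < 5
        assert abs(dx) <= 13 and abs(dy) <= 13


def test_null_policy_is_identity():
    img = np.random.default_rng(1).random((32, 32))
    policy = AugmentationPolicy(shift_fraction=0.0, rotation_limit_degrees=0.0)
    np.testing.assert_array_equal(augment(img, policy, np.random.default_rng(0)), img)


def test_pure_shift_matches_roll():
    img = np.zeros((32, 32))
    img[10, 12] = 1.0
    policy = AugmentationPolicy(shift_fraction=0.2, rotation_limit_degrees=0.0)
    rng = np.random.default_rng(3)
    angle, dx, dy = sample_augmentation_params(policy, 32, np.random.default_rng(3))
    out = augment(img, policy, rng)
    assert out[10 + dy, 12 + dx] == 1.0
    assert out.sum() == 1.0  # zero fill, single hot pixel


# ---------------------------------------------------------------------- loss

def test_multi_target_loss_values():
    assert multi_target_loss((0.0, 0.0), (0, 0)) == pytest.approx(2 * math.log(2), abs=1e-12)
    assert multi_target_loss((30.0, 30.0), (1, 1)) < 1e-9
    with pytest.raises(ValueError):
        multi_target_loss((np.inf, 0.0), (1, 0))


def test_multi_target_loss_additivity_and_naive_oracle():
    rng = np.random.default_rng(11)
    for _ in range(50):
        u = rng.uniform(-8, 8, 2)
        y = rng.integers(0, 2, 2)
        total = multi_target_loss(u, y)
        parts = sum(multi_target_loss((ui,), (yi,)) for ui, yi in zip(u, y))
        assert total == pytest.approx(parts, abs=1e-12)
        # direct (unstable) definition at moderate logits
        s = 1 / (1 + np.exp(-u))
        naive = -np.sum(y * np.log(s) + (1 - y) * np.log(1 - s))
        assert total == pytest.approx(naive, abs=1e-9)


# ------------------------------------------------------------------ CV plan

def test_cv_plan_partition_properties():
    ids = [f"S{i}" for i in range(11_000)]
    plan = make_cv_plan(ids, k=10, test_n=1000, seed=5)
    assert len(plan.test_ids) == 1000
    assert all(len(f) == 1000 for f in plan.folds)
    seen = set(plan.test_ids)
    for f in plan.folds:
        assert seen.isdisjoint(f)
        seen.update(f)
    assert seen == set(ids)


def test_cv_plan_uneven_folds_and_determinism():
    ids = [f"S{i}" for i in range(107)]
    plan = make_cv_plan(ids, k=10, test_n=20, seed=1)
    sizes = sorted(len(f) for f in plan.folds)
    assert max(sizes) - min(sizes) <= 1 and sum(sizes) == 87
    assert plan == make_cv_plan(ids, k=10, test_n=20, seed=1)
    with pytest.raises(ValueError):
        make_cv_plan(ids, test_n=107)


# ------------------------------------------------------------------- metrics

def test_metrics_on_perfect_separation():
    m = compute_metrics([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
    assert m["AUC"] == 1.0 and m["Acc."] == 1.0 and m["F1"] == 1.0
    assert m["Spec."] == 1.0 and m["Prec."] == 1.0 and m["Rec."] == 1.0


def test_auc_matches_pair_counting_oracle():
    rng = np.random.default_rng(21)
    scores = np.round(rng.random(50), 1)  # coarse grid forces ties
    labels = rng.integers(0, 2, 50)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    pairs = [(0.5 if a == b else float(a > b)) for a in pos for b in neg]
    assert auc_rank(scores, labels) == pytest.approx(np.mean(pairs), abs=1e-12)
    assert auc_rank(scores, labels) == pytest.approx(
        roc_auc_score(labels, scores), abs=1e-12
    )


def test_metrics_exhaustive_small_instances():
    # every label pattern with both classes for several score vectors, n <= 8
    rng = np.random.default_rng(31)
    for n in (2, 4, 6, 8):
        scores = np.round(rng.random(n), 1)
        for labels in product((0, 1), repeat=n):
            if len(set(labels)) < 2:
                with pytest.raises(ValueError):
                    auc_rank(scores, labels)
                continue
            y = np.array(labels)
            pos, neg = scores[y == 1], scores[y == 0]
            oracle = np.mean([(0.5 if a == b else float(a > b))
                              for a in pos for b in neg])
            m = compute_metrics(scores, y)
            assert m["AUC"] == pytest.approx(oracle, abs=1e-12)
            pred = (scores >= 0.5).astype(int)
            assert m["Acc."] == pytest.approx(np.mean(pred == y), abs=1e-12)


def test_precision_zero_division_warns():
    with pytest.warns(UserWarning):
        m = compute_metrics([0.1, 0.2, 0.3], [1, 0, 1], threshold=0.9)
    assert m["Prec."] == 0.0


# ------------------------------------------------------------------ grad-cam

class _ToyBackend:
    """Finding logit = mean of feature map 0; maps are fixed."""

    def __init__(self, maps):
        self.maps = maps

    def feature_maps_and_grads(self, image, finding):
        grads = np.zeros_like(self.maps)
        grads[0] = 1.0 / self.maps[0].size
        return self.maps, grads


def test_grad_cam_toy_model_proportional_to_relu_map():
    rng = np.random.default_rng(4)
    maps = rng.normal(size=(3, 8, 8))
    cam = grad_cam(_ToyBackend(maps), np.zeros((8, 8)), finding=0)
    ref = np.maximum(maps[0], 0)
    np.testing.assert_allclose(cam, ref / ref.max(), atol=1e-12)
    assert cam.min() >= 0 and cam.max() <= 1


def test_grad_cam_requires_feature_access():
    with pytest.raises(TypeError):
        grad_cam(object(), np.zeros((8, 8)), 0)


def test_grad_cam_trained_model_focuses_on_apex(trained_model, small_cohort):
    cfg, truths, annotations, images, labels = small_cohort
    # a strongly apical-positive, spine-quiet subject
    idx = int(np.argmax([t.severity["pleural_thickening"] for t in truths]))
    cam = grad_cam(trained_model, images[idx], finding=0)
    assert cam.min() >= 0 and cam.max() <= 1
    mask = apex_mask(ImageConfig())
    apex_share = cam[mask].sum() / max(cam.sum(), 1e-12)
    uniform_share = mask.mean()
    assert apex_share > uniform_share
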