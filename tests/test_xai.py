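"""Score-CAM tests: primitives, algorithm contracts, and a scalar-loop oracle."""

import math

import numpy as np
import pytest

from nosecam.models import TrainedClassifier
from nosecam.nn import SmallCNN
from nosecam.xai import ImportanceMap, mask_input, minmax_norm, scorecam, upsample_map


class TestUpsample:
    def test_constant_map_stays_constant(self):
        out = upsample_map(np.full((5, 7), 0.7))
        assert out.shape == (40, 14)
        np.testing.assert_allclose(out, 0.7, atol=1e-12)

    def test_identity_at_target_size(self):
        m = np.random.default_rng(0).random((40, 14))
        np.testing.assert_array_equal(upsample_map(m), m)

    def test_bilinear_center_symmetry(self):
        # [[0,1],[1,0]] -> exact center of the upsampled grid is 0.5
        out = upsample_map(np.array([[0.0, 1.0], [1.0, 0.0]]), target=(41, 15))
        assert out[20, 7] == pytest.approx(0.5, abs=1e-12)

    def test_empty_and_oversized_rejected(self):
        with pytest.raises(ValueError):
            upsample_map(np.empty((0, 2)))
        with pytest.raises(ValueError):
            upsample_map(np.zeros((50, 14)))


class TestMinMaxNorm:
    def test_simple_vector(self):
        np.testing.assert_allclose(minmax_norm(np.array([1.0, 3.0, 5.0])), [0, 0.5, 1])

    def test_constant_maps_to_zeros(self):
        assert np.all(minmax_norm(np.full((3, 3), 4.2)) == 0)

    def test_idempotent_on_unit_range(self):
        m = np.array([[0.0, 0.25], [0.75, 1.0]])
        np.testing.assert_array_equal(minmax_norm(m), m)


class TestMaskInput:
    def test_ones_identity_and_zeros(self):
        x = np.random.default_rng(1).random((40, 14, 3))
        np.testing.assert_array_equal(mask_input(x, np.ones((40, 14))), x)
        assert np.all(mask_input(x, np.zeros((40, 14))) == 0)

    def test_single_point_mask(self):
        x = np.ones((40, 14, 3))
        h = np.zeros((40, 14))
        h[5, 3] = 1.0
        out = mask_input(x, h)
        assert out.sum() == 3.0
        assert np.all(out[5, 3, :] == 1.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mask"):
            mask_input(np.zeros((40, 14, 3)), np.zeros((14, 40)))


class _ScriptedModel:
    """Stand-in classifier with scripted activation maps and masked scores.

    Score order follows the map order (Score-CAM scores masks in map
    order), so permuting (maps, scores) together emulates a network
    whose final-layer filters were reordered.
    """

    def __init__(self, maps, scores):
        self.maps = np.asarray(maps, float)
        self.scores = np.asarray(scores, float)
        self.classes = ["neg", "pos"]
        self._calls = 0

    def class_index(self, label):
        if label not in self.classes:
            raise KeyError(label)
        return self.classes.index(label)

    def activation_maps(self, x):
        return self.maps

    def predict_proba(self, x):
        k = x.shape[0]
        s = self.scores[:k]
        return np.stack([1 - s, s], axis=1)


class TestScorecamAlgebra:
    def test_single_map_returns_normalized_mask(self):
        rng = np.random.default_rng(2)
        m = rng.random((10, 7))
        model = _ScriptedModel([m], [0.9])
        out = scorecam(model, np.ones((40, 14, 3)), "pos")
        np.testing.assert_allclose(out.values, minmax_norm(upsample_map(m)), atol=1e-12)

    def test_identical_maps_collapse_to_single_map_result(self):
        m = np.random.default_rng(3).random((10, 7))
        one = scorecam(_ScriptedModel([m], [0.5]), np.ones((40, 14, 3)), "pos")
        four = scorecam(_ScriptedModel([m] * 4, [0.1, 0.4, 0.7, 0.9]), np.ones((40, 14, 3)), "pos")
        np.testing.assert_allclose(four.values, one.values, atol=1e-12)

    def test_invariant_under_map_permutation(self):
        rng = np.random.default_rng(4)
        maps = rng.random((5, 10, 7))
        scores = rng.random(5)
        base = scorecam(_ScriptedModel(maps, scores), np.ones((40, 14, 3)), "pos")
        perm = rng.permutation(5)
        shuffled = scorecam(_ScriptedModel(maps[perm], scores[perm]), np.ones((40, 14, 3)), "pos")
        np.testing.assert_allclose(shuffled.values, base.values, atol=1e-12)

    def test_dominant_map_controls_argmax(self):
        # three non-overlapping peaked maps; the first gets a much larger score
        maps = np.zeros((3, 40, 14))
        maps[0, 10, 3] = 1.0
        maps[1, 30, 8] = 1.0
        maps[2, 5, 12] = 1.0
        out = scorecam(_ScriptedModel(maps, [0.99, 0.01, 0.01]), np.ones((40, 14, 3)), "pos")
        assert np.unravel_index(out.values.argmax(), out.values.shape) == (10, 3)

    def test_unknown_class_rejected(self):
        with pytest.raises(KeyError):
            scorecam(_ScriptedModel([np.zeros((2, 2))], [0.5]), np.ones((40, 14, 3)), "bogus")

    def test_output_bounds_and_weights(self):
        maps = np.random.default_rng(5).random((4, 20, 14))
        out = scorecam(_ScriptedModel(maps, [0.2, 0.4, 0.1, 0.3]), np.ones((40, 14, 3)), "pos")
        assert out.values.min() >= 0 and out.values.max() <= 1
        assert out.weights.shape == (4,)
        assert out.weights.sum() == pytest.approx(1.0, abs=1e-9)


def _oracle_scorecam(model, x, target_class):
    """Independent scalar-loop Score-CAM reference.

    Everything is written with explicit Python loops and closed-form
    bilinear interpolation; the network is queried one masked input at a
    time.
    """
    ci = model.classes.index(target_class)
    maps = model.net.activation_maps(x)  # (K, hf, wf)
    k_total, hf, wf = maps.shape
    ht, wt = 40, 14
    masks = []
    for k in range(k_total):
        up = np.empty((ht, wt))
        for i in range(ht):
            for j in range(wt):
                r = i * (hf - 1) / (ht - 1) if hf > 1 else 0.0
                c = j * (wf - 1) / (wt - 1) if wf > 1 else 0.0
                r0, c0 = int(math.floor(r)), int(math.floor(c))
                r1, c1 = min(r0 + 1, hf - 1), min(c0 + 1, wf - 1)
                fr, fc = r - r0, c - c0
                up[i, j] = (
                    maps[k, r0, c0] * (1 - fr) * (1 - fc)
                    + maps[k, r1, c0] * fr * (1 - fc)
                    + maps[k, r0, c1] * (1 - fr) * fc
                    + maps[k, r1, c1] * fr * fc
                )
        lo, hi = up.min(), up.max()
        masks.append((up - lo) / (hi - lo) if hi > lo else np.zeros_like(up))
    scores = []
    for h in masks:
        masked = np.empty_like(x)
        for p in range(3):
            for i in range(ht):
                for j in range(wt):
                    masked[i, j, p] = x[i, j, p] * h[i, j]
        scores.append(model.net.predict_proba(masked)[ci])
    exp = [math.exp(s - max(scores)) for s in scores]
    alphas = [e / sum(exp) for e in exp]
    combined = np.zeros((ht, wt))
    for a, h in zip(alphas, masks):
        combined += a * h
    combined = np.maximum(combined, 0.0)
    lo, hi = combined.min(), combined.max()
    return (combined - lo) / (hi - lo) if hi > lo else np.zeros_like(combined)


class TestScorecamOracle:
    def test_matches_scalar_loop_reference(self):
        """Vectorized Score-CAM equals the loop oracle entry-for-entry on a
        tiny fixed-weight CNN and a fixed input."""
        net = SmallCNN(input_shape=(40, 14, 3), conv_filters=(2,), kernel=(3, 3),
                       dense=8, n_classes=2, seed=99)
        # hand-set filters: one time-gradient detector, one channel bump
        net.params["Wc0"][...] = 0.0
        net.params["Wc0"][0, 1, 0, 0] = -1.0
        net.params["Wc0"][2, 1, 0, 0] = 1.0
        net.params["Wc0"][1, 1, 1, 1] = 1.0
        clf = TrainedClassifier(net, ["neg", "pos"])
        rng = np.random.default_rng(123)
        x = rng.random((40, 14, 3))
        fast = scorecam(clf, x, "pos")
        slow = _oracle_scorecam(clf, x, "pos")
        np.testing.assert_allclose(fast.values, slow, atol=1e-6)
        assert clf.n_forward == 2 + 1  # K + 1 forward passes

    def test_forward_pass_budget_is_k_plus_one(self):
        net = SmallCNN(input_shape=(40, 14, 3), conv_filters=(16,), kernel=(3, 3),
                       dense=8, n_classes=3, seed=1)
        clf = TrainedClassifier(net, ["a", "b", "c"])
        scorecam(clf, np.random.default_rng(0).random((40, 14, 3)), "b")
        assert clf.n_forward == 16 + 1


def test_importance_map_validates_range():
    with pytest.raises(ValueError):
        ImportanceMap(values=np.full((40, 14), 1.5), target_class="x")
    with pytest.raises(ValueError):
        ImportanceMap(values=np.zeros((14, 40)), target_class="x")
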