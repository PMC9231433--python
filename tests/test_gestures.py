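"""Gesture windows, the two-layer classifier, and pair-sequence decoding."""

import numpy as np
import pytest

from freewheel.commands import Direction
from freewheel.filters import SignalTrace
from freewheel.gestures import (
    GESTURES,
    PAIR_ACTIONS,
    WINDOW_LEN,
    AnnModel,
    GestureSequenceDecoder,
    GestureWindow,
    TrainingError,
    VocabularyError,
    WindowShapeError,
    classify_gesture,
    condition_and_window,
    decode_gesture_sequence,
    train_gesture_ann,
    window_to_features,
)
from freewheel.synth import GestureTemplateParams, gen_gesture_window

from conftest import conditioned_dataset


class TestWindowing:
    def test_zero_traces_stay_zero(self):
        """Linear filters preserve the zero signal."""
        z = SignalTrace(np.zeros(WINDOW_LEN))
        win = condition_and_window(z, z)
        assert np.all(win.left == 0) and np.all(win.right == 0)

    def test_length_preserved(self):
        rng = np.random.default_rng(0)
        tr = lambda: SignalTrace(rng.normal(2, 0.1, WINDOW_LEN))
        win = condition_and_window(tr(), tr())
        assert len(win.left) == len(win.right) == WINDOW_LEN

    def test_wrong_length_rejected(self):
        with pytest.raises(WindowShapeError):
            condition_and_window(SignalTrace(np.zeros(10)), SignalTrace(np.zeros(WINDOW_LEN)))

    def test_dc_offset_removed_from_generated_template(self):
        """Conditioning strips the 2 V baseline the generator adds."""
        params = GestureTemplateParams(noise_sigma=0.0)
        raw = gen_gesture_window("left", params)
        win = condition_and_window(SignalTrace(raw.left), SignalTrace(raw.right))
        for filtered in (win.left, win.right):
            assert np.mean(np.abs(filtered)) < params.baseline_dc

    def test_features_concatenate_left_then_right(self):
        win = GestureWindow(np.ones(WINDOW_LEN), 2 * np.ones(WINDOW_LEN))
        feats = window_to_features(win)
        assert feats.shape == (2 * WINDOW_LEN,)
        assert np.all(feats[:WINDOW_LEN] == 1) and np.all(feats[WINDOW_LEN:] == 2)

    def test_zero_window_zero_features(self):
        win = GestureWindow(np.zeros(WINDOW_LEN), np.zeros(WINDOW_LEN))
        assert np.all(window_to_features(win) == 0)


class TestTraining:
    def test_model_shape_is_10_hidden_4_out(self, trained_model):
        model, _ = trained_model
        assert model.hidden_weights.shape == (10, 2 * WINDOW_LEN)
        assert model.output_weights.shape == (4, 10)
        assert model.label_order == GESTURES

    def test_holdout_accuracy_high(self, trained_model):
        _, accuracy = trained_model
        assert accuracy >= 0.95

    def test_same_seed_same_model(self, small_dataset):
        m1, _ = train_gesture_ann(small_dataset, train_seed=42)
        m2, _ = train_gesture_ann(small_dataset, train_seed=42)
        np.testing.assert_array_equal(m1.hidden_weights, m2.hidden_weights)
        np.testing.assert_array_equal(m1.output_weights, m2.output_weights)

    def test_single_label_dataset_rejected(self, small_dataset):
        one_class = [w for w in small_dataset if w.label == "left"]
        with pytest.raises(TrainingError):
            train_gesture_ann(one_class)

    def test_empty_dataset_rejected(self):
        with pytest.raises(TrainingError):
            train_gesture_ann([])

    def test_json_roundtrip(self, trained_model, tmp_path, small_dataset):
        model, _ = trained_model
        path = tmp_path / "model.json"
        model.to_json(path)
        back = AnnModel.from_json(path)
        probs_a = model.forward(window_to_features(small_dataset[0]))
        probs_b = back.forward(window_to_features(small_dataset[0]))
        np.testing.assert_allclose(probs_a, probs_b, atol=1e-12)


def _naive_forward(model, features):
    """Independent brute-force forward pass with explicit python loops."""
    import math

    z = [(features[j] - model.feat_mean[j]) / model.feat_std[j] for j in range(len(features))]
    hidden = []
    for i in range(model.hidden_weights.shape[0]):
        s = model.hidden_biases[i]
        for j in range(len(z)):
            s += model.hidden_weights[i][j] * z[j]
        hidden.append(math.tanh(s))
    logits = []
    for k in range(model.output_weights.shape[0]):
        s = model.output_biases[k]
        for i in range(len(hidden)):
            s += model.output_weights[k][i] * hidden[i]
        logits.append(s)
    mx = max(logits)
    exps = [math.exp(v - mx) for v in logits]
    total = sum(exps)
    return [e / total for e in exps]


class TestClassification:
    def test_scores_sum_to_one(self, trained_model, small_dataset):
        model, _ = trained_model
        for win in small_dataset[::13]:
            _, scores = classify_gesture(model, win)
            assert np.all(scores >= 0)
            assert scores.sum() == pytest.approx(1.0, abs=1e-9)

    def test_noise_free_templates_recovered(self, trained_model):
        """Clean per-class templates classify to their own label."""
        model, _ = trained_model
        params = GestureTemplateParams(noise_sigma=0.0)
        for label in GESTURES:
            raw = gen_gesture_window(label, params)
            win = condition_and_window(SignalTrace(raw.left), SignalTrace(raw.right))
            predicted, _ = classify_gesture(model, win)
            assert predicted == label

    def test_agrees_with_bruteforce_oracle(self, trained_model):
        model, _ = trained_model
        rng = np.random.default_rng(123)
        for _ in range(20):
            win = GestureWindow(rng.normal(0, 0.3, WINDOW_LEN), rng.normal(0, 0.3, WINDOW_LEN))
            label, scores = classify_gesture(model, win)
            oracle = _naive_forward(model, window_to_features(win))
            np.testing.assert_allclose(scores, oracle, atol=1e-9)
            assert label == GESTURES[int(np.argmax(oracle))]

    def test_feature_length_mismatch_rejected(self, trained_model):
        model, _ = trained_model
        with pytest.raises(WindowShapeError):
            model.forward(np.zeros(99))

    def test_tie_breaks_by_label_order(self):
        """Zero weights give a uniform score vector; argmax picks label 0."""
        F = 2 * WINDOW_LEN
        flat = AnnModel(
            hidden_weights=np.zeros((10, F)),
            hidden_biases=np.zeros(10),
            output_weights=np.zeros((4, 10)),
            output_biases=np.zeros(4),
            feat_mean=np.zeros(F),
            feat_std=np.ones(F),
        )
        win = GestureWindow(np.ones(WINDOW_LEN), np.ones(WINDOW_LEN))
        label, scores = classify_gesture(flat, win)
        np.testing.assert_allclose(scores, 0.25)
        assert label == GESTURES[0]

    def test_label_recovery_across_generator_seeds(self):
        """Mean held-out accuracy over 5 dataset seeds stays >= 0.95."""
        accs = []
        for seed in range(5):
            data = conditioned_dataset(10, template_seed=seed)
            _, acc = train_gesture_ann(data, train_seed=seed)
            accs.append(acc)
        assert np.mean(accs) >= 0.95


class TestSequenceDecoding:
    def test_exhaustive_pair_truth_table(self):
        """All 16 ordered gesture pairs: 4 mapped actions, 12 no-ops."""
        for first in GESTURES:
            for second in GESTURES:
                events = decode_gesture_sequence([first, second])
                expected = PAIR_ACTIONS.get((first, second))
                if expected is None:
                    assert events == []
                else:
                    assert events == [(1, expected)]

    @pytest.mark.parametrize(
        "pair, action",
        [
            (("left", "left"), Direction.LEFT),
            (("right", "right"), Direction.RIGHT),
            (("right", "close"), Direction.FORWARD),
            (("left", "close"), Direction.BACKWARD),
        ],
    )
    def test_mapped_pairs(self, pair, action):
        assert decode_gesture_sequence(list(pair)) == [(1, action)]

    def test_idle_gap_within_timeout_still_pairs(self):
        labels = ["left", "open", "open", "left"]
        assert decode_gesture_sequence(labels, timeout_windows=3) == [(3, Direction.LEFT)]

    def test_idle_gap_beyond_timeout_resets(self):
        labels = ["left", "open", "open", "open", "open", "left"]
        # the pending 'left' expires; the final 'left' becomes a new pending
        assert decode_gesture_sequence(labels, timeout_windows=3) == []

    def test_unmatched_pair_resets_state(self):
        # (left, right) is a no-op and clears; following (left, close) decodes fresh
        labels = ["left", "right", "left", "close"]
        assert decode_gesture_sequence(labels) == [(3, Direction.BACKWARD)]

    def test_unknown_label_rejected(self):
        with pytest.raises(VocabularyError):
            GestureSequenceDecoder().step("blink")
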