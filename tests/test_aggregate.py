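"""Majority voting, ensemble grading and evaluation statistics."""

from collections import Counter

import numpy as np
import pytest

import patchvote as pv

CLASSES3 = ("MCT1", "MCT2", "MCT3")


def make_pred(probs, classes=CLASSES3, image_id="img"):
    probs = np.asarray(probs, dtype=float)
    return pv.PatchPrediction(probabilities=probs / probs.sum(),
                              classes=classes, image_id=image_id)


def onehot_pred(label, classes=CLASSES3, image_id="img", confidence=0.9):
    k = len(classes)
    probs = np.full(k, (1 - confidence) / (k - 1))
    probs[classes.index(label)] = confidence
    return make_pred(probs, classes, image_id)


class TestImageMajorityVote:
    def test_strict_majority(self):
        preds = [onehot_pred("MCT2")] * 7 + [onehot_pred("MCT3")] * 3
        vote = pv.image_majority_vote(preds)
        assert vote.label == "MCT2"
        assert vote.vote_counts == {"MCT1": 0, "MCT2": 7, "MCT3": 3}
        assert vote.n_patches == 10

    def test_tie_broken_by_mean_probability(self):
        classes = ("MCT", "MEL")
        a = [make_pred([0.52, 0.48], classes)] * 5   # argmax MCT, weak
        b = [make_pred([0.10, 0.90], classes)] * 5   # argmax MEL, strong
        vote = pv.image_majority_vote(a + b)
        assert vote.label == "MEL"

    def test_tie_and_equal_probability_uses_class_order(self):
        classes = ("A", "B")
        preds = [make_pred([0.8, 0.2], classes), make_pred([0.2, 0.8], classes)]
        assert pv.image_majority_vote(preds).label == "A"

    def test_single_patch(self):
        vote = pv.image_majority_vote([onehot_pred("MCT3")])
        assert vote.label == "MCT3"

    def test_empty_and_mixed_rejected(self):
        with pytest.raises(pv.InvalidDataError):
            pv.image_majority_vote([])
        with pytest.raises(pv.InvalidDataError):
            pv.image_majority_vote([onehot_pred("MCT1", image_id="a"),
                                    onehot_pred("MCT1", image_id="b")])


class TestEnsembleGrade:
    def test_unanimous(self):
        lists = [[onehot_pred("MCT2")] * 4 for _ in range(3)]
        assert pv.ensemble_grade(lists).label == "MCT2"

    def test_pooled_ballot_mode(self):
        # 10 patches x 3 models: 12 MCT1, 10 MCT2, 8 MCT3 ballots
        ballots = ["MCT1"] * 12 + ["MCT2"] * 10 + ["MCT3"] * 8
        lists = [[onehot_pred(b) for b in ballots[k::3]] for k in range(3)]
        vote = pv.ensemble_grade(lists)
        assert vote.label == "MCT1"
        assert vote.n_patches == 30

    def test_matches_mode_oracle_on_random_ballots(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 12))
            lists = []
            for _ in range(3):
                lists.append([onehot_pred(CLASSES3[rng.integers(0, 3)],
                                          confidence=rng.uniform(0.5, 0.99))
                              for _ in range(n)])
            vote = pv.ensemble_grade(lists)
            counts = Counter(p.label for preds in lists for p in preds)
            top = max(counts.values())
            assert counts[vote.label] == top

    def test_average_mode_uses_mean_probability(self):
        classes = ("MCT1", "MCT2", "MCT3")
        lists = [[make_pred([0.4, 0.35, 0.25], classes)],
                 [make_pred([0.4, 0.35, 0.25], classes)],
                 [make_pred([0.0, 0.9, 0.1], classes)]]
        assert pv.ensemble_grade(lists, mode="vote").label == "MCT1"
        assert pv.ensemble_grade(lists, mode="average").label == "MCT2"

    def test_length_mismatch_rejected(self):
        lists = [[onehot_pred("MCT1")] * 2, [onehot_pred("MCT1")] * 3,
                 [onehot_pred("MCT1")] * 2]
        with pytest.raises(pv.InvalidDataError):
            pv.ensemble_grade(lists)

    def test_unknown_mode_rejected(self):
        with pytest.raises(pv.InvalidParameterError):
            pv.ensemble_grade([[onehot_pred("MCT1")]] * 3, mode="median")


class TestComputeReport:
    def _image_pred(self, image_id, label, classes=("A", "B")):
        return pv.image_majority_vote(
            [onehot_pred(label, classes, image_id) for _ in range(3)])

    def test_all_correct(self):
        classes = ("A", "B")
        preds = [self._image_pred(f"i{k}", classes[k % 2]) for k in range(8)]
        truth = {f"i{k}": classes[k % 2] for k in range(8)}
        patch_preds = [onehot_pred(classes[k % 2], classes, f"i{k}")
                       for k in range(8)]
        report = pv.compute_report(preds, truth, patch_preds)
        assert report.image_level_accuracy == 1.0
        assert report.patch_level_accuracy == 1.0
        cm = report.confusion_matrix.values
        assert np.all(cm == np.diag(np.diag(cm)))
        assert all(report.auc(c) == 1.0 for c in classes)

    def test_confusion_matrix_consistency(self, rng):
        classes = ("A", "B", "C")
        preds, truth = [], {}
        for k in range(60):
            predicted = classes[rng.integers(0, 3)]
            preds.append(self._image_pred(f"i{k}", predicted, classes))
            truth[f"i{k}"] = classes[rng.integers(0, 3)]
        report = pv.compute_report(preds, truth)
        cm = report.confusion_matrix
        assert cm.values.sum() == 60
        trace = np.trace(cm.values)
        assert trace / 60 == pytest.approx(report.image_level_accuracy)
        for c in classes:
            assert cm.loc[c].sum() == sum(1 for v in truth.values() if v == c)

    def test_chance_level_patch_accuracy(self):
        gen = np.random.default_rng(314)
        classes = ("A", "B")
        patch_preds, truth = [], {}
        for k in range(10_000):
            image_id = f"i{k}"
            truth[image_id] = classes[k % 2]
            patch_preds.append(onehot_pred(classes[gen.integers(0, 2)],
                                           classes, image_id))
        image_preds = [pv.image_majority_vote([p]) for p in patch_preds[:50]]
        report = pv.compute_report(image_preds, truth, patch_preds)
        assert report.patch_level_accuracy == pytest.approx(0.5, abs=0.02)

    def test_auc_perfect_ranking_oracle(self):
        classes = ("pos", "neg")
        scores = {"a": (0.9, "pos"), "b": (0.8, "pos"),
                  "c": (0.7, "neg"), "d": (0.1, "neg")}
        preds, truth = [], {}
        for image_id, (s, label) in scores.items():
            preds.append(pv.image_majority_vote(
                [make_pred([s, 1 - s], classes, image_id)]))
            truth[image_id] = label
        report = pv.compute_report(preds, truth)
        assert report.auc("pos") == 1.0

    def test_auc_invariant_under_monotone_transform(self, rng):
        classes = ("A", "B")
        raw = rng.uniform(0.05, 0.95, 30)
        labels = rng.integers(0, 2, 30)

        def build(scores):
            preds, truth = [], {}
            for k, (s, lab) in enumerate(zip(scores, labels)):
                preds.append(pv.image_majority_vote(
                    [make_pred([s, 1 - s], classes, f"i{k}")]))
                truth[f"i{k}"] = classes[lab]
            return pv.compute_report(preds, truth)

        a = build(raw).auc("A")
        b = build(raw ** 3 / (raw ** 3 + (1 - raw) ** 3)).auc("A")
        assert a == pytest.approx(b, abs=1e-12)

    def test_voting_lifts_image_accuracy_above_patch_accuracy(self):
        """With per-patch accuracy p > 1/K and independent patch errors,
        majority voting over >= 9 patches is more accurate at image level."""
        gen = np.random.default_rng(2024)
        classes = ("A", "B", "C")
        deltas = []
        for _ in range(20):
            image_preds, patch_preds, truth = [], [], {}
            for k in range(40):
                image_id = f"i{k}"
                true = classes[k % 3]
                truth[image_id] = true
                preds = []
                for _ in range(9):
                    if gen.random() < 0.6:
                        lab = true
                    else:
                        lab = classes[gen.integers(0, 3)]
                    preds.append(onehot_pred(lab, classes, image_id))
                image_preds.append(pv.image_majority_vote(preds))
                patch_preds.extend(preds)
            report = pv.compute_report(image_preds, truth, patch_preds)
            deltas.append(report.image_level_accuracy
                          - report.patch_level_accuracy)
        assert np.mean(deltas) > 0
        assert sum(d >= 0 for d in deltas) >= 18

    def test_unknown_truth_label_rejected(self):
        pred = self._image_pred("i0", "A")
        with pytest.raises(pv.InvalidDataError):
            pv.compute_report([pred], {"i0": "Z"})

    def test_report_json_round_trip(self, tmp_path):
        preds = [self._image_pred("i0", "A"), self._image_pred("i1", "B")]
        report = pv.compute_report(preds, {"i0": "A", "i1": "B"})
        path = tmp_path / "report.json"
        report.to_json(path)
        import json
        doc = json.loads(path.read_text())
        assert doc["image_level_accuracy"] == 1.0
        assert doc["classes"] == ["A", "B"]
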