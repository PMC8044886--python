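"""Patch-to-image label aggregation and evaluation statistics.

An image's diagnosis is the majority vote over its patches' argmax labels;
a mast-cell-tumor grade is the majority vote over the pooled
(patch x model) ballots of a three-network ensemble (probability averaging
is available as an alternative ensemble mode).  Evaluation reports
patch-level and image-level accuracy, an image-level confusion matrix and
one-vs-rest ROC/AUC per class, scored by the image's mean patch
probability vector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve as _sk_roc

from .classify import PatchPrediction
from .exceptions import InvalidDataError, InvalidParameterError


@dataclass
class ImagePrediction:
    """Majority-voted image label with the vote tally behind it."""

    image_id: str
    label: str
    classes: tuple[str, ...]
    vote_counts: dict[str, int]
    mean_probabilities: np.ndarray
    n_patches: int

    def __post_init__(self):
        self.mean_probabilities = np.asarray(self.mean_probabilities, dtype=float)
        if sum(self.vote_counts.values()) != self.n_patches:
            raise InvalidDataError("vote counts must sum to n_patches")


def _majority(ballots: list[str], mean_proba: np.ndarray,
              classes: tuple[str, ...]) -> str:
    """Modal ballot; ties broken by mean probability, then class order."""
    counts = {c: 0 for c in classes}
    for b in ballots:
        counts[b] += 1
    top = max(counts.values())
    tied = [c for c in classes if counts[c] == top]
    if len(tied) == 1:
        return tied[0]
    probs = {c: mean_proba[classes.index(c)] for c in tied}
    best = max(probs.values())
    # classes tuple order is the final deterministic tie-break
    return next(c for c in classes if c in tied and probs[c] == best)


def _check_single_image(predictions: list[PatchPrediction]) -> tuple[str, tuple[str, ...]]:
    if not predictions:
        raise InvalidDataError("no patch predictions to aggregate")
    image_ids = {p.image_id for p in predictions}
    if len(image_ids) > 1:
        raise InvalidDataError(f"mixed image ids in one vote: {sorted(image_ids)}")
    class_lists = {p.classes for p in predictions}
    if len(class_lists) > 1:
        raise InvalidDataError("patch predictions use different class lists")
    return image_ids.pop(), predictions[0].classes


def image_majority_vote(patch_predictions: list[PatchPrediction]) -> ImagePrediction:
    """Majority vote over one image's patch argmax labels."""
    image_id, classes = _check_single_image(patch_predictions)
    mean_proba = np.mean([p.probabilities for p in patch_predictions], axis=0)
    ballots = [p.label for p in patch_predictions]
    label = _majority(ballots, mean_proba, classes)
    counts = {c: ballots.count(c) for c in classes}
    return ImagePrediction(image_id=image_id, label=label, classes=classes,
                           vote_counts=counts, mean_probabilities=mean_proba,
                           n_patches=len(ballots))


def ensemble_grade(per_model_patch_predictions: list[list[PatchPrediction]],
                   mode: str = "vote") -> ImagePrediction:
    """Combine several models' patch predictions into one image grade.

    ``mode="vote"`` pools every (patch x model) argmax ballot and takes the
    majority; ``mode="average"`` takes the argmax of the mean probability
    vector over all ballots.  Both use the mean-probability-then-class-order
    tie-break.
    """
    if mode not in ("vote", "average"):
        raise InvalidParameterError(f"unknown ensemble mode {mode!r}")
    lists = [list(preds) for preds in per_model_patch_predictions]
    if not lists or not lists[0]:
        raise InvalidDataError("no predictions to ensemble")
    n = len(lists[0])
    if any(len(preds) != n for preds in lists):
        raise InvalidDataError("models predicted different numbers of patches")
    pooled = [p for preds in lists for p in preds]
    image_id, classes = _check_single_image(pooled)
    mean_proba = np.mean([p.probabilities for p in pooled], axis=0)
    ballots = [p.label for p in pooled]
    if mode == "vote":
        label = _majority(ballots, mean_proba, classes)
    else:
        best = mean_proba.max()
        label = next(c for c, v in zip(classes, mean_proba) if v == best)
    counts = {c: ballots.count(c) for c in classes}
    return ImagePrediction(image_id=image_id, label=label, classes=classes,
                           vote_counts=counts, mean_probabilities=mean_proba,
                           n_patches=len(ballots))


@dataclass
class EvaluationReport:
    """Patch- and image-level accuracy, confusion matrix, per-class ROC/AUC."""

    classes: tuple[str, ...]
    image_level_accuracy: float
    confusion_matrix: pd.DataFrame  # rows = truth, columns = predicted
    roc: dict[str, dict]            # class -> {fpr, tpr, auc}
    patch_level_accuracy: float | None = None
    n_images: int = 0
    n_patches: int = 0

    def auc(self, label: str) -> float:
        return self.roc[label]["auc"]

    def to_json(self, path: str | Path) -> None:
        doc = {
            "classes": list(self.classes),
            "image_level_accuracy": self.image_level_accuracy,
            "patch_level_accuracy": self.patch_level_accuracy,
            "n_images": self.n_images,
            "n_patches": self.n_patches,
            "confusion_matrix": self.confusion_matrix.values.tolist(),
            "roc": {c: {"fpr": list(map(float, r["fpr"])),
                        "tpr": list(map(float, r["tpr"])),
                        "auc": None if np.isnan(r["auc"]) else float(r["auc"])}
                    for c, r in self.roc.items()},
        }
        Path(path).write_text(json.dumps(doc, indent=2))

    def summary(self) -> str:
        lines = [f"images: {self.n_images}  patches: {self.n_patches}",
                 f"image-level accuracy: {self.image_level_accuracy:.4f}"]
        if self.patch_level_accuracy is not None:
            lines.append(f"patch-level accuracy: {self.patch_level_accuracy:.4f}")
        for c in self.classes:
            a = self.roc[c]["auc"]
            lines.append(f"AUC[{c}]: {'n/a' if np.isnan(a) else f'{a:.4f}'}")
        lines.append("confusion matrix (rows = truth):")
        lines.append(self.confusion_matrix.to_string())
        return "\n".join(lines)


def compute_report(image_predictions: list[ImagePrediction],
                   truth_labels: dict[str, str],
                   patch_predictions: list[PatchPrediction] | None = None,
                   ) -> EvaluationReport:
    """Evaluate predictions against per-image truth labels.

    Patch-level accuracy (when patch predictions are given) scores each
    patch against its parent image's label.  One-vs-rest ROC curves use
    the image-level mean probability as the score; AUC is the trapezoidal
    area (NaN for classes absent from the truth or predicted everywhere).
    """
    if not image_predictions:
        raise InvalidDataError("no image predictions")
    classes = image_predictions[0].classes
    for pred in image_predictions:
        if pred.classes != classes:
            raise InvalidDataError("image predictions use different class lists")
        if pred.image_id not in truth_labels:
            raise InvalidDataError(f"no truth label for image {pred.image_id!r}")
    truths = [str(truth_labels[p.image_id]) for p in image_predictions]
    unknown = set(truths) - set(classes)
    if unknown:
        raise InvalidDataError(f"truth labels outside model classes: {sorted(unknown)}")

    predicted = [p.label for p in image_predictions]
    image_acc = float(np.mean([t == p for t, p in zip(truths, predicted)]))
    cm = _sk_confusion(truths, predicted, labels=list(classes))
    cm_frame = pd.DataFrame(cm, index=list(classes), columns=list(classes))

    scores = np.stack([p.mean_probabilities for p in image_predictions])
    roc: dict[str, dict] = {}
    truth_arr = np.asarray(truths)
    for k, c in enumerate(classes):
        binary = (truth_arr == c).astype(int)
        if binary.min() == binary.max():  # one-class: ROC undefined
            roc[c] = {"fpr": np.array([]), "tpr": np.array([]), "auc": np.nan}
            continue
        fpr, tpr, _ = _sk_roc(binary, scores[:, k])
        roc[c] = {"fpr": fpr, "tpr": tpr, "auc": float(_trapezoid_auc(fpr, tpr))}

    patch_acc = None
    n_patches = 0
    if patch_predictions is not None and len(patch_predictions) > 0:
        correct = []
        for p in patch_predictions:
            if p.image_id not in truth_labels:
                raise InvalidDataError(f"no truth label for image {p.image_id!r}")
            correct.append(p.label == str(truth_labels[p.image_id]))
        patch_acc = float(np.mean(correct))
        n_patches = len(correct)

    return EvaluationReport(classes=classes,
                            image_level_accuracy=image_acc,
                            confusion_matrix=cm_frame,
                            roc=roc,
                            patch_level_accuracy=patch_acc,
                            n_images=len(image_predictions),
                            n_patches=n_patches)
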