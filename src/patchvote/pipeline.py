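"""End-to-end pipelines: normalize -> segment -> tile -> classify -> vote.

``TumorClassificationPipeline`` trains a single patch classifier and
majority-votes patch labels into an image diagnosis (the five-class
round-cell-tumor task).  ``GradingEnsemble`` shares the same preprocessing
but trains three backbones and pools their patch ballots into one grading
vote.  The first training image (configurable) serves as the stain
reference; segmentation runs in the reference stain space using the
reference basis.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .aggregate import (EvaluationReport, ImagePrediction, compute_report,
                        ensemble_grade, image_majority_vote)
from .classify import PatchClassifier, PatchPrediction
from .exceptions import InvalidDataError
from .segment import NucleiSegmenter
from .stain import StainNormalizer
from .tiling import PatchBox, PatchExtractor, PatchSet, crop_patches

_VALIDATION_FRACTION = 0.1


def fallback_patch(mask: np.ndarray, patch_size: int) -> PatchBox:
    """Best coarse-grid window when no candidate meets the coverage bar.

    Every image must yield at least one patch at prediction time; the
    full-stride grid window with maximal nuclear coverage is a
    deterministic, sensible stand-in.
    """
    mask = np.asarray(mask) != 0
    h, w = mask.shape
    best, best_cov = PatchBox(0, 0, patch_size), -1.0
    for r in range(0, h - patch_size + 1, patch_size):
        for c in range(0, w - patch_size + 1, patch_size):
            cov = float(mask[r:r + patch_size, c:c + patch_size].mean())
            if cov > best_cov:
                best, best_cov = PatchBox(r, c, patch_size), cov
    return best


class _PreprocessingMixin:
    """Shared normalize/segment/tile machinery for the two pipelines."""

    def _build_components(self):
        self.normalizer_ = StainNormalizer(od_threshold=self.od_threshold)
        self.segmenter_ = NucleiSegmenter(min_area=self.min_area)
        self.extractor_ = PatchExtractor(
            patch_size=self.patch_size,
            coverage_threshold=self.coverage_threshold,
            fine_stride_fraction=self.fine_stride_fraction)

    def _prepare_image(self, image: np.ndarray, image_id: str,
                       allow_empty: bool) -> tuple[list[np.ndarray], PatchSet]:
        """Normalize, segment and tile one image; returns crops and boxes."""
        norm = self.normalizer_.transform(np.asarray(image))
        label_map = self.segmenter_.segment(
            norm, basis=self.normalizer_.reference_profile_.basis)
        patches = self.extractor_.extract(label_map.mask, image_id=image_id)
        if len(patches) == 0 and not allow_empty:
            box = fallback_patch(label_map.mask, self.patch_size)
            patches = PatchSet(boxes=[box],
                               coverages=[float(label_map.mask[
                                   box.row0:box.row0 + box.size,
                                   box.col0:box.col0 + box.size].mean())],
                               source_image_id=image_id)
        return crop_patches(norm, patches), patches

    def _fit_preprocessing(self, images) -> None:
        if len(images) == 0:
            raise InvalidDataError("no training images")
        self._build_components()
        self.normalizer_.fit(np.asarray(images[self.reference_index]))

    def _collect_training_patches(self, images, labels):
        # allow_empty=False: a low-coverage image contributes its densest
        # fallback window, so the appearance predicted from fallbacks at
        # test time is also represented in training.
        crops_all, labels_all, image_ids = [], [], []
        for i, (image, label) in enumerate(zip(images, labels)):
            image_id = f"train_{i:04d}"
            crops, _ = self._prepare_image(image, image_id, allow_empty=False)
            crops_all.extend(crops)
            labels_all.extend([str(label)] * len(crops))
            image_ids.extend([image_id] * len(crops))
        if not crops_all:
            raise InvalidDataError("no training image produced any patch")
        return crops_all, np.asarray(labels_all), np.asarray(image_ids)

    def _image_level_split(self, patch_labels, patch_image_ids, seed: int):
        """Hold out ~10% of training images (>= 1 per class), patch-wise.

        Splitting at the image level keeps all patches of an image on one
        side, avoiding patch leakage into the validation set.  Returns
        ``None`` when some class has a single image (the classifier then
        falls back to its internal stratified patch split).
        """
        rng = np.random.default_rng(seed)
        image_label = {}
        for img, lab in zip(patch_image_ids, patch_labels):
            image_label[img] = lab
        val_images: set = set()
        by_class: dict[str, list] = {}
        for img, lab in image_label.items():
            by_class.setdefault(lab, []).append(img)
        if any(len(imgs) < 2 for imgs in by_class.values()):
            return None
        for lab, imgs in sorted(by_class.items()):
            imgs = sorted(imgs)
            k = max(1, int(round(_VALIDATION_FRACTION * len(imgs))))
            k = min(k, len(imgs) - 1)
            val_images.update(rng.choice(imgs, size=k, replace=False))
        val_mask = np.isin(patch_image_ids, sorted(val_images))
        if val_mask.all() or not val_mask.any():
            return None
        return ~val_mask, val_mask


class TumorClassificationPipeline(_PreprocessingMixin, BaseEstimator):
    """Five-class histotype pipeline with majority-voted image labels.

    Parameters cover the scan geometry (480 px patches, 20% coverage, 10%
    fine stride), segmentation minimum area, the backbone and its training
    schedule, and the index of the training image used as the stain
    reference.

    Attributes (after ``fit``): ``normalizer_``, ``segmenter_``,
    ``extractor_``, ``classifier_``, ``classes_``.
    """

    def __init__(self, backbone: str = "tiny_test", patch_size: int = 480,
                 coverage_threshold: float = 0.20,
                 fine_stride_fraction: float = 0.10,
                 od_threshold: float = 0.15, min_area: int = 80,
                 batch_size: int = 32, learning_rate: float = 1e-3,
                 max_epochs: int = 30, patience: int = 10,
                 reference_index: int = 0, random_state: int = 0):
        self.backbone = backbone
        self.patch_size = patch_size
        self.coverage_threshold = coverage_threshold
        self.fine_stride_fraction = fine_stride_fraction
        self.od_threshold = od_threshold
        self.min_area = min_area
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.reference_index = reference_index
        self.random_state = random_state

    def fit(self, images, labels) -> "TumorClassificationPipeline":
        self._fit_preprocessing(images)
        crops, patch_labels, patch_image_ids = self._collect_training_patches(
            images, labels)
        split = self._image_level_split(patch_labels, patch_image_ids,
                                        self.random_state)
        self.classifier_ = PatchClassifier(
            backbone=self.backbone, batch_size=self.batch_size,
            learning_rate=self.learning_rate, max_epochs=self.max_epochs,
            patience=self.patience, random_state=self.random_state)
        if split is None:
            self.classifier_.fit(crops, patch_labels)
        else:
            train_mask, val_mask = split
            self.classifier_.fit(
                [c for c, m in zip(crops, train_mask) if m],
                patch_labels[train_mask],
                [c for c, m in zip(crops, val_mask) if m],
                patch_labels[val_mask])
        self.classes_ = self.classifier_.classes_
        return self

    def predict_image(self, image, image_id: str = "image"
                      ) -> tuple[ImagePrediction, list[PatchPrediction]]:
        """Diagnose one image; returns the vote and the patch predictions."""
        crops, patches = self._prepare_image(image, image_id, allow_empty=False)
        patch_preds = self.classifier_.predict_patches(
            crops, image_id=image_id, boxes=patches.boxes)
        return image_majority_vote(patch_preds), patch_preds

    def predict(self, images) -> list[str]:
        return [self.predict_image(img, f"image_{i:04d}")[0].label
                for i, img in enumerate(images)]

    def evaluate(self, images, labels) -> EvaluationReport:
        """Score the pipeline on labelled images (patch and image level)."""
        image_preds, patch_preds, truth = [], [], {}
        for i, (image, label) in enumerate(zip(images, labels)):
            image_id = f"eval_{i:04d}"
            vote, preds = self.predict_image(image, image_id)
            image_preds.append(vote)
            patch_preds.extend(preds)
            truth[image_id] = str(label)
        return compute_report(image_preds, truth, patch_preds)


class GradingEnsemble(_PreprocessingMixin, BaseEstimator):
    """Three-backbone ensemble for three-grade mast-cell-tumor grading.

    All members share one preprocessing pass (the patches are identical);
    each member trains from its own seed.  The image grade pools every
    (patch x model) ballot into one majority vote (``mode="vote"``) or
    averages all probability vectors (``mode="average"``).
    """

    def __init__(self, backbones=("alexnet_like", "inception_like", "resnet_like"),
                 mode: str = "vote", patch_size: int = 480,
                 coverage_threshold: float = 0.20,
                 fine_stride_fraction: float = 0.10,
                 od_threshold: float = 0.15, min_area: int = 80,
                 batch_size: int = 32, learning_rate: float = 1e-3,
                 max_epochs: int = 30, patience: int = 10,
                 reference_index: int = 0, random_state: int = 0):
        self.backbones = backbones
        self.mode = mode
        self.patch_size = patch_size
        self.coverage_threshold = coverage_threshold
        self.fine_stride_fraction = fine_stride_fraction
        self.od_threshold = od_threshold
        self.min_area = min_area
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.reference_index = reference_index
        self.random_state = random_state

    def fit(self, images, labels) -> "GradingEnsemble":
        self._fit_preprocessing(images)
        crops, patch_labels, patch_image_ids = self._collect_training_patches(
            images, labels)
        split = self._image_level_split(patch_labels, patch_image_ids,
                                        self.random_state)
        self.members_ = []
        for k, backbone in enumerate(self.backbones):
            clf = PatchClassifier(
                backbone=backbone, batch_size=self.batch_size,
                learning_rate=self.learning_rate, max_epochs=self.max_epochs,
                patience=self.patience, random_state=self.random_state + 1000 * (k + 1))
            if split is None:
                clf.fit(crops, patch_labels)
            else:
                train_mask, val_mask = split
                clf.fit([c for c, m in zip(crops, train_mask) if m],
                        patch_labels[train_mask],
                        [c for c, m in zip(crops, val_mask) if m],
                        patch_labels[val_mask])
            self.members_.append(clf)
        self.classes_ = self.members_[0].classes_
        return self

    def predict_image(self, image, image_id: str = "image"
                      ) -> tuple[ImagePrediction, list[list[PatchPrediction]]]:
        crops, patches = self._prepare_image(image, image_id, allow_empty=False)
        per_model = [clf.predict_patches(crops, image_id=image_id,
                                         boxes=patches.boxes)
                     for clf in self.members_]
        return ensemble_grade(per_model, mode=self.mode), per_model

    def predict(self, images) -> list[str]:
        return [self.predict_image(img, f"image_{i:04d}")[0].label
                for i, img in enumerate(images)]

    def evaluate(self, images, labels) -> EvaluationReport:
        image_preds, patch_preds, truth = [], [], {}
        for i, (image, label) in enumerate(zip(images, labels)):
            image_id = f"eval_{i:04d}"
            vote, per_model = self.predict_image(image, image_id)
            image_preds.append(vote)
            for preds in per_model:
                patch_preds.extend(preds)
            truth[image_id] = str(label)
        return compute_report(image_preds, truth, patch_preds)


def split_by_case(manifest, test_cases_per_class: int = 1, seed: int = 0):
    """Case-grouped train/test split of a dataset manifest.

    Returns boolean masks (train, test) over manifest rows; no case ever
    straddles the split.
    """
    rng = np.random.default_rng(seed)
    test_cases: set = set()
    for label, group in manifest.groupby("label"):
        cases = sorted(group["case_id"].unique())
        if len(cases) <= test_cases_per_class:
            raise InvalidDataError(
                f"class {label!r} has too few cases to split")
        test_cases.update(rng.choice(cases, size=test_cases_per_class,
                                     replace=False))
    test_mask = manifest["case_id"].isin(test_cases).to_numpy()
    return ~test_mask, test_mask
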