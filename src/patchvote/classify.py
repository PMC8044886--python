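"""Patch classification with compact CPU-trainable networks.

Each backbone couples a fixed convolutional-style front end with a
trainable softmax multilayer perceptron.  The front end computes, from the
patch pixels alone, the representations a histology CNN's early layers
would learn: a nuclear blob profile (multiscale adaptive thresholding of
the hematoxylin channel followed by connected-component size, shape,
texture and spatial-dispersion statistics), per-stain concentration
histograms, and a mean-pooled color layout pyramid.  The named variants
borrow the design motif of the architecture family they are named after
at a size that trains on one CPU core in minutes:

- ``tiny_test``       — blob profile + histograms only, one hidden layer;
                        intended for test suites.
- ``alexnet_like``    — adds a single-branch 4x4 layout, two hidden layers.
- ``inception_like``  — concatenated 2/4/8 multi-resolution layout branches.
- ``resnet_like``     — 4x4 layout concatenated with its high-pass residual
                        (identity minus blur), deeper head.

Training follows the transfer-learning-era recipe for small histology
datasets: mini-batches of 32, Adam at 1e-3, categorical cross-entropy, at
most 30 epochs with early stopping after 10 epochs without validation-loss
improvement, restoring the best-validation-epoch weights.  No pretrained
weights ship with the package, so the ``transfer_learning`` flag currently
selects seeded random initialization either way.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.measure import regionprops
from skimage.transform import resize as _sk_resize
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split

from ._mlp import SoftmaxMLP, cross_entropy
from .exceptions import InvalidDataError, InvalidParameterError
from .segment import multiscale_threshold_segment, postprocess_instances
from .stain import (CANONICAL_EOSIN, CANONICAL_HEMATOXYLIN, StainBasis,
                    compute_concentrations, rgb_to_optical_density)
from .tiling import PatchBox

# Front-end stain basis: the canonical H&E vectors.  Pipeline patches are
# stain-normalized before classification, so the canonical directions are
# a faithful stand-in for the per-image basis.
_FRONTEND_BASIS = StainBasis(CANONICAL_HEMATOXYLIN, CANONICAL_EOSIN)

# Blob-area histogram bin edges (px^2): min_area .. large aggregates.
_AREA_EDGES = np.concatenate([[80.0], 2.0 ** np.arange(8, 14)])
_N_BLOB_FEATURES = 11 + (len(_AREA_EDGES) - 1)
_N_HIST_FEATURES = 16 + 16

DEFAULT_BATCH_SIZE = 32
DEFAULT_LEARNING_RATE = 1e-3
DEFAULT_MAX_EPOCHS = 30
DEFAULT_PATIENCE = 10


@dataclass(frozen=True)
class BackboneSpec:
    name: str
    scales: tuple[int, ...]      # mean-pooled layout grid sizes
    hidden: tuple[int, ...]
    highpass_residual: bool = False

    @property
    def n_features(self) -> int:
        n = _N_BLOB_FEATURES + _N_HIST_FEATURES
        n += sum(3 * s * s for s in self.scales)
        if self.highpass_residual:
            n += 3 * self.scales[-1] ** 2
        return n


BACKBONES: dict[str, BackboneSpec] = {
    "tiny_test": BackboneSpec("tiny_test", scales=(), hidden=(32,)),
    "alexnet_like": BackboneSpec("alexnet_like", scales=(4,), hidden=(128, 64)),
    "inception_like": BackboneSpec("inception_like", scales=(2, 4, 8),
                                   hidden=(96, 48)),
    "resnet_like": BackboneSpec("resnet_like", scales=(4,), hidden=(128, 64),
                                highpass_residual=True),
}


@dataclass
class PatchPrediction:
    """Class-probability vector for one patch, with provenance."""

    probabilities: np.ndarray
    classes: tuple[str, ...]
    image_id: str = ""
    box: PatchBox | None = None

    def __post_init__(self):
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if len(self.probabilities) != len(self.classes):
            raise InvalidDataError("probability vector does not match class list")
        if abs(self.probabilities.sum() - 1.0) > 1e-6 or (self.probabilities < 0).any():
            raise InvalidDataError("probabilities must be a distribution")

    @property
    def label(self) -> str:
        return self.classes[int(np.argmax(self.probabilities))]


def _digest(row: np.ndarray) -> str:
    import hashlib

    return hashlib.md5(np.ascontiguousarray(row).tobytes()).hexdigest()


def _pool(img: np.ndarray, size: int) -> np.ndarray:
    """Mean-pool an HxWx3 float image to size x size x 3."""
    h, w = img.shape[:2]
    if h % size == 0 and w % size == 0:
        return img.reshape(size, h // size, size, w // size, 3).mean(axis=(1, 3))
    return _sk_resize(img, (size, size), anti_aliasing=True, preserve_range=True)


def _blob_profile(h_map: np.ndarray) -> np.ndarray:
    """Nuclear blob statistics from the patch's hematoxylin channel.

    Applies the same multiscale adaptive thresholding used for whole-image
    segmentation to the patch, then summarizes the components: count, area
    moments, covered fraction, eccentricity moments, within-blob intensity
    spread (chromatin texture) and quadrat dispersion (spatial clustering),
    plus a log-spaced blob-area histogram.
    """
    channel = np.clip(h_map / max(float(h_map.max()), 1.0), 0.0, 1.0)
    mask = multiscale_threshold_segment(channel)
    label_map = postprocess_instances(mask, min_area=80)
    areas = label_map.areas.astype(float)
    if label_map.n_nuclei == 0:
        scalars = np.zeros(11)
    else:
        props = regionprops(label_map.labels, intensity_image=h_map)
        ecc = np.array([p.eccentricity for p in props])
        solidity = np.array([p.solidity for p in props[:80]])
        texture = np.array([float(np.std(p.image_intensity[p.image]))
                            for p in props[:80]])
        centroids = np.array([p.centroid for p in props])
        side = label_map.labels.shape[0]
        quadrats, _, _ = np.histogram2d(centroids[:, 0], centroids[:, 1],
                                        bins=4, range=[[0, side], [0, side]])
        dispersion = float(quadrats.var() / max(quadrats.mean(), 1e-6))
        scalars = np.array([
            len(areas) / 50.0, np.log1p(areas.mean()), np.log1p(np.median(areas)),
            np.log1p(areas.std()), float(label_map.mask.mean()),
            float(ecc.mean()), float(ecc.std()), float(solidity.mean()),
            float(solidity.std()), float(texture.mean()),
            dispersion / 5.0,
        ])
    hist, _ = np.histogram(areas, bins=_AREA_EDGES)
    return np.concatenate([scalars, hist / max(len(areas), 1)])


def extract_features(patches, spec: BackboneSpec) -> np.ndarray:
    """Fixed front end: blob profile + stain histograms + pooled layout."""
    rows = []
    for patch in patches:
        patch = np.asarray(patch)
        if patch.ndim != 3 or patch.shape[2] != 3:
            raise InvalidParameterError("patches must be HxWx3 RGB arrays")
        od = rgb_to_optical_density(patch)
        h_map, e_map = compute_concentrations(od, _FRONTEND_BASIS)
        parts = [_blob_profile(h_map)]
        for conc, upper in ((h_map, 3.0), (e_map, 1.5)):
            hist, _ = np.histogram(conc, bins=16, range=(0.0, upper))
            parts.append(hist / conc.size)
        if spec.scales:
            img = patch.astype(float) / 255.0
            needed = set(spec.scales)
            if spec.highpass_residual:
                needed.add(spec.scales[-1] // 2)
            pools = {s: _pool(img, s) for s in needed}
            parts.extend(pools[s].ravel() for s in spec.scales)
            if spec.highpass_residual:
                s = spec.scales[-1]
                blur = np.repeat(np.repeat(pools[s // 2], 2, axis=0), 2, axis=1)
                parts.append((pools[s] - blur).ravel())
        rows.append(np.concatenate(parts))
    return np.asarray(rows) if rows else np.zeros((0, spec.n_features))


class PatchClassifier(ClassifierMixin, BaseEstimator):
    """Backbone + softmax head patch classifier (scikit-learn estimator).

    Parameters
    ----------
    backbone : str, default "tiny_test"
        One of :data:`BACKBONES`.
    batch_size, learning_rate, max_epochs, patience
        Mini-batch Adam training schedule with validation-loss early
        stopping (defaults 32 / 1e-3 / 30 / 10).
    validation_fraction : float, default 0.1
        Fraction held out (stratified) when no validation set is passed
        to :meth:`fit`.
    transfer_learning : bool, default True
        Accepted for interface compatibility; with no pretrained weights
        available the initialization is seeded-random in both settings.
    random_state : int, default 0
        Seeds initialization and batch shuffling.

    Attributes
    ----------
    classes_ : ndarray of str — fixed class order of the output vector.
    net_ : SoftmaxMLP — trained network.
    history_ : DataFrame — per-epoch train/validation loss and accuracy.
    best_epoch_, n_epochs_ : int
    """

    def __init__(self, backbone: str = "tiny_test",
                 batch_size: int = DEFAULT_BATCH_SIZE,
                 learning_rate: float = DEFAULT_LEARNING_RATE,
                 max_epochs: int = DEFAULT_MAX_EPOCHS,
                 patience: int = DEFAULT_PATIENCE,
                 validation_fraction: float = 0.1,
                 transfer_learning: bool = True,
                 random_state: int = 0):
        self.backbone = backbone
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.transfer_learning = transfer_learning
        self.random_state = random_state

    # -- construction -----------------------------------------------------
    def _spec(self) -> BackboneSpec:
        try:
            return BACKBONES[self.backbone]
        except KeyError:
            raise InvalidParameterError(
                f"unknown backbone {self.backbone!r}; "
                f"choose from {sorted(BACKBONES)}") from None

    def build(self, classes) -> "PatchClassifier":
        """Initialize the network for a fixed class list without training.

        Predictions are defined immediately after building and are
        deterministic in ``random_state``.
        """
        classes = [str(c) for c in classes]
        if len(classes) < 2:
            raise InvalidParameterError("need at least 2 classes")
        spec = self._spec()
        self.classes_ = np.asarray(classes)
        self.net_ = SoftmaxMLP([spec.n_features, *spec.hidden, len(classes)],
                               seed=self.random_state)
        self.feature_mean_ = np.zeros(spec.n_features)
        self.feature_scale_ = np.ones(spec.n_features)
        return self

    def _features(self, patches) -> np.ndarray:
        feats = extract_features(patches, self._spec())
        return (feats - self.feature_mean_) / self.feature_scale_

    # -- training ---------------------------------------------------------
    def _check_all_classes(self, y, where: str) -> None:
        missing = set(map(str, self.classes_)) - set(map(str, y))
        if missing:
            raise InvalidDataError(f"{where} set lacks class(es): {sorted(missing)}")

    def fit(self, X, y, X_val=None, y_val=None):
        """Train on patches ``X`` (sequence of HxWx3 arrays) and labels ``y``.

        When ``X_val`` is omitted, a stratified ``validation_fraction``
        split of the training patches is held out.
        """
        y = np.asarray([str(v) for v in y])
        if len(X) == 0 or len(y) != len(X):
            raise InvalidDataError("training set is empty or labels mismatch")
        if (X_val is None) != (y_val is None):
            raise InvalidDataError("pass both X_val and y_val or neither")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise InvalidDataError("need at least 2 classes in training data")
        spec = self._spec()
        raw = extract_features(X, spec)
        # Canonical sample order (content digest) makes training invariant
        # to the order in which patches were supplied.
        order = np.argsort([_digest(row) for row in raw], kind="stable")
        raw, y = raw[order], y[order]
        if X_val is None:
            n_val = max(len(self.classes_),
                        int(round(self.validation_fraction * len(raw))))
            try:
                idx_train, idx_val = train_test_split(
                    np.arange(len(raw)), test_size=n_val,
                    random_state=self.random_state, stratify=y)
                raw_val, y_val = raw[idx_val], y[idx_val]
                raw, y = raw[idx_train], y[idx_train]
            except ValueError:
                # degenerate: a class with a single patch cannot be
                # stratified; monitor the training set itself instead
                warnings.warn("too few patches for a held-out validation "
                              "split; validating on the training set",
                              stacklevel=2)
                raw_val, y_val = raw, y
        else:
            y_val = np.asarray([str(v) for v in y_val])
            if len(X_val) == 0 or len(y_val) != len(X_val):
                raise InvalidDataError("validation set is empty or labels mismatch")
            unknown = set(y_val) - set(map(str, self.classes_))
            if unknown:
                raise InvalidDataError(
                    f"validation labels outside training classes: {sorted(unknown)}")
            raw_val = extract_features(X_val, spec)
        self._check_all_classes(y, "training")
        self._check_all_classes(y_val, "validation")

        self.feature_mean_ = raw.mean(axis=0)
        self.feature_scale_ = np.maximum(raw.std(axis=0), 1e-6)
        Xf = (raw - self.feature_mean_) / self.feature_scale_
        Xv = (raw_val - self.feature_mean_) / self.feature_scale_

        class_index = {c: i for i, c in enumerate(self.classes_)}
        onehot = np.eye(len(self.classes_))[[class_index[c] for c in y]]
        onehot_val = np.eye(len(self.classes_))[[class_index[c] for c in y_val]]

        self.net_ = SoftmaxMLP([spec.n_features, *spec.hidden, len(self.classes_)],
                               seed=self.random_state)
        rng = np.random.default_rng(self.random_state + 1)
        history, best_loss, best_weights, best_epoch, wait = [], np.inf, None, 0, 0
        for epoch in range(1, self.max_epochs + 1):
            self.net_.train_epoch(Xf, onehot, self.learning_rate,
                                  self.batch_size, rng)
            train_loss = self.net_.loss(Xf, onehot)
            val_proba = self.net_.predict_proba(Xv)
            val_loss = cross_entropy(val_proba, onehot_val)
            val_acc = float((val_proba.argmax(axis=1)
                             == onehot_val.argmax(axis=1)).mean())
            history.append({"epoch": epoch, "train_loss": train_loss,
                            "val_loss": val_loss, "val_accuracy": val_acc})
            if val_loss < best_loss - 1e-12:
                best_loss, best_epoch, wait = val_loss, epoch, 0
                best_weights = self.net_.get_weights()
            else:
                wait += 1
                if wait >= self.patience:
                    break
        if best_weights is not None:
            self.net_.set_weights(best_weights)
        self.history_ = pd.DataFrame(history)
        self.best_epoch_ = best_epoch
        self.n_epochs_ = len(history)
        return self

    # -- inference --------------------------------------------------------
    def predict_proba(self, X) -> np.ndarray:
        if not hasattr(self, "net_"):
            raise InvalidParameterError("classifier is not fitted/built")
        if len(X) == 0:
            return np.zeros((0, len(self.classes_)))
        return self.net_.predict_proba(self._features(X))

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[proba.argmax(axis=1)] if len(proba) else np.array([])

    def predict_patches(self, patches, image_id: str = "",
                        boxes=None) -> list[PatchPrediction]:
        """Order-preserving per-patch predictions with provenance."""
        proba = self.predict_proba(patches)
        classes = tuple(str(c) for c in self.classes_)
        boxes = list(boxes) if boxes is not None else [None] * len(proba)
        return [PatchPrediction(probabilities=p, classes=classes,
                                image_id=image_id, box=b)
                for p, b in zip(proba, boxes)]

    # -- persistence -------------------------------------------------------
    def save(self, directory: str | Path) -> None:
        """Write weights (npz), sidecar JSON and training history (CSV)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        state = self.net_.state_dict()
        state["feature_mean"] = self.feature_mean_
        state["feature_scale"] = self.feature_scale_
        np.savez(directory / "weights.npz", **state)
        sidecar = {
            "classes": [str(c) for c in self.classes_],
            "backbone": self.backbone,
            "config": {k: v for k, v in self.get_params().items()},
            "best_epoch": getattr(self, "best_epoch_", None),
            "n_epochs": getattr(self, "n_epochs_", None),
        }
        (directory / "model.json").write_text(json.dumps(sidecar, indent=2))
        if hasattr(self, "history_"):
            self.history_.to_csv(directory / "history.csv", index=False)

    @classmethod
    def load(cls, directory: str | Path) -> "PatchClassifier":
        directory = Path(directory)
        sidecar = json.loads((directory / "model.json").read_text())
        model = cls(**sidecar["config"])
        with np.load(directory / "weights.npz") as state:
            model.net_ = SoftmaxMLP.from_state_dict(state)
            model.feature_mean_ = state["feature_mean"].copy()
            model.feature_scale_ = state["feature_scale"].copy()
        model.classes_ = np.asarray(sidecar["classes"])
        model.best_epoch_ = sidecar.get("best_epoch")
        model.n_epochs_ = sidecar.get("n_epochs")
        history = directory / "history.csv"
        if history.exists():
            model.history_ = pd.read_csv(history)
        return model


def build_backbone(name: str, n_classes: int, random_state: int = 0
                   ) -> PatchClassifier:
    """Construct an initialized, untrained classifier for ``n_classes``.

    Class labels default to ``class_0..class_{n-1}`` and are replaced when
    :meth:`PatchClassifier.fit` is called.
    """
    if n_classes < 2:
        raise InvalidParameterError("n_classes must be >= 2")
    clf = PatchClassifier(backbone=name, random_state=random_state)
    return clf.build([f"class_{i}" for i in range(n_classes)])


def train_classifier(train_patches, train_labels, val_patches, val_labels,
                     backbone: str = "tiny_test", **config) -> PatchClassifier:
    """Functional wrapper over :meth:`PatchClassifier.fit`."""
    clf = PatchClassifier(backbone=backbone, **config)
    return clf.fit(train_patches, train_labels, val_patches, val_labels)


def predict_patches(model: PatchClassifier, patches, image_id: str = "",
                    boxes=None) -> list[PatchPrediction]:
    return model.predict_patches(patches, image_id=image_id, boxes=boxes)
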