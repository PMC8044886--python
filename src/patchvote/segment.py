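"""Nuclei detection by multiscale adaptive thresholding of the hematoxylin channel.

Nuclei are hematoxylin-dense, so the hematoxylin concentration map acts as
a nuclear probability surface.  Segmentation sweeps a grid of thresholds
over that surface and, at each threshold, counts connected components
whose area falls inside a plausible nucleus-size band; the threshold that
maximizes this count is selected (adaptive scale selection).  Instance
post-processing fills holes, drops sub-minimum components and can split
touching nuclei with a distance-transform watershed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.measure import label as cc_label
from skimage.segmentation import watershed
from sklearn.base import BaseEstimator

from .exceptions import DegenerateInputError, InvalidParameterError
from .stain import (DEFAULT_BACKGROUND_INTENSITY, StainBasis,
                    compute_concentrations, estimate_stain_basis,
                    rgb_to_optical_density)

# Plausible nucleus area band in px^2 at 0.233 um/px (x400): roughly
# 2-9 um equivalent radius.
DEFAULT_AREA_BAND = (80.0, 5000.0)
DEFAULT_MIN_AREA = 80
DEFAULT_THRESHOLDS = tuple(np.linspace(0.05, 0.95, 20))

# 4-connectivity throughout, for reproducible component counts.
_CONNECTIVITY = 1
_STRUCT4 = ndimage.generate_binary_structure(2, 1)


@dataclass
class NucleiLabelMap:
    """Instance segmentation: 0 = background, labels 1..n_nuclei."""

    labels: np.ndarray

    @property
    def n_nuclei(self) -> int:
        return int(self.labels.max())

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def areas(self) -> np.ndarray:
        """Per-nucleus pixel areas, indexed by label-1."""
        if self.n_nuclei == 0:
            return np.zeros(0, dtype=int)
        return np.bincount(self.labels.ravel())[1:]

    def centroids(self) -> np.ndarray:
        """(n_nuclei, 2) array of (row, col) centroids."""
        if self.n_nuclei == 0:
            return np.zeros((0, 2))
        return np.array(ndimage.center_of_mass(self.mask, self.labels,
                                               np.arange(1, self.n_nuclei + 1)))

    def to_table(self) -> pd.DataFrame:
        """Per-nucleus table with 0-based pixel coordinates (x = column)."""
        cents = self.centroids()
        return pd.DataFrame({
            "id": np.arange(1, self.n_nuclei + 1),
            "centroid_x": cents[:, 1] if len(cents) else [],
            "centroid_y": cents[:, 0] if len(cents) else [],
            "area": self.areas,
        })

    def save(self, tiff_path: str | Path, csv_path: str | Path | None = None) -> None:
        tifffile.imwrite(str(tiff_path), self.labels.astype(np.uint16))
        if csv_path is not None:
            self.to_table().to_csv(csv_path, index=False)

    @classmethod
    def load(cls, tiff_path: str | Path) -> "NucleiLabelMap":
        return cls(labels=tifffile.imread(str(tiff_path)).astype(np.int32))


def nuclear_channel(image: np.ndarray, basis: StainBasis,
                    background_intensity: float = DEFAULT_BACKGROUND_INTENSITY
                    ) -> np.ndarray:
    """Hematoxylin concentration map rescaled to [0, 1].

    The map is divided by max(peak concentration, 1.0); the floor keeps
    near-hematoxylin-free images (e.g. pure eosin) near zero instead of
    amplifying noise.
    """
    od = rgb_to_optical_density(image, background_intensity)
    h_map, _ = compute_concentrations(od, basis)
    scale = max(float(h_map.max()), 1.0)
    return np.clip(h_map / scale, 0.0, 1.0)


def multiscale_threshold_segment(channel: np.ndarray,
                                 thresholds=DEFAULT_THRESHOLDS,
                                 area_band: tuple[float, float] = DEFAULT_AREA_BAND,
                                 ) -> np.ndarray:
    """Binary nuclei mask at the component-count-maximizing threshold.

    For each threshold the channel is binarized and 4-connected components
    with area inside ``area_band`` are counted; the binarization at the
    count-maximizing threshold is returned (lowest threshold wins ties).
    A channel yielding no in-band component at any threshold produces an
    empty mask.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise InvalidParameterError("threshold grid is empty")
    if thresholds.size < 5:
        raise InvalidParameterError("threshold grid needs at least 5 values")
    if np.any(np.diff(thresholds) <= 0) or thresholds[0] <= 0 or thresholds[-1] >= 1:
        raise InvalidParameterError("thresholds must be strictly increasing within (0, 1)")
    channel = np.asarray(channel, dtype=float)
    lo, hi = area_band
    best_count, best_mask = 0, np.zeros(channel.shape, dtype=bool)
    for t in thresholds:
        bw = channel > t
        labels, n = cc_label(bw, connectivity=_CONNECTIVITY, return_num=True)
        if n == 0:
            continue
        areas = np.bincount(labels.ravel())[1:]
        count = int(np.count_nonzero((areas >= lo) & (areas <= hi)))
        if count > best_count:
            best_count, best_mask = count, bw
    return best_mask


def postprocess_instances(mask: np.ndarray,
                          min_area: int = DEFAULT_MIN_AREA,
                          fill_holes: bool = True,
                          split_touching: bool = False,
                          ) -> NucleiLabelMap:
    """Clean a binary mask into labelled nucleus instances.

    Fills holes, optionally splits touching nuclei by distance-transform
    watershed, removes components below ``min_area`` and renumbers labels
    consecutively from 1.
    """
    mask = np.asarray(mask, dtype=bool)
    if fill_holes:
        mask = ndimage.binary_fill_holes(mask, structure=_STRUCT4)
    if split_touching and mask.any():
        distance = ndimage.distance_transform_edt(mask)
        peaks = peak_local_max(distance, min_distance=7, labels=mask,
                               exclude_border=False)
        markers = np.zeros(mask.shape, dtype=np.int32)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        markers, _ = ndimage.label(markers > 0, structure=_STRUCT4)
        labels = watershed(-distance, markers, mask=mask, connectivity=_CONNECTIVITY)
    else:
        labels = cc_label(mask, connectivity=_CONNECTIVITY)
    areas = np.bincount(labels.ravel())
    keep = np.flatnonzero(areas >= min_area)
    keep = keep[keep > 0]
    remap = np.zeros(areas.size, dtype=np.int32)
    remap[keep] = np.arange(1, keep.size + 1)
    return NucleiLabelMap(labels=remap[labels])


def segment_nuclei(image: np.ndarray,
                   basis: StainBasis | None = None,
                   thresholds=DEFAULT_THRESHOLDS,
                   area_band: tuple[float, float] = DEFAULT_AREA_BAND,
                   min_area: int = DEFAULT_MIN_AREA,
                   fill_holes: bool = True,
                   split_touching: bool = False,
                   background_intensity: float = DEFAULT_BACKGROUND_INTENSITY,
                   ) -> NucleiLabelMap:
    """Full segmentation: hematoxylin channel -> multiscale threshold -> cleanup.

    When no stain basis is given, one is estimated from the image itself;
    images too faint for basis estimation (blank glass) yield an empty map.
    """
    image = np.asarray(image)
    if basis is None:
        od = rgb_to_optical_density(image, background_intensity)
        try:
            basis = estimate_stain_basis(od)
        except DegenerateInputError:
            return NucleiLabelMap(labels=np.zeros(image.shape[:2], dtype=np.int32))
    channel = nuclear_channel(image, basis, background_intensity)
    mask = multiscale_threshold_segment(channel, thresholds, area_band)
    return postprocess_instances(mask, min_area, fill_holes, split_touching)


class NucleiSegmenter(BaseEstimator):
    """Multiscale adaptive-threshold nuclei segmenter (stateless estimator).

    ``fit`` is a no-op kept for pipeline compatibility; :meth:`segment`
    returns a :class:`NucleiLabelMap` for one image and :meth:`transform`
    maps over a list of images.
    """

    def __init__(self, thresholds=DEFAULT_THRESHOLDS,
                 area_band: tuple[float, float] = DEFAULT_AREA_BAND,
                 min_area: int = DEFAULT_MIN_AREA,
                 fill_holes: bool = True,
                 split_touching: bool = False,
                 background_intensity: float = DEFAULT_BACKGROUND_INTENSITY):
        self.thresholds = thresholds
        self.area_band = area_band
        self.min_area = min_area
        self.fill_holes = fill_holes
        self.split_touching = split_touching
        self.background_intensity = background_intensity

    def fit(self, X=None, y=None) -> "NucleiSegmenter":
        return self

    def segment(self, image: np.ndarray, basis: StainBasis | None = None
                ) -> NucleiLabelMap:
        return segment_nuclei(
            image, basis=basis, thresholds=self.thresholds,
            area_band=self.area_band, min_area=self.min_area,
            fill_holes=self.fill_holes, split_touching=self.split_touching,
            background_intensity=self.background_intensity)

    def transform(self, X, basis: StainBasis | None = None) -> list[NucleiLabelMap]:
        return [self.segment(img, basis) for img in X]
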