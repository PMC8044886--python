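"""Hematoxylin/eosin stain separation and reference-based color normalization.

H&E images are modelled with the Beer-Lambert law: transmitted intensity
``I = I0 * 10**(-OD)`` where the optical density ``OD`` at each pixel is an
approximately additive mix of per-dye contributions,

    OD(pixel) = c_H * v_H + c_E * v_E + residual,

with ``v_H``, ``v_E`` unit 3-vectors (the stain basis) and ``c_H``, ``c_E``
non-negative concentrations.  Normalization estimates the basis of each
image from the principal plane of its OD cloud (with percentile-angle
robustification), projects pixels onto it, and monotonically remaps each
stain's concentration distribution over tissue pixels onto the distribution
of a user-chosen reference image.  Pixels whose OD magnitude is below the
tissue threshold (glass/background) are left untouched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import DegenerateInputError, InvalidParameterError

# Canonical H&E optical-density vectors (Ruifrok-style convention).
# Shared with the synthetic renderer so generated images and the
# estimator tests agree on ground truth.
CANONICAL_HEMATOXYLIN = np.array([0.650, 0.704, 0.286])
CANONICAL_EOSIN = np.array([0.072, 0.990, 0.105])
CANONICAL_HEMATOXYLIN = CANONICAL_HEMATOXYLIN / np.linalg.norm(CANONICAL_HEMATOXYLIN)
CANONICAL_EOSIN = CANONICAL_EOSIN / np.linalg.norm(CANONICAL_EOSIN)

DEFAULT_BACKGROUND_INTENSITY = 256.0
DEFAULT_OD_THRESHOLD = 0.15
# 0 and 100 are included so the piecewise-linear map spans the full
# concentration range (identity mapping is then exact, with no tail clamp).
DEFAULT_PERCENTILE_GRID = tuple(range(0, 101))

_MIN_TISSUE_PIXELS = 100


@dataclass(frozen=True)
class StainBasis:
    """Unit-norm hematoxylin and eosin direction vectors in OD space."""

    h_vector: np.ndarray
    e_vector: np.ndarray

    def __post_init__(self):
        for name, v in (("h_vector", self.h_vector), ("e_vector", self.e_vector)):
            v = np.asarray(v, dtype=float)
            if v.shape != (3,):
                raise InvalidParameterError(f"{name} must be a 3-vector")
            if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                raise InvalidParameterError(f"{name} must have unit norm")
            object.__setattr__(self, name, v)
        cosang = float(np.clip(np.dot(self.h_vector, self.e_vector), -1.0, 1.0))
        if np.degrees(np.arccos(cosang)) <= 1.0:
            raise DegenerateInputError("stain vectors are nearly collinear")

    @property
    def matrix(self) -> np.ndarray:
        """3x2 mixing matrix with columns (v_H, v_E)."""
        return np.stack([self.h_vector, self.e_vector], axis=1)


@dataclass
class ReferenceProfile:
    """Stain basis plus per-stain concentration percentiles of a reference image.

    Percentiles are computed over tissue pixels (OD norm above
    ``od_threshold``) at the points of ``percentile_grid``.
    """

    basis: StainBasis
    percentile_grid: np.ndarray
    h_percentiles: np.ndarray
    e_percentiles: np.ndarray
    od_threshold: float = DEFAULT_OD_THRESHOLD
    background_intensity: float = DEFAULT_BACKGROUND_INTENSITY

    def __post_init__(self):
        self.percentile_grid = np.asarray(self.percentile_grid, dtype=float)
        self.h_percentiles = np.asarray(self.h_percentiles, dtype=float)
        self.e_percentiles = np.asarray(self.e_percentiles, dtype=float)
        for name, p in (("h_percentiles", self.h_percentiles),
                        ("e_percentiles", self.e_percentiles)):
            if p.shape != self.percentile_grid.shape:
                raise InvalidParameterError(f"{name} does not match the percentile grid")
            if np.any(np.diff(p) < -1e-12):
                raise InvalidParameterError(f"{name} must be non-decreasing")

    def to_json(self, path: str | Path) -> None:
        doc = {
            "h_vector": self.basis.h_vector.tolist(),
            "e_vector": self.basis.e_vector.tolist(),
            "percentile_grid": self.percentile_grid.tolist(),
            "h_percentiles": self.h_percentiles.tolist(),
            "e_percentiles": self.e_percentiles.tolist(),
            "od_threshold": self.od_threshold,
            "background_intensity": self.background_intensity,
        }
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ReferenceProfile":
        doc = json.loads(Path(path).read_text())
        basis = StainBasis(np.array(doc["h_vector"]), np.array(doc["e_vector"]))
        return cls(
            basis=basis,
            percentile_grid=np.array(doc["percentile_grid"]),
            h_percentiles=np.array(doc["h_percentiles"]),
            e_percentiles=np.array(doc["e_percentiles"]),
            od_threshold=doc["od_threshold"],
            background_intensity=doc["background_intensity"],
        )


def rgb_to_optical_density(image: np.ndarray,
                           background_intensity: float = DEFAULT_BACKGROUND_INTENSITY
                           ) -> np.ndarray:
    """Convert an RGB image to optical densities.

    ``od = -log10((I + 1) / I0)`` clamped below at 0.  The +1 offset keeps
    pure black pixels finite; a pixel at ``I0 - 1`` maps to exactly zero
    density (clean background).
    """
    if background_intensity <= 0:
        raise InvalidParameterError("background_intensity must be positive")
    intensities = np.asarray(image, dtype=float)
    od = -np.log10((intensities + 1.0) / background_intensity)
    return np.clip(od, 0.0, None)


def optical_density_to_rgb(od: np.ndarray,
                           background_intensity: float = DEFAULT_BACKGROUND_INTENSITY
                           ) -> np.ndarray:
    """Invert :func:`rgb_to_optical_density` (rounds to uint8)."""
    if background_intensity <= 0:
        raise InvalidParameterError("background_intensity must be positive")
    intensities = background_intensity * np.power(10.0, -np.asarray(od, dtype=float)) - 1.0
    return np.clip(np.rint(intensities), 0, 255).astype(np.uint8)


def tissue_mask_from_od(od: np.ndarray, od_threshold: float = DEFAULT_OD_THRESHOLD
                        ) -> np.ndarray:
    """Boolean mask of pixels whose OD Euclidean norm exceeds the threshold."""
    return np.linalg.norm(od, axis=-1) > od_threshold


def estimate_stain_basis(od: np.ndarray,
                         tissue_mask: np.ndarray | None = None,
                         od_threshold: float = DEFAULT_OD_THRESHOLD,
                         angular_percentiles: tuple[float, float] = (1.0, 99.0),
                         ) -> StainBasis:
    """Estimate the H and E direction vectors from an image's OD cloud.

    The two principal directions of the (uncentered) tissue OD cloud span
    the stain plane; within that plane the 1st/99th-percentile pixel
    angles, linearly extrapolated to the edge of the angular distribution
    (``2*theta_p - theta_3p``, which removes the inward bias of a plain
    percentile cut while staying robust to sub-percent outliers), give the
    stain directions.  The vector with the larger blue-channel OD
    component is assigned to hematoxylin.

    Raises :class:`DegenerateInputError` when fewer than 100 tissue pixels
    are available or the cloud is essentially one-dimensional (single pure
    stain).
    """
    od = np.asarray(od, dtype=float).reshape(-1, 3)
    if tissue_mask is not None:
        od = od[np.asarray(tissue_mask, dtype=bool).reshape(-1)]
    keep = np.linalg.norm(od, axis=1) > od_threshold
    pixels = od[keep]
    if pixels.shape[0] < _MIN_TISSUE_PIXELS:
        raise DegenerateInputError(
            f"only {pixels.shape[0]} tissue pixels above OD {od_threshold}; "
            f"need at least {_MIN_TISSUE_PIXELS}")

    # Principal plane of the uncentered cloud (stains are non-negative mixes).
    _, svals, vt = np.linalg.svd(pixels, full_matrices=False)
    if svals[1] < 0.02 * svals[0]:
        raise DegenerateInputError("OD cloud is rank deficient (single stain?)")
    plane = vt[:2]
    # Orient plane axes so projections are mostly positive (deterministic sign).
    proj = pixels @ plane.T
    for k in range(2):
        if proj[:, k].sum() < 0:
            plane[k] = -plane[k]
            proj[:, k] = -proj[:, k]
    angles = np.arctan2(proj[:, 1], proj[:, 0])
    p_lo, p_hi = angular_percentiles
    a1, a3 = np.percentile(angles, [p_lo, 3.0 * p_lo])
    lo = 2.0 * a1 - a3
    b1, b3 = np.percentile(angles, [p_hi, 100.0 - 3.0 * (100.0 - p_hi)])
    hi = 2.0 * b1 - b3
    v1 = plane[0] * np.cos(lo) + plane[1] * np.sin(lo)
    v2 = plane[0] * np.cos(hi) + plane[1] * np.sin(hi)
    vectors = []
    for v in (v1, v2):
        # Stain vectors are attenuations: flip into the non-negative orthant.
        if v.sum() < 0:
            v = -v
        vectors.append(v / np.linalg.norm(v))
    v1, v2 = vectors
    # Hematoxylin is blue-violet: larger blue-channel OD component.
    if v1[2] >= v2[2]:
        return StainBasis(h_vector=v1, e_vector=v2)
    return StainBasis(h_vector=v2, e_vector=v1)


def compute_concentrations(od: np.ndarray, basis: StainBasis
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel least-squares stain concentrations (negatives clipped to 0).

    Returns ``(h_map, e_map)`` with the same spatial shape as ``od``; the
    component of OD orthogonal to the stain plane is discarded.
    """
    od = np.asarray(od, dtype=float)
    spatial = od.shape[:-1]
    coeffs = od.reshape(-1, 3) @ np.linalg.pinv(basis.matrix).T
    coeffs = np.clip(coeffs, 0.0, None)
    return coeffs[:, 0].reshape(spatial), coeffs[:, 1].reshape(spatial)


def concentration_percentiles(conc: np.ndarray, tissue: np.ndarray,
                              grid: np.ndarray) -> np.ndarray:
    values = np.asarray(conc)[np.asarray(tissue, dtype=bool)]
    if values.size == 0:
        raise DegenerateInputError("empty tissue mask")
    return np.percentile(values, grid)


def compute_reference_profile(image: np.ndarray,
                              od_threshold: float = DEFAULT_OD_THRESHOLD,
                              percentile_grid=DEFAULT_PERCENTILE_GRID,
                              background_intensity: float = DEFAULT_BACKGROUND_INTENSITY,
                              ) -> ReferenceProfile:
    """Estimate basis and per-stain concentration percentiles of a reference image."""
    grid = np.asarray(percentile_grid, dtype=float)
    od = rgb_to_optical_density(image, background_intensity)
    basis = estimate_stain_basis(od, od_threshold=od_threshold)
    h_map, e_map = compute_concentrations(od, basis)
    tissue = tissue_mask_from_od(od, od_threshold)
    return ReferenceProfile(
        basis=basis,
        percentile_grid=grid,
        h_percentiles=concentration_percentiles(h_map, tissue, grid),
        e_percentiles=concentration_percentiles(e_map, tissue, grid),
        od_threshold=od_threshold,
        background_intensity=background_intensity,
    )


def map_to_reference(h_map: np.ndarray, e_map: np.ndarray,
                     source_profile: ReferenceProfile,
                     target_profile: ReferenceProfile,
                     tissue_mask: np.ndarray,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Percentile-match concentration maps onto a target distribution.

    A monotone piecewise-linear map sends the source profile's percentile
    values onto the target's, applied independently per stain over tissue
    pixels; non-tissue pixels pass through unchanged.
    """
    if not np.array_equal(source_profile.percentile_grid, target_profile.percentile_grid):
        raise InvalidParameterError("profiles use different percentile grids")
    tissue = np.asarray(tissue_mask, dtype=bool)
    if not tissue.any():
        raise DegenerateInputError("empty tissue mask")
    out = []
    for conc, src, tgt in (
        (h_map, source_profile.h_percentiles, target_profile.h_percentiles),
        (e_map, source_profile.e_percentiles, target_profile.e_percentiles),
    ):
        conc = np.asarray(conc, dtype=float)
        mapped = conc.copy()
        mapped[tissue] = np.interp(conc[tissue], src, tgt)
        out.append(mapped)
    return out[0], out[1]


def normalize_image(image: np.ndarray, reference: ReferenceProfile) -> np.ndarray:
    """Standardize an image's staining against a reference profile.

    rgb -> OD -> estimate source basis -> concentrations -> percentile
    matching -> reconstruct with the reference basis.  Images without
    tissue (e.g. blank glass) are returned unchanged.
    """
    image = np.asarray(image)
    od = rgb_to_optical_density(image, reference.background_intensity)
    tissue = tissue_mask_from_od(od, reference.od_threshold)
    if tissue.sum() < _MIN_TISSUE_PIXELS:
        return image.astype(np.uint8, copy=True)
    basis = estimate_stain_basis(od, od_threshold=reference.od_threshold)
    h_map, e_map = compute_concentrations(od, basis)
    grid = reference.percentile_grid
    source_profile = ReferenceProfile(
        basis=basis,
        percentile_grid=grid,
        h_percentiles=concentration_percentiles(h_map, tissue, grid),
        e_percentiles=concentration_percentiles(e_map, tissue, grid),
        od_threshold=reference.od_threshold,
        background_intensity=reference.background_intensity,
    )
    h_mapped, e_mapped = map_to_reference(h_map, e_map, source_profile,
                                          reference, tissue)
    od_out = (h_mapped[..., None] * reference.basis.h_vector
              + e_mapped[..., None] * reference.basis.e_vector)
    rgb_out = optical_density_to_rgb(od_out, reference.background_intensity)
    result = image.astype(np.uint8, copy=True)
    result[tissue] = rgb_out[tissue]
    return result


class StainNormalizer(TransformerMixin, BaseEstimator):
    """Reference-based H&E stain normalizer (scikit-learn transformer).

    Parameters
    ----------
    od_threshold : float, default 0.15
        OD-norm threshold separating tissue from background/glass.
    percentile_grid : sequence of float, default 1..99
        Percentile points at which the concentration distributions are
        matched.
    background_intensity : float, default 256
        Incident-light intensity I0 of the Beer-Lambert model.

    Attributes
    ----------
    reference_profile_ : ReferenceProfile
        Basis and percentile targets estimated from the reference image
        passed to :meth:`fit`.
    """

    def __init__(self, od_threshold: float = DEFAULT_OD_THRESHOLD,
                 percentile_grid=DEFAULT_PERCENTILE_GRID,
                 background_intensity: float = DEFAULT_BACKGROUND_INTENSITY):
        self.od_threshold = od_threshold
        self.percentile_grid = percentile_grid
        self.background_intensity = background_intensity

    def fit(self, reference_image: np.ndarray, y=None) -> "StainNormalizer":
        """Estimate the reference profile from a single reference image."""
        self.reference_profile_ = compute_reference_profile(
            reference_image,
            od_threshold=self.od_threshold,
            percentile_grid=self.percentile_grid,
            background_intensity=self.background_intensity,
        )
        return self

    def transform(self, X):
        """Normalize one image (H x W x 3 array) or a list of images."""
        if not hasattr(self, "reference_profile_"):
            raise InvalidParameterError("StainNormalizer is not fitted")
        if isinstance(X, np.ndarray) and X.ndim == 3:
            return normalize_image(X, self.reference_profile_)
        return [normalize_image(img, self.reference_profile_) for img in X]
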