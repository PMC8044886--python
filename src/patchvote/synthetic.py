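"""Seeded H&E-like image generator with ground-truth nuclei and labels.

Images emulate densely cellular round-cell-tumor fields: an eosin-toned
tissue background with hematoxylin-dense elliptical nuclei whose density,
size distribution, stain strength and spatial clustering are controlled
per class.  RGB values come from the Beer-Lambert model using the same
canonical stain vectors as the normalization module, plus a per-image
global stain-strength jitter (the variability stain normalization is
meant to remove) and Gaussian texture noise.  Nuclei are plain ellipses —
enough to exercise every pipeline contract, with no claim to histological
realism.

Default geometry: 1280x960 px at the nominal 0.233 um/px, a quarter of
the 2560x1920 acquisition format, keeping CPU runtimes in minutes;
full-size rendering is a parameter away.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.draw import ellipse as _draw_ellipse

from .exceptions import InvalidParameterError
from .segment import NucleiLabelMap
from .stain import CANONICAL_EOSIN, CANONICAL_HEMATOXYLIN, optical_density_to_rgb

PIXEL_SIZE_UM = 0.233
MM2_PER_PIXEL = (PIXEL_SIZE_UM * 1e-3) ** 2

DEFAULT_DIMS = (960, 1280)  # rows, cols
FULL_DIMS = (1920, 2560)

RCT_CLASSES = ("HIS", "LYM", "MCT", "MEL", "PLA")
GRADE_CLASSES = ("MCT1", "MCT2", "MCT3")


@dataclass(frozen=True)
class SyntheticClassSpec:
    """Appearance parameters of one synthetic tumor class.

    density is in nuclei per mm²; radii and separations in pixels; stain
    strengths are dimensionless Beer-Lambert concentrations.
    """

    label: str
    density_per_mm2: float
    radius_mean_px: float
    radius_sd_px: float
    hematoxylin_mean: float
    hematoxylin_sd: float
    eosin_background: float
    texture_noise_sd: float = 3.0
    clustering: float = 0.0
    aspect_mean: float = 0.85    # minor/major axis ratio (1 = circular)
    aspect_sd: float = 0.05
    chromatin_texture: float = 0.0  # lognormal speckle sd inside nuclei
    min_separation_px: float = 0.0

    def __post_init__(self):
        if self.density_per_mm2 <= 0:
            raise InvalidParameterError("density must be positive")
        if self.radius_mean_px <= 2:
            raise InvalidParameterError("radius mean must exceed 2 px")
        if min(self.hematoxylin_mean, self.eosin_background) < 0:
            raise InvalidParameterError("stain strengths must be >= 0")
        if not 0.0 <= self.clustering <= 1.0:
            raise InvalidParameterError("clustering must lie in [0, 1]")
        if not 0.0 < self.aspect_mean <= 1.0:
            raise InvalidParameterError("aspect_mean must lie in (0, 1]")


@dataclass
class SyntheticImage:
    """Rendered image, its ground-truth instance mask and provenance."""

    image: np.ndarray
    truth: NucleiLabelMap
    label: str
    seed: int
    image_id: str = ""
    case_id: str = ""


# Fields with reduced eosin inside nuclei and a small hematoxylin floor in
# the cytoplasmic background.
_NUCLEAR_EOSIN_FACTOR = 0.7
_BACKGROUND_HEMATOXYLIN = 0.04
_STAIN_JITTER_SD = 0.06


def segmentation_test_spec() -> SyntheticClassSpec:
    """Moderate-density field of well-separated nuclei.

    ~150 nuclei on the default 1280x960 frame with enforced spacing, used
    to measure detection performance against an unambiguous ground truth.
    """
    return SyntheticClassSpec(
        label="SEG", density_per_mm2=2250.0, radius_mean_px=16.0,
        radius_sd_px=2.0, hematoxylin_mean=1.0, hematoxylin_sd=0.10,
        eosin_background=0.35, texture_noise_sd=3.0, clustering=0.0,
        aspect_mean=0.90, aspect_sd=0.05, chromatin_texture=0.05,
        min_separation_px=44.0)


def _shrink_towards(value: float, center: float, hard: bool) -> float:
    return center + 0.5 * (value - center) if hard else value


def rct_class_specs(hard_mode: bool = False) -> dict[str, SyntheticClassSpec]:
    """Built-in five-class specs (distinct density x radius x chroma tuples).

    ``hard_mode`` halves every inter-class parameter gap for robustness
    testing.
    """
    base = {
        # Histiocytoma: medium round nuclei, even spread, bland chromatin.
        "HIS": SyntheticClassSpec("HIS", 5170.0, 20.0, 2.5, 0.85, 0.08, 0.38,
                                  clustering=0.0, aspect_mean=0.85,
                                  aspect_sd=0.05, chromatin_texture=0.05),
        # Lymphoma: small, round, tightly packed, hyperchromatic.
        "LYM": SyntheticClassSpec("LYM", 11470.0, 13.0, 1.5, 1.15, 0.08, 0.30,
                                  clustering=0.0, aspect_mean=0.95,
                                  aspect_sd=0.03, chromatin_texture=0.05),
        # Mast cell tumor: large round nuclei, coarse granular texture.
        "MCT": SyntheticClassSpec("MCT", 3390.0, 24.0, 3.0, 0.70, 0.08, 0.45,
                                  clustering=0.15, aspect_mean=0.90,
                                  aspect_sd=0.05, chromatin_texture=0.45),
        # Melanoma: large spindle nuclei arranged in nests.
        "MEL": SyntheticClassSpec("MEL", 3900.0, 32.0, 5.0, 1.00, 0.10, 0.35,
                                  clustering=0.60, aspect_mean=0.35,
                                  aspect_sd=0.08, chromatin_texture=0.10),
        # Plasmacytoma: oval eccentric nuclei, dense sheets.
        "PLA": SyntheticClassSpec("PLA", 10000.0, 18.0, 2.0, 1.30, 0.10, 0.33,
                                  clustering=0.10, aspect_mean=0.60,
                                  aspect_sd=0.06, chromatin_texture=0.05),
    }
    specs = _maybe_harden(base, hard_mode)
    _assert_separated(specs)
    return specs


def grading_class_specs(hard_mode: bool = False) -> dict[str, SyntheticClassSpec]:
    """Three grades with monotonically increasing pleomorphism proxies.

    Radius spread and nuclear density both increase from grade 1 to 3.
    """
    base = {
        "MCT1": SyntheticClassSpec("MCT1", 3000.0, 22.0, 2.0, 0.75, 0.06, 0.42,
                                   clustering=0.10, aspect_mean=0.90,
                                   aspect_sd=0.05, chromatin_texture=0.10),
        "MCT2": SyntheticClassSpec("MCT2", 3800.0, 24.0, 4.0, 0.85, 0.08, 0.38,
                                   clustering=0.20, aspect_mean=0.85,
                                   aspect_sd=0.05, chromatin_texture=0.25),
        "MCT3": SyntheticClassSpec("MCT3", 5000.0, 26.0, 7.0, 1.00, 0.10, 0.33,
                                   clustering=0.30, aspect_mean=0.80,
                                   aspect_sd=0.08, chromatin_texture=0.45),
    }
    specs = _maybe_harden(base, hard_mode)
    _assert_separated(specs)
    assert (specs["MCT1"].radius_sd_px < specs["MCT2"].radius_sd_px
            < specs["MCT3"].radius_sd_px)
    assert (specs["MCT1"].density_per_mm2 < specs["MCT2"].density_per_mm2
            < specs["MCT3"].density_per_mm2)
    return specs


_SEPARATION_FIELDS = ("density_per_mm2", "radius_mean_px", "radius_sd_px",
                      "hematoxylin_mean", "eosin_background", "clustering",
                      "aspect_mean", "chromatin_texture")


def _maybe_harden(specs: dict[str, SyntheticClassSpec], hard: bool
                  ) -> dict[str, SyntheticClassSpec]:
    if not hard:
        return specs
    centers = {f: float(np.mean([getattr(s, f) for s in specs.values()]))
               for f in _SEPARATION_FIELDS}
    return {
        name: replace(s, **{f: _shrink_towards(getattr(s, f), centers[f], True)
                            for f in _SEPARATION_FIELDS})
        for name, s in specs.items()
    }


def _assert_separated(specs: dict[str, SyntheticClassSpec]) -> None:
    names = list(specs)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            differing = sum(
                not np.isclose(getattr(specs[a], f), getattr(specs[b], f))
                for f in _SEPARATION_FIELDS)
            assert differing >= 2, f"specs {a} and {b} differ in < 2 parameters"


def _sample_centers(rng: np.random.Generator, n: int, dims: tuple[int, int],
                    spec: SyntheticClassSpec) -> np.ndarray:
    """Nucleus centers: uniform, Thomas-process clustered, or spaced."""
    h, w = dims
    margin = spec.radius_mean_px + 3 * spec.radius_sd_px
    lo = np.array([margin, margin])
    hi = np.array([h - margin, w - margin])
    if np.any(hi <= lo):
        lo = np.array([0.0, 0.0])
        hi = np.array([float(h), float(w)])

    def uniform(k):
        return rng.uniform(lo, hi, size=(k, 2))

    if spec.min_separation_px > 0:
        centers: list[np.ndarray] = []
        attempts = 0
        while len(centers) < n and attempts < 200 * n:
            c = rng.uniform(lo, hi)
            attempts += 1
            if all(np.hypot(*(c - p)) >= spec.min_separation_px for p in centers):
                centers.append(c)
        return np.array(centers) if centers else np.zeros((0, 2))

    n_clustered = int(round(spec.clustering * n))
    pts = [uniform(n - n_clustered)]
    if n_clustered > 0:
        n_parents = max(1, n_clustered // 8)
        parents = uniform(n_parents)
        assignment = rng.integers(0, n_parents, size=n_clustered)
        spread = 3.0 * spec.radius_mean_px
        offsets = rng.normal(0.0, spread, size=(n_clustered, 2))
        pts.append(np.clip(parents[assignment] + offsets, lo, hi))
    return np.vstack(pts)


def render_image(spec: SyntheticClassSpec, dims: tuple[int, int] = DEFAULT_DIMS,
                 seed: int = 0) -> SyntheticImage:
    """Render one H&E-like field; fully determined by ``spec`` and ``seed``."""
    h, w = int(dims[0]), int(dims[1])
    if h < 64 or w < 64:
        raise InvalidParameterError("dims must be at least 64x64")
    rng = np.random.default_rng(seed)
    expected = spec.density_per_mm2 * h * w * MM2_PER_PIXEL
    n = int(rng.poisson(expected)) if expected > 0 else 0

    labels = np.zeros((h, w), dtype=np.int32)
    h_conc = np.full((h, w), _BACKGROUND_HEMATOXYLIN)
    e_conc = np.full((h, w), spec.eosin_background)

    centers = _sample_centers(rng, n, (h, w), spec) if n > 0 else np.zeros((0, 2))
    for i, (cy, cx) in enumerate(centers, start=1):
        r_major = max(3.0, rng.normal(spec.radius_mean_px, spec.radius_sd_px))
        aspect = float(np.clip(rng.normal(spec.aspect_mean, spec.aspect_sd),
                               0.25, 1.0))
        theta = rng.uniform(0.0, np.pi)
        strength = max(0.05, rng.normal(spec.hematoxylin_mean, spec.hematoxylin_sd))
        rr, cc = _draw_ellipse(cy, cx, r_major, r_major * aspect,
                               shape=(h, w), rotation=theta)
        labels[rr, cc] = i
        if spec.chromatin_texture > 0:
            # lognormal speckle, unit mean, emulating chromatin granularity
            tau = spec.chromatin_texture
            speckle = np.exp(tau * rng.standard_normal(rr.size) - tau * tau / 2)
            h_conc[rr, cc] = strength * speckle
        else:
            h_conc[rr, cc] = strength
        e_conc[rr, cc] = spec.eosin_background * _NUCLEAR_EOSIN_FACTOR

    # Per-image staining variability (what normalization removes).
    h_conc = h_conc * np.exp(rng.normal(0.0, _STAIN_JITTER_SD))
    e_conc = e_conc * np.exp(rng.normal(0.0, _STAIN_JITTER_SD))

    od = (h_conc[..., None] * CANONICAL_HEMATOXYLIN
          + e_conc[..., None] * CANONICAL_EOSIN)
    rgb = optical_density_to_rgb(od).astype(float)
    if spec.texture_noise_sd > 0:
        rgb = rgb + rng.normal(0.0, spec.texture_noise_sd, size=rgb.shape)
    image = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)

    # Overlapping nuclei may be fully overdrawn: renumber survivors.
    present = np.unique(labels)
    present = present[present > 0]
    remap = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    remap[present] = np.arange(1, present.size + 1)
    return SyntheticImage(image=image, truth=NucleiLabelMap(labels=remap[labels]),
                          label=spec.label, seed=int(seed))


def _subseed(seed: int, *branch: int) -> int:
    """Deterministic per-image seed below 2**31."""
    ss = np.random.SeedSequence([int(seed), *map(int, branch)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _generate_dataset(specs: dict[str, SyntheticClassSpec], n_per_class: int,
                      dims: tuple[int, int], seed: int, images_per_case: int,
                      out_dir: str | Path | None,
                      ) -> tuple[list[SyntheticImage], pd.DataFrame]:
    if n_per_class < 1:
        raise InvalidParameterError("n_per_class must be >= 1")
    images: list[SyntheticImage] = []
    records = []
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        (out_path / "images").mkdir(parents=True, exist_ok=True)
        (out_path / "masks").mkdir(parents=True, exist_ok=True)
    for class_idx, (label, spec) in enumerate(sorted(specs.items())):
        for i in range(n_per_class):
            img_seed = _subseed(seed, class_idx, i)
            synth = render_image(spec, dims=dims, seed=img_seed)
            synth.image_id = f"{label}_{i:03d}"
            synth.case_id = f"{label}_case{i // images_per_case:02d}"
            image_path = ""
            if out_path is not None:
                image_path = str(out_path / "images" / f"{synth.image_id}.png")
                iio.imwrite(image_path, synth.image)
                synth.truth.save(out_path / "masks" / f"{synth.image_id}.tif")
            images.append(synth)
            records.append({"path": image_path, "case_id": synth.case_id,
                            "image_id": synth.image_id, "label": label,
                            "seed": img_seed})
    manifest = pd.DataFrame.from_records(records)
    if out_path is not None:
        manifest.to_csv(out_path / "manifest.csv", index=False)
    return images, manifest


def generate_rct_dataset(n_per_class: int, dims: tuple[int, int] = DEFAULT_DIMS,
                         seed: int = 0, hard_mode: bool = False,
                         out_dir: str | Path | None = None,
                         ) -> tuple[list[SyntheticImage], pd.DataFrame]:
    """Balanced five-class dataset; images grouped into pseudo-cases of <= 5."""
    return _generate_dataset(rct_class_specs(hard_mode), n_per_class, dims,
                             seed, images_per_case=5, out_dir=out_dir)


def generate_grading_dataset(n_per_grade: int, dims: tuple[int, int] = DEFAULT_DIMS,
                             seed: int = 0, hard_mode: bool = False,
                             out_dir: str | Path | None = None,
                             ) -> tuple[list[SyntheticImage], pd.DataFrame]:
    """Balanced three-grade mast-cell-tumor dataset (pseudo-cases of <= 5)."""
    return _generate_dataset(grading_class_specs(hard_mode), n_per_grade, dims,
                             seed, images_per_case=5, out_dir=out_dir)
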