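"""Reading and writing the pipeline's file formats (PNG/TIFF images, CSV tables)."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .exceptions import InvalidDataError

IMAGE_SUFFIXES = (".png", ".tif", ".tiff")


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG or TIFF image as an HxWx3 uint8 array."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(str(path))
    else:
        arr = iio.imread(str(path))
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[..., :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise InvalidDataError(f"{path} is not an RGB image (shape {arr.shape})")
    return arr.astype(np.uint8)


def write_image(path: str | Path, image: np.ndarray) -> None:
    path = Path(path)
    image = np.asarray(image, dtype=np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(str(path), image)
    else:
        iio.imwrite(str(path), image)


def list_images(directory: str | Path) -> list[Path]:
    directory = Path(directory)
    return sorted(p for p in directory.iterdir()
                  if p.suffix.lower() in IMAGE_SUFFIXES)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Dataset manifest CSV: path, case_id, image_id, label (seed optional)."""
    manifest = pd.read_csv(path)
    required = {"path", "case_id", "image_id", "label"}
    missing = required - set(manifest.columns)
    if missing:
        raise InvalidDataError(f"manifest is missing columns: {sorted(missing)}")
    return manifest
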