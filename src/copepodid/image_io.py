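"""Raster image I/O and dataset manifests.

All downstream modules work on a single intensity convention: a 2-D
float array in [0, 1], row-major, origin at the top-left corner, row
index increasing downward and column index increasing rightward.
Loading normalises whatever bit depth the file uses (8- or 16-bit,
grayscale or RGB) into that domain, so filter and threshold code never
needs to know where an image came from.

A dataset is described by a plain CSV manifest with columns
``image_path,species_code,role`` (role is ``train`` or ``test``); the
label set is closed and validated at read time.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image

#: Species codes used throughout: Acartia spinicauda, Bestiolina
#: similis, Oithona aruensis / dissimilis / simplex, Parvocalanus
#: crassirostris, Tortanus barbatus / forcipatus.
DEFAULT_SPECIES_CODES = ("As", "Bs", "Oa", "Od", "Os", "Pc", "Tb", "Tf")

#: Species -> genus grouping used for genus-level evaluation.
DEFAULT_GENUS_MAP = {
    "As": "Acartia",
    "Bs": "Bestiolina",
    "Oa": "Oithona",
    "Od": "Oithona",
    "Os": "Oithona",
    "Pc": "Parvocalanus",
    "Tb": "Tortanus",
    "Tf": "Tortanus",
}

# ITU-R BT.601 luma weights for RGB -> grayscale, normalised to sum
# exactly to 1 so neutral gray maps to itself.
_LUMA = np.array([0.2989, 0.5870, 0.1140])
_LUMA = _LUMA / _LUMA.sum()


@dataclass
class RasterImage:
    """A grayscale intensity grid with provenance.

    ``pixels`` is float64 in [0, 1]; shape is (height, width).
    """

    pixels: np.ndarray
    source_path: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("RasterImage requires a non-empty 2-D array")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def to_grayscale(arr: np.ndarray) -> np.ndarray:
    """Collapse an RGB(A) array to one luminance channel.

    Idempotent on arrays that are already 2-D. Alpha is ignored.
    """
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        return arr[..., :3] @ _LUMA
    raise ValueError("unsupported image format: expected 1 or 3 channels")


def load_image(path: str | os.PathLike) -> RasterImage:
    """Load a TIFF or PNG image as a grayscale RasterImage in [0, 1].

    8-bit data is divided by 255 and 16-bit by 65535; RGB collapses to
    luminance with BT.601 weights (0.2989 R + 0.5870 G + 0.1140 B).

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        For unsupported formats or bit depths.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"file not found: {path}")
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.dtype == np.uint8:
        scale = 255.0
    elif arr.dtype == np.uint16:
        scale = 65535.0
    elif np.issubdtype(arr.dtype, np.floating):
        scale = 1.0
    else:
        raise ValueError(f"unsupported image format: dtype {arr.dtype}")
    gray = to_grayscale(arr.astype(np.float64) / scale)
    return RasterImage(np.clip(gray, 0.0, 1.0), source_path=path)


def save_image(img: RasterImage | np.ndarray, path: str | os.PathLike) -> None:
    """Write intensities (or a boolean mask) as an 8-bit PNG/TIFF."""
    arr = img.pixels if isinstance(img, RasterImage) else np.asarray(img)
    if arr.dtype == bool:
        out = np.where(arr, 255, 0).astype(np.uint8)
    else:
        out = np.clip(np.round(arr * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(out).save(os.fspath(path))


@dataclass
class DatasetManifest:
    """Validated list of (image_path, species_code, role) entries."""

    entries: pd.DataFrame
    label_set: tuple = field(default=DEFAULT_SPECIES_CODES)

    def __len__(self) -> int:
        return len(self.entries)

    def subset(self, role: str) -> pd.DataFrame:
        return self.entries[self.entries["role"] == role].reset_index(drop=True)

    def counts(self) -> pd.DataFrame:
        """Per (species_code, role) image counts."""
        return (
            self.entries.groupby(["species_code", "role"])
            .size()
            .unstack(fill_value=0)
        )


def read_manifest(
    path: str | os.PathLike,
    label_set: tuple = DEFAULT_SPECIES_CODES,
    check_paths: bool = False,
) -> DatasetManifest:
    """Read and validate a CSV manifest.

    Raises ``ValueError`` on labels outside ``label_set`` or duplicate
    image paths; with ``check_paths`` every path must resolve (relative
    paths resolve against the manifest's directory).
    """
    path = os.fspath(path)
    df = pd.read_csv(path, dtype=str)
    required = {"image_path", "species_code", "role"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    df = df[["image_path", "species_code", "role"]].copy()
    bad = set(df["species_code"]) - set(label_set)
    if bad:
        raise ValueError(f"label not in declared label set: {sorted(bad)}")
    dup = df["image_path"].duplicated()
    if dup.any():
        raise ValueError(f"duplicate entry: {df.loc[dup, 'image_path'].iloc[0]}")
    bad_role = set(df["role"]) - {"train", "test"}
    if bad_role:
        raise ValueError(f"unknown role: {sorted(bad_role)}")
    if check_paths:
        base = os.path.dirname(path)
        for p in df["image_path"]:
            full = p if os.path.isabs(p) else os.path.join(base, p)
            if not os.path.exists(full):
                raise FileNotFoundError(f"file not found: {full}")
    return DatasetManifest(df.reset_index(drop=True), tuple(label_set))
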