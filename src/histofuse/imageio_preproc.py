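"""Raster tile I/O and preprocessing shared by all feature extractors.

Tiles follow the LC25000 on-disk convention: RGB PNG/JPEG rasters, natively
768x768, organised one subdirectory per class or listed in a manifest CSV
with columns ``path,label``.  The class vocabulary is fixed to LACA (lung
adenocarcinoma), LSCC (lung squamous cell carcinoma) and benign lung tissue,
with stable integer codes 0/1/2 in that order.

Preprocessing is the standard two-step applied before feature extraction:
resize to 224x224 (bilinear, anti-aliased) for every branch, and a BT.601
luma grayscale conversion for the textural branch.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError
from skimage.transform import resize as _skimage_resize

logger = logging.getLogger(__name__)

#: Fixed class vocabulary and integer codes.
CLASS_NAMES: tuple[str, ...] = ("LACA", "LSCC", "benign")
CLASS_CODES: dict[str, int] = {name: i for i, name in enumerate(CLASS_NAMES)}

#: ITU-R BT.601 luma weights used for the grayscale conversion.
LUMA_WEIGHTS: tuple[float, float, float] = (0.299, 0.587, 0.114)

#: Side length every tile is resized to before feature extraction.
PIPELINE_SIDE = 224

#: Native LC25000 tile side length.
NATIVE_SIDE = 768


@dataclass
class ImageTile:
    """An RGB raster tile with an optional class label.

    Parameters
    ----------
    pixels:
        ``(H, W, 3)`` uint8 array of intensities in [0, 255].
    label:
        Class name from :data:`CLASS_NAMES`, or None when unknown.
    source_id:
        Opaque identifier (file path, synthetic seed tag, ...) used for
        feature caching and manifests.
    """

    pixels: np.ndarray
    label: str | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(
                f"tile must be H x W x 3, got shape {px.shape}"
            )
        if px.dtype != np.uint8:
            if px.size and (px.min() < 0 or px.max() > 255):
                raise ValueError("tile intensities must lie in [0, 255]")
            px = np.asarray(np.round(px), dtype=np.uint8)
        if self.label is not None and self.label not in CLASS_CODES:
            raise ValueError(
                f"unknown label {self.label!r}; expected one of {CLASS_NAMES}"
            )
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def label_code(self) -> int | None:
        return None if self.label is None else CLASS_CODES[self.label]


@dataclass
class GrayImage:
    """A single-channel real-valued image with intensities in [0, 255]."""

    intensities: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError(f"gray image must be 2-D, got shape {arr.shape}")
        self.intensities = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape  # type: ignore[return-value]


def load_tile(path: str | Path, label: str | None = None) -> ImageTile:
    """Read a PNG/JPEG raster into an :class:`ImageTile`.

    The label comes from the explicit ``label`` argument, or from the parent
    directory name when that matches the class vocabulary — never from the
    pixel content.  Grayscale sources are replicated to three channels with a
    logged warning; other non-RGB modes are rejected.
    """
    path = Path(path)
    try:
        with Image.open(path) as img:
            img.load()
            mode = img.mode
            if mode == "RGB":
                px = np.asarray(img)
            elif mode in ("L", "I;16", "I"):
                logger.warning(
                    "grayscale raster %s replicated to 3 channels", path
                )
                arr = np.asarray(img.convert("L"))
                px = np.repeat(arr[:, :, None], 3, axis=2)
            else:
                raise ValueError(
                    f"unreadable raster: {path} has non-RGB mode {mode!r}"
                )
    except (UnidentifiedImageError, OSError) as exc:
        raise ValueError(f"unreadable raster: {path}") from exc

    if label is None:
        parent = path.parent.name
        if parent in CLASS_CODES:
            label = parent
    return ImageTile(pixels=px, label=label, source_id=str(path))


def resize_tile(tile: ImageTile, side: int = PIPELINE_SIDE) -> ImageTile:
    """Resize a tile to ``side x side`` with anti-aliased bilinear sampling.

    Resizing to the tile's current size is the identity (pixels unchanged).
    """
    if side < 8:
        raise ValueError(f"target side must be >= 8, got {side}")
    if tile.height == side and tile.width == side:
        return ImageTile(tile.pixels.copy(), tile.label, tile.source_id)
    out = _skimage_resize(
        tile.pixels.astype(np.float64),
        (side, side, 3),
        order=1,
        anti_aliasing=True,
        preserve_range=True,
    )
    out = np.clip(np.round(out), 0, 255).astype(np.uint8)
    return ImageTile(out, tile.label, tile.source_id)


def to_grayscale(tile: ImageTile) -> GrayImage:
    """BT.601 luma conversion, kept real-valued (no re-quantisation).

    luma = 0.299 R + 0.587 G + 0.114 B per pixel; the output stays a float
    so the LBP threshold sees unrounded intensity differences.
    """
    w = np.asarray(LUMA_WEIGHTS, dtype=np.float64)
    return GrayImage(tile.pixels.astype(np.float64) @ w)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a dataset manifest CSV with columns (path, label)."""
    df = pd.read_csv(path)
    missing = {"path", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    bad = set(df["label"]) - set(CLASS_NAMES)
    if bad:
        raise ValueError(f"manifest contains unknown labels: {sorted(bad)}")
    return df


def load_dataset(manifest: str | Path | pd.DataFrame,
                 root: str | Path | None = None) -> list[ImageTile]:
    """Load every tile listed in a manifest (CSV path or DataFrame)."""
    if not isinstance(manifest, pd.DataFrame):
        manifest_path = Path(manifest)
        if root is None:
            root = manifest_path.parent
        manifest = read_manifest(manifest_path)
    root = Path(root) if root is not None else Path(".")
    tiles = []
    for row in manifest.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = root / p
        tiles.append(load_tile(p, label=row.label))
    return tiles


def tiles_from_directory(directory: str | Path) -> list[ImageTile]:
    """Load tiles from a directory laid out one subdirectory per class."""
    directory = Path(directory)
    tiles: list[ImageTile] = []
    for name in CLASS_NAMES:
        sub = directory / name
        if not sub.is_dir():
            continue
        for p in sorted(sub.iterdir()):
            if p.suffix.lower() in (".png", ".jpg", ".jpeg"):
                tiles.append(load_tile(p, label=name))
    if not tiles:
        raise ValueError(f"no class subdirectories with rasters in {directory}")
    return tiles
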