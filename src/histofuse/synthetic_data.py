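"""Deterministic synthetic histology-like tile generator.

Generates 768x768 RGB tiles (the native LC25000 tile geometry) for three
visually distinct tissue classes so every pipeline stage is testable with
no download: a stain-tinted smoothed random background field at a
class-specific correlation length, overlaid with a Poisson-distributed
count of elliptical "nuclei" of class-specific density and eccentricity,
plus i.i.d. pixel noise.  The classes imitate the qualitative contrast
between benign lung tissue (sparse, round nuclei on a coarse background)
and the two carcinoma appearances (denser, more elongated nuclei with
distinct background correlation lengths); parameters are chosen for
separability, not histological realism.

Per-tile seeds are derived from one master seed through a splitmix64
counter, so tile i of a dataset is reproducible independently of the
others (order-independent and parallel-safe).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse as _draw_ellipse

from .imageio_preproc import CLASS_NAMES, ImageTile, NATIVE_SIDE


@dataclass(frozen=True)
class SyntheticClassParams:
    """Appearance parameters for one synthetic tissue class.

    nucleus_density: Poisson mean count of nuclei per tile;
    eccentricity_range: sampled uniformly per nucleus;
    background_hue: stain-like RGB base colour;
    correlation_length: Gaussian smoothing sigma of the background field
    (pixels); noise_level: per-pixel Gaussian noise sigma (intensity).
    """

    class_name: str
    nucleus_density: float
    eccentricity_range: tuple[float, float]
    background_hue: tuple[int, int, int]
    correlation_length: float
    noise_level: float
    nucleus_radius: float = 9.0

    def __post_init__(self) -> None:
        if self.nucleus_density < 0:
            raise ValueError("nucleus density must be >= 0")
        lo, hi = self.eccentricity_range
        if not 0.0 <= lo <= hi < 1.0:
            raise ValueError("eccentricity range must satisfy 0 <= lo <= hi < 1")


#: Default class parameter sets (pairwise distinct in several fields).
DEFAULT_CLASS_PARAMS: dict[str, SyntheticClassParams] = {
    "benign": SyntheticClassParams(
        class_name="benign", nucleus_density=80.0,
        eccentricity_range=(0.05, 0.30), background_hue=(235, 205, 215),
        correlation_length=20.0, noise_level=6.0),
    "LACA": SyntheticClassParams(
        class_name="LACA", nucleus_density=260.0,
        eccentricity_range=(0.25, 0.55), background_hue=(215, 170, 205),
        correlation_length=6.0, noise_level=10.0),
    "LSCC": SyntheticClassParams(
        class_name="LSCC", nucleus_density=420.0,
        eccentricity_range=(0.55, 0.85), background_hue=(220, 160, 185),
        correlation_length=12.0, noise_level=10.0),
}

#: Nucleus stain colour (hematoxylin-like purple) before per-nucleus jitter.
_NUCLEUS_RGB = np.array([90.0, 60.0, 130.0])

_MASK64 = 0xFFFFFFFFFFFFFFFF


def splitmix64(x: int) -> int:
    """One splitmix64 step; maps a 64-bit state to a well-mixed output."""
    x = (x + 0x9E3779B97F4A7C15) & _MASK64
    z = x
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK64
    return (z ^ (z >> 31)) & _MASK64


def child_seed(master_seed: int, index: int) -> int:
    """Derive the i-th child seed (< 2^31) from a master seed."""
    mixed = splitmix64(((master_seed & _MASK64) << 20) ^ index)
    return int(mixed % (2 ** 31))


def generate_tile(params: SyntheticClassParams, seed: int,
                  side: int = NATIVE_SIDE) -> ImageTile:
    """Render one synthetic tile; bit-identical for identical (params, seed)."""
    rng = np.random.default_rng(seed)

    # Smoothed background field at the class correlation length, scaled to
    # a fixed contrast and added to the stain-like base hue.
    field = rng.standard_normal((side, side))
    field = gaussian_filter(field, sigma=params.correlation_length)
    sd = field.std()
    if sd > 0:
        field = field / sd * 12.0
    img = np.empty((side, side, 3))
    hue = np.asarray(params.background_hue, dtype=np.float64)
    for ch in range(3):
        img[:, :, ch] = hue[ch] + field

    # Poisson-count elliptical nuclei with class eccentricity.
    n_nuclei = int(rng.poisson(params.nucleus_density))
    for _ in range(n_nuclei):
        r = rng.uniform(0, side)
        c = rng.uniform(0, side)
        ecc = rng.uniform(*params.eccentricity_range)
        a = params.nucleus_radius * rng.uniform(0.7, 1.3)
        b = a * np.sqrt(1.0 - ecc ** 2)
        theta = rng.uniform(0, np.pi)
        alpha = rng.uniform(0.55, 0.85)
        color = _NUCLEUS_RGB + rng.normal(0.0, 8.0, size=3)
        rr, cc = _draw_ellipse(r, c, a, b, rotation=theta, shape=(side, side))
        img[rr, cc] = (1 - alpha) * img[rr, cc] + alpha * color

    img += rng.normal(0.0, params.noise_level, size=img.shape)
    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return ImageTile(pixels=pixels, label=params.class_name,
                     source_id=f"synthetic:{params.class_name}:{seed}")


def generate_dataset(n_per_class: int, seed: int,
                     out_dir: str | Path | None = None,
                     side: int = NATIVE_SIDE,
                     class_params: dict[str, SyntheticClassParams] | None = None,
                     ) -> tuple[list[ImageTile], pd.DataFrame]:
    """Generate ``3 * n_per_class`` labelled tiles plus a manifest.

    Tiles are ordered class-major in the canonical class order; tile i
    gets child seed ``child_seed(seed, i)``.  When ``out_dir`` is given,
    PNGs are written one subdirectory per class along with
    ``manifest.csv`` (columns path, label, seed).
    """
    if n_per_class < 5:
        raise ValueError("n_per_class must be >= 5")
    class_params = class_params or DEFAULT_CLASS_PARAMS
    tiles: list[ImageTile] = []
    records = []
    idx = 0
    for name in CLASS_NAMES:
        params = class_params[name]
        for j in range(n_per_class):
            s = child_seed(seed, idx)
            tile = generate_tile(params, s, side=side)
            tiles.append(tile)
            records.append({"path": f"{name}/tile_{j:04d}.png",
                            "label": name, "seed": s})
            idx += 1
    manifest = pd.DataFrame(records)
    if out_dir is not None:
        out_dir = Path(out_dir)
        for tile, rec in zip(tiles, records):
            p = out_dir / rec["path"]
            p.parent.mkdir(parents=True, exist_ok=True)
            Image.fromarray(tile.pixels).save(p)
            tile.source_id = str(p)
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return tiles, manifest
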