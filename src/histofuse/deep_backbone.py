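"""Deep feature block: pluggable CNN backbone + global average pooling.

The deep branch contract is any map from a 224x224x3 tile to a spatial
feature map (default 7x7x1280, the EfficientNet-B0 penultimate shape);
global average pooling then reduces the map to a 1280-vector.  The backbone
itself is pluggable:

* ``seeded_test`` — a fixed, seed-determined stack of non-overlapping
  strided patch projections with a tanh nonlinearity, mapping
  224x224x3 -> 7x7x1280 deterministically.  This backbone carries all
  automated testing; it is a real convolutional feature extractor, just an
  untrained one.
* ``pretrained_adapter`` — a user-supplied callable (e.g. a beheaded
  pretrained EfficientNet-B0 wrapped by the caller) honouring the same
  shape contract; the adapter applies its own input normalisation.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .fusion_matrix import FeatureBlock
from .imageio_preproc import ImageTile

#: Default spatial feature-map shape (EfficientNet-B0 penultimate layer).
DEFAULT_OUT_SHAPE = (7, 7, 1280)


@dataclass
class BackboneSpec:
    """Backbone selection: kind, output shape and weight source."""

    kind: str = "seeded_test"
    out_shape: tuple[int, int, int] = DEFAULT_OUT_SHAPE
    seed: int = 0
    weight_source: object | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("seeded_test", "pretrained_adapter"):
            raise ValueError(f"unknown backbone kind {self.kind!r}")
        if self.kind == "pretrained_adapter" and not callable(self.weight_source):
            raise ValueError(
                "pretrained_adapter requires a callable weight_source "
                "mapping an HxWx3 uint8 array to a feature map"
            )


def global_average_pool(fmap: np.ndarray) -> np.ndarray:
    """Channel-wise spatial mean: h' x w' x C -> length-C vector."""
    fmap = np.asarray(fmap, dtype=np.float64)
    if fmap.ndim != 3:
        raise ValueError(f"feature map must be 3-D, got shape {fmap.shape}")
    if fmap.shape[0] == 0 or fmap.shape[1] == 0:
        raise ValueError("feature map has empty spatial extent")
    return fmap.mean(axis=(0, 1))


def _factorize_stride(total: int) -> list[int]:
    """Decompose a total downsampling factor into patch strides <= 4."""
    factors = []
    rest = total
    for f in (4, 3, 2):
        while rest % f == 0 and rest > 1:
            factors.append(f)
            rest //= f
    if rest != 1:
        raise ValueError(f"cannot realise downsampling factor {total} "
                         "with strides in (2, 3, 4)")
    return factors


class SeededTestBackbone:
    """Deterministic random-weight convolutional feature extractor.

    Each stage partitions the image into non-overlapping f x f patches and
    linearly projects every patch (a strided convolution), followed by tanh.
    Weights are drawn once from N(0, 1/fan_in) with a fixed seed; the same
    seed and input always give a bit-identical feature map.  Pixels are
    scaled to [0, 1] on input.
    """

    def __init__(self, seed: int, in_side: int = 224,
                 out_shape: tuple[int, int, int] = DEFAULT_OUT_SHAPE):
        h, w, C = out_shape
        if h != w:
            raise ValueError("test backbone requires a square output map")
        if in_side % h != 0:
            raise ValueError(f"input side {in_side} not divisible by output side {h}")
        self.in_side = in_side
        self.out_shape = tuple(out_shape)
        self.seed = int(seed)
        self.strides = _factorize_stride(in_side // h)
        rng = np.random.default_rng(self.seed)
        # Channel schedule: grow towards C, capped mid-pipeline at 128.
        chans = [3]
        for i, f in enumerate(self.strides):
            if i == len(self.strides) - 1:
                chans.append(C)
            else:
                chans.append(min(128, chans[-1] * f * f))
        self.weights = []
        for f, c_in, c_out in zip(self.strides, chans[:-1], chans[1:]):
            fan_in = c_in * f * f
            self.weights.append(
                rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=(fan_in, c_out))
            )

    def __call__(self, pixels: np.ndarray) -> np.ndarray:
        x = np.asarray(pixels, dtype=np.float64) / 255.0
        if x.shape[:2] != (self.in_side, self.in_side) or x.shape[2] != 3:
            raise ValueError(
                f"expected {self.in_side}x{self.in_side}x3 input, got {x.shape}"
            )
        for f, W in zip(self.strides, self.weights):
            h, w, c = x.shape
            x = (x.reshape(h // f, f, w // f, f, c)
                  .transpose(0, 2, 1, 3, 4)
                  .reshape(h // f, w // f, f * f * c))
            x = np.tanh(x @ W)
        return x


def make_test_backbone(seed: int, in_side: int = 224,
                       out_shape: tuple[int, int, int] = DEFAULT_OUT_SHAPE
                       ) -> SeededTestBackbone:
    """Build the seeded deterministic test backbone."""
    return SeededTestBackbone(seed=seed, in_side=in_side, out_shape=out_shape)


def resolve_backbone(spec: BackboneSpec, in_side: int = 224
                     ) -> Callable[[np.ndarray], np.ndarray]:
    """Turn a :class:`BackboneSpec` into a feature-map callable."""
    if spec.kind == "seeded_test":
        return make_test_backbone(spec.seed, in_side=in_side,
                                  out_shape=spec.out_shape)
    return spec.weight_source  # pretrained adapter: caller-supplied callable


def extract_deep_features(tile: ImageTile,
                          backbone: BackboneSpec | Callable[[np.ndarray], np.ndarray],
                          expected_dim: int | None = None) -> FeatureBlock:
    """Run the backbone and pool to the ``deep`` feature block.

    ``expected_dim`` defaults to the spec's channel count (or 1280 for a
    bare callable); a backbone emitting a different channel count is an
    error rather than a silent contract change.
    """
    if isinstance(backbone, BackboneSpec):
        if expected_dim is None:
            expected_dim = backbone.out_shape[2]
        fn = resolve_backbone(backbone, in_side=tile.height)
    else:
        fn = backbone
        if expected_dim is None:
            expected_dim = DEFAULT_OUT_SHAPE[2]
    fmap = np.asarray(fn(tile.pixels))
    if fmap.ndim != 3 or fmap.shape[2] != expected_dim:
        raise ValueError(
            f"backbone produced shape {fmap.shape}, expected channels={expected_dim}"
        )
    return FeatureBlock(name="deep", values=global_average_pool(fmap))
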