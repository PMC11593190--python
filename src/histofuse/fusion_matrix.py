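"""Feature-block fusion, matrix assembly and the train/test split.

A sample is described by up to three named feature blocks — ``deep`` (1280
values from the CNN backbone after global average pooling), ``textural``
(P+2 values from the uniform LBP histogram, 1280 at the default P=1278) and
``contextual`` (n_patches * embed_dim values from the ViT encoder, 150,528
at ViT-Base/16 defaults).  Fusion concatenates the blocks present in the
fixed order (deep, textural, contextual) and records block offsets so any
block can be sliced back out bit-exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical concatenation order of the feature blocks.
BLOCK_ORDER: tuple[str, ...] = ("deep", "textural", "contextual")


@dataclass
class FeatureBlock:
    """One named, fixed-dimension feature vector."""

    name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.name not in BLOCK_ORDER:
            raise ValueError(
                f"unknown block name {self.name!r}; expected one of {BLOCK_ORDER}"
            )
        v = np.asarray(self.values, dtype=np.float64).ravel()
        if v.size == 0:
            raise ValueError("feature block must be non-empty")
        self.values = v

    @property
    def dim(self) -> int:
        return int(self.values.size)


@dataclass
class FusedFeature:
    """Concatenated per-sample feature vector with recorded block offsets.

    ``offsets`` is an ordered tuple of ``(block name, start, length)``;
    slicing ``values[start:start+length]`` recovers the input block.
    """

    values: np.ndarray
    offsets: tuple[tuple[str, int, int], ...]

    @property
    def dim(self) -> int:
        return int(self.values.size)

    def get_block(self, name: str) -> np.ndarray:
        for bname, start, length in self.offsets:
            if bname == name:
                return self.values[start:start + length]
        raise KeyError(f"no block named {name!r} in fused feature")


def fuse(blocks: list[FeatureBlock] | tuple[FeatureBlock, ...]) -> FusedFeature:
    """Concatenate feature blocks in (deep, textural, contextual) order.

    Only the blocks present are concatenated; duplicates are an error.
    deep(1280) + textural(1280) fuses to 2560; adding the default
    contextual block (150,528) gives 153,088.
    """
    if not blocks:
        raise ValueError("cannot fuse an empty block list")
    names = [b.name for b in blocks]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate block names in {names}")
    ordered = sorted(blocks, key=lambda b: BLOCK_ORDER.index(b.name))
    offsets = []
    start = 0
    for b in ordered:
        offsets.append((b.name, start, b.dim))
        start += b.dim
    values = np.concatenate([b.values for b in ordered])
    return FusedFeature(values=values, offsets=tuple(offsets))


@dataclass
class FeatureMatrix:
    """Stacked n x d fused-feature matrix with labels and shared offsets."""

    X: np.ndarray
    labels: np.ndarray
    offsets: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.X.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.X.shape[0] != self.labels.shape[0]:
            raise ValueError("labels length must match number of rows")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def dim(self) -> int:
        return self.X.shape[1]

    def subset(self, idx: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(self.X[idx], self.labels[idx], self.offsets)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X)
        df.insert(0, "label", self.labels)
        return df

    def save_npz(self, path) -> None:
        offs = np.array(
            [(n, s, l) for n, s, l in self.offsets],
            dtype=[("name", "U16"), ("start", "i8"), ("length", "i8")],
        )
        np.savez_compressed(path, X=self.X, labels=self.labels, offsets=offs)

    @classmethod
    def load_npz(cls, path) -> "FeatureMatrix":
        with np.load(path, allow_pickle=False) as z:
            offsets = tuple(
                (str(r["name"]), int(r["start"]), int(r["length"]))
                for r in z["offsets"]
            )
            return cls(z["X"], z["labels"], offsets)


def assemble_matrix(samples: list[FusedFeature], labels) -> FeatureMatrix:
    """Stack fused samples row-wise into a :class:`FeatureMatrix`."""
    if not samples:
        raise ValueError("cannot assemble an empty sample list")
    labels = np.asarray(labels)
    if labels.shape[0] != len(samples):
        raise ValueError("labels length must match number of samples")
    offsets = samples[0].offsets
    for i, s in enumerate(samples):
        if s.offsets != offsets:
            raise ValueError(
                f"sample {i} has offsets {s.offsets}, expected {offsets}"
            )
    X = np.stack([s.values for s in samples])
    return FeatureMatrix(X=X, labels=labels, offsets=offsets)


def split_dataset(samples, ratio: float = 0.8, seed: int = 0,
                  stratified: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic train/test index split.

    Parameters
    ----------
    samples:
        Either an integer sample count (unstratified only) or a label array.
    ratio:
        Training fraction in (0, 1); the canonical protocol is 0.8, which
        sends 12,000 of 15,000 tiles to training and 3,000 to test.
    seed:
        Fully determines the permutation.
    stratified:
        Allocate per class so class proportions are preserved exactly when
        ``ratio * n_class`` is integral (the default; 1,000 test tiles per
        class at full scale).

    Returns sorted, disjoint, exhaustive ``(train_idx, test_idx)`` arrays.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"ratio must be in (0, 1), got {ratio}")
    rng = np.random.default_rng(seed)
    if np.isscalar(samples):
        n = int(samples)
        if stratified:
            raise ValueError("stratified split requires a label array")
        perm = rng.permutation(n)
        n_train = int(round(ratio * n))
        return np.sort(perm[:n_train]), np.sort(perm[n_train:])

    labels = np.asarray(samples)
    n = labels.shape[0]
    if not stratified:
        return split_dataset(n, ratio, seed, stratified=False)
    train_parts, test_parts = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            raise ValueError(
                f"class {cls!r} has {idx.size} sample(s); stratified split needs >= 2"
            )
        idx = rng.permutation(idx)
        n_train = int(round(ratio * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        train_parts.append(idx[:n_train])
        test_parts.append(idx[n_train:])
    return (np.sort(np.concatenate(train_parts)),
            np.sort(np.concatenate(test_parts)))
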