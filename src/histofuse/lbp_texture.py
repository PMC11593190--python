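"""From-scratch local binary pattern (LBP) texture features.

The LBP code of a pixel with intensity g_c and circular neighbours
g_0..g_{P-1} at radius R is

    LBP_{P,R} = sum_p s(g_p - g_c) * 2^p,      s(x) = 1 if x >= 0 else 0,

with neighbour p at angle theta_p = 2*pi*p/P, counter-clockwise from east
in image coordinates: offset (-R sin theta_p, +R cos theta_p) in (row, col).
Non-integer neighbour positions are bilinearly interpolated; coordinates
within 1e-8 of an integer are snapped so axial samples read pixels exactly.

Two histogram modes are supported:

* ``raw`` — one bin per code, 2^P bins; only enumerable for P <= 16.
* ``uniform`` — patterns with at most two circular 0/1 transitions are
  binned by their number of ones (bins 0..P), all other patterns share the
  P+1 "non-uniform" bin, giving P+2 bins.  At the pipeline default
  P = 1278, R = 1 this yields a 1280-dimensional textural block, matching
  the deep block's width.

P = 1278 on a radius-1 circle heavily oversamples the 8 physical
neighbouring pixels; the sampling is implemented literally (interpolated
duplicates) with interpolation stencils precomputed once per config.
Pixels within ceil(R) of the border are excluded from the histogram rather
than padded.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .fusion_matrix import FeatureBlock
from .imageio_preproc import GrayImage

#: Snap tolerance for neighbour coordinates that should be integral.
COORD_SNAP = 1e-8


@dataclass(frozen=True)
class LBPConfig:
    """LBP extraction parameters.

    P: number of circular neighbours; R: circle radius in pixels;
    mode: ``uniform`` (P+2 bins) or ``raw`` (2^P bins, P <= 16 only);
    normalize: divide the histogram by the number of coded pixels.
    """

    P: int = 1278
    R: float = 1.0
    mode: str = "uniform"
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.P < 1:
            raise ValueError(f"P must be positive, got {self.P}")
        if self.R <= 0:
            raise ValueError(f"R must be positive, got {self.R}")
        if self.mode not in ("uniform", "raw"):
            raise ValueError(f"mode must be 'uniform' or 'raw', got {self.mode!r}")
        if self.mode == "raw" and self.P > 16:
            raise ValueError("raw mode requires P <= 16 (2^P bins)")

    @property
    def n_bins(self) -> int:
        return self.P + 2 if self.mode == "uniform" else 2 ** self.P

    @property
    def border(self) -> int:
        return int(math.ceil(self.R))


@dataclass
class LBPNeighborhood:
    """Centre intensity g_c and the ordered P neighbour intensities g_p."""

    g_c: float
    g_p: np.ndarray

    def __post_init__(self) -> None:
        self.g_p = np.asarray(self.g_p, dtype=np.float64).ravel()


@dataclass
class LBPCodeMap:
    """Integer LBP codes over the valid (border-excluded) region."""

    codes: np.ndarray
    n_bins: int

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.size and (self.codes.min() < 0
                                or self.codes.max() >= self.n_bins):
            raise ValueError("codes out of range for n_bins")


def threshold_s(x: float) -> int:
    """The LBP sign threshold: 0 for x < 0, 1 for x >= 0."""
    return 1 if x >= 0 else 0


def neighbor_offsets(cfg: LBPConfig) -> np.ndarray:
    """(P, 2) array of (d_row, d_col) offsets, snapped near integers."""
    p = np.arange(cfg.P)
    theta = 2.0 * np.pi * p / cfg.P
    dr = -cfg.R * np.sin(theta)
    dc = cfg.R * np.cos(theta)
    offs = np.stack([dr, dc], axis=1)
    near = np.abs(offs - np.round(offs)) < COORD_SNAP
    offs[near] = np.round(offs[near])
    return offs


def _stencil(d: float) -> tuple[int, float]:
    """Floor corner and fractional weight along one axis."""
    f = math.floor(d)
    return int(f), d - f


@lru_cache(maxsize=32)
def _stencils(P: int, R: float) -> tuple:
    """Per-neighbour bilinear stencils: (fr, fc, w00, w01, w10, w11)."""
    offs = neighbor_offsets(LBPConfig(P=P, R=R, mode="uniform"))
    out = []
    for dr, dc in offs:
        fr, ar = _stencil(float(dr))
        fc, ac = _stencil(float(dc))
        out.append((fr, fc,
                    (1 - ar) * (1 - ac), (1 - ar) * ac,
                    ar * (1 - ac), ar * ac))
    return tuple(out)


def sample_neighbors(gray: GrayImage, center: tuple[int, int],
                     cfg: LBPConfig) -> LBPNeighborhood:
    """Bilinearly sample the P circular neighbours of one pixel."""
    r, c = center
    G = gray.intensities
    b = cfg.border
    H, W = G.shape
    if not (b <= r < H - b and b <= c < W - b):
        raise ValueError(
            f"center {center} closer than ceil(R)={b} to the border of {G.shape}"
        )
    vals = np.empty(cfg.P)
    for p, (fr, fc, w00, w01, w10, w11) in enumerate(_stencils(cfg.P, cfg.R)):
        r0, c0 = r + fr, c + fc
        v = w00 * G[r0, c0]
        if w01:
            v += w01 * G[r0, c0 + 1]
        if w10:
            v += w10 * G[r0 + 1, c0]
        if w11:
            v += w11 * G[r0 + 1, c0 + 1]
        vals[p] = v
    return LBPNeighborhood(g_c=float(G[r, c]), g_p=vals)


def lbp_code(nb: LBPNeighborhood) -> int:
    """Raw decimal LBP code: sum_p s(g_p - g_c) 2^p."""
    P = nb.g_p.size
    if P > 62:
        raise ValueError("raw codes only enumerable for small P")
    code = 0
    for p in range(P):
        if nb.g_p[p] >= nb.g_c:
            code += 1 << p
    return code


def uniform_bin(bits) -> int:
    """Uniform-pattern bin of a circular 0/1 sequence.

    Patterns with <= 2 circular transitions map to their count of ones
    (0..P); every other pattern maps to the shared bin P+1.
    """
    bits = np.asarray(bits, dtype=np.int64).ravel()
    P = bits.size
    transitions = int(np.count_nonzero(bits != np.roll(bits, 1)))
    if transitions <= 2:
        return int(bits.sum())
    return P + 1


def lbp_code_map(gray: GrayImage, cfg: LBPConfig) -> LBPCodeMap:
    """Vectorised LBP codes for every valid (border-excluded) pixel.

    Streams over the P neighbours keeping only running accumulators
    (ones count, circular transition count, raw code) so memory stays at a
    few valid-region planes even at P = 1278.
    """
    G = gray.intensities
    b = cfg.border
    H, W = G.shape
    if H <= 2 * b or W <= 2 * b:
        raise ValueError(
            f"image {G.shape} too small for any valid center at R={cfg.R}"
        )
    h, w = H - 2 * b, W - 2 * b
    Gc = G[b:H - b, b:W - b]

    raw = cfg.mode == "raw"
    if raw:
        code = np.zeros((h, w), dtype=np.int64)
    else:
        ones = np.zeros((h, w), dtype=np.int64)
        trans = np.zeros((h, w), dtype=np.int64)
        first = prev = None

    for p, (fr, fc, w00, w01, w10, w11) in enumerate(_stencils(cfg.P, cfg.R)):
        r0, c0 = b + fr, b + fc
        # interpolate the *difference* g_p - g_c: the sign threshold depends
        # only on differences, and this keeps constant patches exactly tied
        # (weights need not sum to 1 bit-exactly)
        diff = w00 * (G[r0:r0 + h, c0:c0 + w] - Gc)
        if w01:
            diff += w01 * (G[r0:r0 + h, c0 + 1:c0 + 1 + w] - Gc)
        if w10:
            diff += w10 * (G[r0 + 1:r0 + 1 + h, c0:c0 + w] - Gc)
        if w11:
            diff += w11 * (G[r0 + 1:r0 + 1 + h, c0 + 1:c0 + 1 + w] - Gc)
        bit = diff >= 0.0
        if raw:
            code += bit.astype(np.int64) << p
        else:
            ones += bit
            if p == 0:
                first = bit
            else:
                trans += bit != prev
            prev = bit

    if raw:
        return LBPCodeMap(codes=code, n_bins=cfg.n_bins)
    trans += prev != first  # circular wrap-around transition
    codes = np.where(trans <= 2, ones, cfg.P + 1)
    return LBPCodeMap(codes=codes, n_bins=cfg.n_bins)


def lbp_feature_vector(gray: GrayImage, cfg: LBPConfig) -> FeatureBlock:
    """Histogram of LBP codes over the valid region as the textural block.

    Normalised to sum 1 by default; dimension P+2 (uniform) or 2^P (raw).
    """
    cmap = lbp_code_map(gray, cfg)
    hist = np.bincount(cmap.codes.ravel(), minlength=cmap.n_bins)
    hist = hist.astype(np.float64)
    if cfg.normalize:
        hist /= hist.sum()
    return FeatureBlock(name="textural", values=hist)
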