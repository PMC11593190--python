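"""From-scratch vision-transformer (ViT) encoder for contextual features.

The tile is cut into non-overlapping ``patch_size x patch_size`` patches
(16 px at defaults, so a 224x224 tile yields 14x14 = 196 patch tokens),
each flattened, linearly projected to the embedding dimension d and summed
with a positional encoding.  The token matrix then passes through n_layers
pre-norm transformer encoder layers:

    x <- x + MHA(LN(x));   x <- x + MLP(LN(x))

where multi-head self-attention concatenates h scaled dot-product heads

    head_i = softmax(Q W_Q^i (K W_K^i)^T / sqrt(d_k)) V W_V^i,  d_k = d/h,

and projects the concatenation by W_o.  The MLP is two linear maps with an
exact GELU between them.  Defaults follow ViT-Base/16 (d=768, h=12,
12 layers, MLP 3072), so the final per-token matrix is 196 x 768 and the
flattened contextual block has 150,528 entries.  No class token is used:
the contextual block is exactly the patch tokens.

Weights come either from a seeded scaled-normal initialisation (fixed
sinusoidal positional table; fully deterministic, used for all automated
runs) or from a user-supplied pretrained parameter bundle with the same
shapes (learned positional table).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .fusion_matrix import FeatureBlock
from .imageio_preproc import ImageTile

LN_EPS = 1e-6


@dataclass(frozen=True)
class ViTConfig:
    """Encoder geometry and weight source.

    ``weight_source`` is an integer seed for the scaled-normal random
    initialisation, or a :class:`ViTParams` bundle for pretrained weights.
    ``positional`` selects the positional table: ``sinusoidal`` (default
    for seeded runs) or ``zero`` (disables position information; useful to
    exercise permutation equivariance).
    """

    patch_size: int = 16
    embed_dim: int = 768
    n_heads: int = 12
    n_layers: int = 12
    mlp_dim: int = 3072
    weight_source: object = 0
    positional: str = "sinusoidal"

    def __post_init__(self) -> None:
        if self.embed_dim % self.n_heads != 0:
            raise ValueError(
                f"embed_dim {self.embed_dim} not divisible by n_heads {self.n_heads}"
            )
        if self.positional not in ("sinusoidal", "zero", "learned"):
            raise ValueError(f"unknown positional mode {self.positional!r}")

    @property
    def d_k(self) -> int:
        return self.embed_dim // self.n_heads

    def n_tokens(self, side: int) -> int:
        if side % self.patch_size != 0:
            raise ValueError(
                f"image side {side} not divisible by patch size {self.patch_size}"
            )
        return (side // self.patch_size) ** 2


@dataclass
class LayerParams:
    """One encoder layer: attention projections, MLP and layer norms."""

    Wq: np.ndarray
    Wk: np.ndarray
    Wv: np.ndarray
    Wo: np.ndarray
    ln1_g: np.ndarray
    ln1_b: np.ndarray
    ln2_g: np.ndarray
    ln2_b: np.ndarray
    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray


@dataclass
class ViTParams:
    """Full encoder parameter bundle."""

    patch_proj: np.ndarray   # (patch_size^2 * 3, d)
    positions: np.ndarray    # (n_tokens, d)
    layers: list[LayerParams]


def patchify(tile: ImageTile | np.ndarray, patch_size: int) -> np.ndarray:
    """Cut a tile into flattened non-overlapping patches.

    Patches are ordered row-major over the patch grid; each patch row is
    the patch's pixels flattened row-major with the channel axis last, so a
    224x224x3 tile at patch size 16 gives a 196 x 768 raw patch matrix.
    """
    px = tile.pixels if isinstance(tile, ImageTile) else np.asarray(tile)
    if px.ndim != 3:
        raise ValueError(f"expected HxWxC pixels, got shape {px.shape}")
    H, W, C = px.shape
    if H % patch_size or W % patch_size:
        raise ValueError(
            f"image {H}x{W} not divisible by patch size {patch_size}"
        )
    gh, gw = H // patch_size, W // patch_size
    patches = (px.reshape(gh, patch_size, gw, patch_size, C)
                 .transpose(0, 2, 1, 3, 4)
                 .reshape(gh * gw, patch_size * patch_size * C))
    return np.asarray(patches, dtype=np.float64)


def softmax_rows(M: np.ndarray) -> np.ndarray:
    """Row-wise softmax with max-subtraction stabilisation."""
    M = np.asarray(M, dtype=np.float64)
    Z = np.exp(M - M.max(axis=-1, keepdims=True))
    return Z / Z.sum(axis=-1, keepdims=True)


def attention(Q: np.ndarray, K: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Scaled dot-product attention: softmax(Q K^T / sqrt(d_k)) V."""
    Q, K, V = (np.asarray(a, dtype=np.float64) for a in (Q, K, V))
    if Q.shape[-1] != K.shape[-1]:
        raise ValueError("Q and K must share their feature dimension d_k")
    if K.shape[0] != V.shape[0]:
        raise ValueError("K and V must have the same number of rows")
    d_k = Q.shape[-1]
    weights = softmax_rows(Q @ K.T / np.sqrt(d_k))
    return weights @ V


def multi_head_attention(tokens: np.ndarray, params: LayerParams,
                         h: int) -> np.ndarray:
    """Self-attention over tokens with h parallel heads.

    The per-head projections W_Q^i, W_K^i, W_V^i are the i-th d_k-column
    blocks of the full (d, d) matrices; head outputs are concatenated
    column-wise and projected by W_o.
    """
    X = np.asarray(tokens, dtype=np.float64)
    d = X.shape[1]
    if d % h != 0:
        raise ValueError(f"token dim {d} not divisible by n_heads {h}")
    d_k = d // h
    Q, K, V = X @ params.Wq, X @ params.Wk, X @ params.Wv
    heads = [
        attention(Q[:, i * d_k:(i + 1) * d_k],
                  K[:, i * d_k:(i + 1) * d_k],
                  V[:, i * d_k:(i + 1) * d_k])
        for i in range(h)
    ]
    return np.concatenate(heads, axis=1) @ params.Wo


def layer_norm(x: np.ndarray, gamma: np.ndarray, beta: np.ndarray,
               eps: float = LN_EPS) -> np.ndarray:
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    return gamma * (x - mu) / np.sqrt(var + eps) + beta


def gelu(x: np.ndarray) -> np.ndarray:
    """Exact Gaussian-error-linear unit: x * Phi(x)."""
    return 0.5 * x * (1.0 + erf(x / np.sqrt(2.0)))


def encoder_layer(tokens: np.ndarray, params: LayerParams,
                  n_heads: int) -> np.ndarray:
    """One pre-norm residual encoder layer (MHA then MLP sub-blocks)."""
    x = np.asarray(tokens, dtype=np.float64)
    x = x + multi_head_attention(layer_norm(x, params.ln1_g, params.ln1_b),
                                 params, n_heads)
    y = layer_norm(x, params.ln2_g, params.ln2_b)
    y = gelu(y @ params.W1 + params.b1) @ params.W2 + params.b2
    return x + y


def sinusoidal_positions(n_tokens: int, d: int) -> np.ndarray:
    """Fixed sine/cosine positional table (token index x embedding dim)."""
    pos = np.arange(n_tokens)[:, None]
    i = np.arange(d // 2)[None, :]
    angles = pos / np.power(10000.0, 2.0 * i / d)
    table = np.zeros((n_tokens, d))
    table[:, 0::2] = np.sin(angles)
    table[:, 1::2] = np.cos(angles[:, : d - d // 2])
    return table


def init_params(cfg: ViTConfig, n_tokens: int, seed: int) -> ViTParams:
    """Seeded scaled-normal initialisation of the full parameter bundle.

    Projection weights ~ N(0, 0.02^2); layer-norm gains 1, shifts 0; MLP
    biases 0.  The positional table follows ``cfg.positional``.
    """
    rng = np.random.default_rng(seed)
    d, m = cfg.embed_dim, cfg.mlp_dim
    in_dim = cfg.patch_size ** 2 * 3

    def W(*shape):
        return rng.normal(0.0, 0.02, size=shape)

    patch_proj = rng.normal(0.0, 1.0 / np.sqrt(in_dim), size=(in_dim, d))
    if cfg.positional == "zero":
        positions = np.zeros((n_tokens, d))
    else:
        positions = sinusoidal_positions(n_tokens, d)
    layers = [
        LayerParams(
            Wq=W(d, d), Wk=W(d, d), Wv=W(d, d), Wo=W(d, d),
            ln1_g=np.ones(d), ln1_b=np.zeros(d),
            ln2_g=np.ones(d), ln2_b=np.zeros(d),
            W1=W(d, m), b1=np.zeros(m),
            W2=W(m, d), b2=np.zeros(d),
        )
        for _ in range(cfg.n_layers)
    ]
    return ViTParams(patch_proj=patch_proj, positions=positions, layers=layers)


def resolve_params(cfg: ViTConfig, n_tokens: int) -> ViTParams:
    if isinstance(cfg.weight_source, ViTParams):
        return cfg.weight_source
    return init_params(cfg, n_tokens, int(cfg.weight_source))


def encode_tokens(tile: ImageTile | np.ndarray, cfg: ViTConfig) -> np.ndarray:
    """Run the full encoder; returns the n_tokens x d token matrix."""
    px = tile.pixels if isinstance(tile, ImageTile) else np.asarray(tile)
    side = px.shape[0]
    n_tokens = cfg.n_tokens(side)
    params = resolve_params(cfg, n_tokens)
    raw = patchify(px, cfg.patch_size) / 255.0  # pixel scaling to [0, 1]
    x = raw @ params.patch_proj + params.positions
    for lp in params.layers:
        x = encoder_layer(x, lp, cfg.n_heads)
    return x


def vit_encode(tile: ImageTile, cfg: ViTConfig) -> FeatureBlock:
    """Contextual feature block: encoder tokens flattened row-major.

    At defaults the 196 x 768 token matrix flattens to 150,528 values.
    """
    tokens = encode_tokens(tile, cfg)
    return FeatureBlock(name="contextual", values=tokens.ravel())
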