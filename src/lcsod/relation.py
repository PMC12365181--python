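"""Pairwise box-geometry relation encoding and relation-biased attention.

The relation pathway turns each ordered pair of boxes (a, b), given in
center convention with positive width/height, into a 4-vector of relative
geometry features

    e(Ba, Bb) = [ log(|xa-xb|/wa + 1), log(|ya-yb|/ha + 1),
                  log(wa/wb),          log(ha/hb) ]

which is invariant under uniform rescaling of all coordinates. Each scalar
feature is expanded with a sine/cosine embedding of dimension ``d``
(wavelength base ``T``, argument scale ``s``):

    embed[2k]   = sin(s * e / T^(2k/d)),
    embed[2k+1] = cos(s * e / T^(2k/d)),   k = 0..d/2-1,

giving an N x N x 4d array. A learned linear map ``W`` (4d -> M heads) plus
offset ``A``, clamped from below at ``eps`` to keep every entry positive (and
its gradient alive), yields one scalar bias per attention head and ordered
pair; that bias is added to the pre-softmax self-attention logits.

Public functions take and return numpy arrays; the differentiable variants
(suffix ``_t``) operate on autodiff tensors and are what the detector uses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, softmax as _softmax_t
from .errors import ConfigurationError, DegenerateBoxError


@dataclass
class RelationParams:
    """Hyper-parameters of the relation encoder.

    ``T``, ``d``, ``s`` default to 10000, 16 and 100; ``M`` attention heads
    default to 8; ``eps`` is the positive clamp floor.
    """

    T: float = 10000.0
    d: int = 16
    s: float = 100.0
    M: int = 8
    eps: float = 1e-6

    def __post_init__(self) -> None:
        if self.d % 2 != 0 or self.d < 2:
            raise ConfigurationError(f"embedding dim d must be even and >= 2, got {self.d}")
        if self.eps <= 0:
            raise ConfigurationError(f"eps must be > 0, got {self.eps}")
        if self.T <= 1:
            raise ConfigurationError(f"wavelength base T must be > 1, got {self.T}")
        if self.M < 1:
            raise ConfigurationError(f"head count M must be >= 1, got {self.M}")

    @property
    def embed_dim(self) -> int:
        return 4 * self.d


def geometry_features(boxes_a: np.ndarray, boxes_b: np.ndarray) -> np.ndarray:
    """Pairwise geometry features, ``(Na, Nb, 4)``.

    ``boxes_a``/``boxes_b`` are ``(N, 4)`` arrays in center convention
    ``[cx, cy, w, h]`` (absolute or normalized — the features are
    scale-invariant either way). Entry ``[i, j]`` is ``e(Ba_i, Bb_j)``.
    """
    a = np.atleast_2d(np.asarray(boxes_a, dtype=float))
    b = np.atleast_2d(np.asarray(boxes_b, dtype=float))
    if np.any(a[:, 2:] <= 0) or np.any(b[:, 2:] <= 0):
        raise DegenerateBoxError("geometry features require positive width/height")
    dx = np.abs(a[:, None, 0] - b[None, :, 0])
    dy = np.abs(a[:, None, 1] - b[None, :, 1])
    wa, ha = a[:, 2][:, None], a[:, 3][:, None]
    return np.stack(
        [
            np.log(dx / wa + 1.0),
            np.log(dy / ha + 1.0),
            np.log(wa / b[None, :, 2]),
            np.log(ha / b[None, :, 3]),
        ],
        axis=-1,
    )


def sinusoidal_embed(features: np.ndarray, params: RelationParams | None = None) -> np.ndarray:
    """Sine/cosine-expand each scalar feature to ``d`` dimensions.

    Input ``(..., F)`` -> output ``(..., F * d)`` with the layout
    ``[feat0 sin/cos interleaved, feat1 sin/cos interleaved, ...]``.
    """
    params = params or RelationParams()
    e = np.asarray(features, dtype=float)
    k = np.arange(params.d // 2)
    inv_freq = params.s / params.T ** (2.0 * k / params.d)  # (d/2,)
    angles = e[..., None] * inv_freq  # (..., F, d/2)
    out = np.empty(angles.shape[:-1] + (params.d,), dtype=float)
    out[..., 0::2] = np.sin(angles)
    out[..., 1::2] = np.cos(angles)
    return out.reshape(e.shape[:-1] + (e.shape[-1] * params.d,))


def relation_head_t(embedded: np.ndarray, W: Tensor, A: Tensor,
                    eps: float) -> Tensor:
    """Differentiable ``max(eps, embedded @ W + A)``; output ``(..., M)``."""
    emb = Tensor(np.asarray(embedded, dtype=float))
    if W.shape[0] != emb.shape[-1]:
        raise ConfigurationError(
            f"relation W expects input dim {W.shape[0]}, embedding has {emb.shape[-1]}")
    return (emb @ W + A).maximum(eps)


def relation_head(embedded: np.ndarray, W: np.ndarray, A: np.ndarray,
                  params: RelationParams | None = None) -> np.ndarray:
    """Per-head relation bias ``max(eps, W . Embed + A)``, shape ``(N, N, M)``.

    Every entry is >= ``eps`` by construction.
    """
    params = params or RelationParams()
    out = relation_head_t(embedded, Tensor(W), Tensor(A), params.eps)
    return out.data


def _multi_head_attention_t(
    q: Tensor, k: Tensor, v: Tensor, out_proj: Tensor,
    n_heads: int, bias: Tensor | np.ndarray | None = None,
) -> tuple[Tensor, Tensor]:
    """Shared core of plain and relation-biased self-attention.

    ``q``/``k``/``v``: (N, d_model) projected tensors; ``bias``: (M, N, N)
    added to the logits. Returns (output (N, d_model), attention (M, N, N)).
    """
    n, d_model = q.shape
    if d_model % n_heads:
        raise ConfigurationError(f"d_model {d_model} not divisible by {n_heads} heads")
    d_head = d_model // n_heads

    def split(x: Tensor) -> Tensor:  # (N, d_model) -> (M, N, d_head)
        return x.reshape(n, n_heads, d_head).transpose(1, 0, 2)

    qh, kh, vh = split(q), split(k), split(v)
    logits = (qh @ kh.transpose(0, 2, 1)) / np.sqrt(d_model)
    if bias is not None:
        logits = logits + (bias if isinstance(bias, Tensor) else Tensor(bias))
    attn = _softmax_t(logits, axis=-1)
    out = (attn @ vh).transpose(1, 0, 2).reshape(n, d_model)
    return out @ out_proj, attn


@dataclass
class AttentionWeights:
    """Projection matrices of one self-attention block (no biases), used by
    the functional attention entry points below."""

    wq: np.ndarray
    wk: np.ndarray
    wv: np.ndarray
    wo: np.ndarray

    @staticmethod
    def random(rng: np.random.Generator, d_model: int) -> "AttentionWeights":
        scale = 1.0 / np.sqrt(d_model)
        return AttentionWeights(
            *(rng.normal(0.0, scale, (d_model, d_model)) for _ in range(4)))


def relation_attention(
    queries: np.ndarray, bias: np.ndarray, weights: AttentionWeights,
    n_heads: int | None = None, return_attn: bool = False,
):
    """Relation-biased multi-head self-attention over one query set.

    ``queries``: (N, d_model); ``bias``: (N, N, M) per-head relation bias,
    added to the scaled dot-product logits before the softmax.
    """
    bias = np.asarray(bias, dtype=float)
    n_heads = n_heads if n_heads is not None else bias.shape[-1]
    q = Tensor(np.asarray(queries, dtype=float))
    if bias.shape[0] != q.shape[0] or bias.shape[1] != q.shape[0]:
        raise ConfigurationError(
            f"bias shape {bias.shape} incompatible with {q.shape[0]} queries")
    if bias.shape[-1] != n_heads:
        raise ConfigurationError(
            f"bias has {bias.shape[-1]} heads, attention expects {n_heads}")
    out, attn = _multi_head_attention_t(
        q @ Tensor(weights.wq), q @ Tensor(weights.wk), q @ Tensor(weights.wv),
        Tensor(weights.wo), n_heads, bias=bias.transpose(2, 0, 1))
    if return_attn:
        return out.data, attn.data
    return out.data


def plain_attention(
    queries: np.ndarray, weights: AttentionWeights, n_heads: int = 8,
    return_attn: bool = False,
):
    """Standard scaled dot-product multi-head self-attention (zero bias)."""
    q = Tensor(np.asarray(queries, dtype=float))
    out, attn = _multi_head_attention_t(
        q @ Tensor(weights.wq), q @ Tensor(weights.wk), q @ Tensor(weights.wv),
        Tensor(weights.wo), n_heads, bias=None)
    if return_attn:
        return out.data, attn.data
    return out.data


def relation_bias_matrix(
    boxes_prev: np.ndarray, boxes_cur: np.ndarray,
    W: np.ndarray | Tensor, A: np.ndarray | Tensor,
    params: RelationParams | None = None,
):
    """Full pipeline: boxes -> geometry -> embedding -> clamped per-head bias.

    ``boxes_prev`` provides the row (target) boxes and ``boxes_cur`` the
    column (source) boxes, matching the layer rule of using the two most
    recent box sets. Returns ``(N, N, M)``; a Tensor when W/A are Tensors.
    """
    params = params or RelationParams()
    emb = sinusoidal_embed(geometry_features(boxes_prev, boxes_cur), params)
    if isinstance(W, Tensor) or isinstance(A, Tensor):
        Wt = W if isinstance(W, Tensor) else Tensor(W)
        At = A if isinstance(A, Tensor) else Tensor(A)
        return relation_head_t(emb, Wt, At, params.eps)
    return relation_head(emb, W, A, params)
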