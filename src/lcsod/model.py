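"""A desk-scale relation-biased detection transformer.

Architecture: a 3-block strided convolutional backbone turns an RGB image
into a single grid of feature tokens with 2-D sine positional encoding; a
small transformer encoder produces the memory; class/box heads on the memory
score every token and the top-scoring tokens seed each query stream
(two-stage selection: the query content is a learned embedding plus a
projection of the selected token, the token's predicted box is the initial
reference box B_0). Two parallel decoder streams share all decoder weights:

* matching queries — self-attention biased per head by the clamped pairwise
  box-relation term computed from the two most recent box sets
  (``relation(B_{l-1}, B_l)``, with ``relation(B_0, B_0)`` at the first
  layer); trained with one-to-one Hungarian assignment and used at inference;
* hybrid queries — plain self-attention, trained with one-to-K (repeated
  ground truth) assignment, discarded at inference.

Each decoder layer predicts center-normalized boxes in [0,1] and per-class
sigmoid logits (a background column is trained but ignored at inference).
By default the box head refines the running reference box in logit space,
``sigmoid(MLP(Q) + logit(ref))``; ``ModelConfig.box_delta=False`` switches
to absolute sigmoid regression from the query alone. Relation bias is
computed from stop-gradient box coordinates, so the relation parameters W
and A learn through the linear map and clamp while the bias stays a
geometry prior.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .autodiff import (
    Adam,
    LayerNorm,
    Linear,
    MLP,
    Module,
    Parameter,
    Tensor,
    conv2d,
    softmax,
)
from .coco import (
    CENTER_NORMALIZED,
    CORNER_ABSOLUTE,
    BoundingBox,
    PredictionRecord,
    PredictionSet,
    convert_box,
)
from .errors import ConfigurationError
from .relation import RelationParams, geometry_features, sinusoidal_embed


@dataclass
class ModelConfig:
    """Detector hyper-parameters. Mini defaults fit one CPU; the full-scale
    preset mirrors the published configuration of the original system."""

    n_classes: int
    d_model: int = 64
    n_heads: int = 8
    n_encoder_layers: int = 2
    n_decoder_layers: int = 2
    n_matching_queries: int = 20
    n_hybrid_candidates: int = 40
    k: int = 6  # ground-truth repeat factor for the hybrid stream
    ffn_dim: int = 128
    image_size: int = 64
    # decoder box parameterization: refine the running reference box in logit
    # space (True) or regress absolute sigmoid boxes from the query (False)
    box_delta: bool = True
    relation: RelationParams = field(default_factory=RelationParams)

    def __post_init__(self) -> None:
        if isinstance(self.relation, dict):
            self.relation = RelationParams(**self.relation)
        if self.d_model % self.n_heads != 0:
            raise ConfigurationError(
                f"d_model {self.d_model} not divisible by n_heads {self.n_heads}")
        for name in ("n_classes", "d_model", "n_heads", "n_encoder_layers",
                     "n_decoder_layers", "n_matching_queries",
                     "n_hybrid_candidates", "k", "ffn_dim", "image_size"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.relation.M != self.n_heads:
            raise ConfigurationError(
                f"relation head count {self.relation.M} != n_heads {self.n_heads}")

    @staticmethod
    def mini(n_classes: int) -> "ModelConfig":
        return ModelConfig(n_classes=n_classes)

    @staticmethod
    def full_scale(n_classes: int) -> "ModelConfig":
        return ModelConfig(
            n_classes=n_classes, d_model=256, n_heads=8,
            n_encoder_layers=6, n_decoder_layers=6,
            n_matching_queries=900, n_hybrid_candidates=1500, k=6,
            ffn_dim=2048, image_size=256)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class LayerOutput:
    """One decoder layer's output for one stream (batched)."""

    queries: Tensor  # (B, N, d_model)
    boxes: Tensor  # (B, N, 4) center-normalized in [0,1]
    class_logits: Tensor  # (B, N, n_classes + 1)


def sine_position_encoding(h: int, w: int, d_model: int) -> np.ndarray:
    """Fixed 2-D sine/cosine token position encoding, ``(h*w, d_model)``."""
    d_half = d_model // 2
    k = np.arange(d_half // 2)
    inv = 1.0 / (10000.0 ** (2.0 * k / d_half))
    ys, xs = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")

    def encode(coord: np.ndarray) -> np.ndarray:
        ang = coord.reshape(-1)[:, None] * inv
        out = np.empty((coord.size, d_half))
        out[:, 0::2] = np.sin(ang)
        out[:, 1::2] = np.cos(ang)
        return out

    return np.concatenate([encode(ys), encode(xs)], axis=-1)


class _Attention(Module):
    """Batched multi-head attention with optional per-head additive bias.

    Logits are scaled by 1/sqrt(d_model), matching the relation-biased
    self-attention formula used throughout the package.
    """

    def __init__(self, rng: np.random.Generator, d_model: int, n_heads: int):
        self.q = Linear(rng, d_model, d_model)
        self.k = Linear(rng, d_model, d_model)
        self.v = Linear(rng, d_model, d_model)
        self.o = Linear(rng, d_model, d_model)
        self.n_heads = n_heads
        self.d_model = d_model

    def __call__(self, query: Tensor, key: Tensor, value: Tensor,
                 bias: Tensor | None = None) -> Tensor:
        b, nq, d = query.shape
        nk = key.shape[1]
        m = self.n_heads
        dh = d // m

        def split(x: Tensor, n: int) -> Tensor:
            return x.reshape(b, n, m, dh).transpose(0, 2, 1, 3)

        qh = split(self.q(query), nq)
        kh = split(self.k(key), nk)
        vh = split(self.v(value), nk)
        logits = (qh @ kh.transpose(0, 1, 3, 2)) / np.sqrt(self.d_model)
        if bias is not None:
            logits = logits + bias  # (B, M, Nq, Nk)
        attn = softmax(logits, axis=-1)
        out = (attn @ vh).transpose(0, 2, 1, 3).reshape(b, nq, d)
        return self.o(out)


class _FFN(Module):
    def __init__(self, rng: np.random.Generator, d_model: int, ffn_dim: int):
        self.lin1 = Linear(rng, d_model, ffn_dim)
        self.lin2 = Linear(rng, ffn_dim, d_model)

    def __call__(self, x: Tensor) -> Tensor:
        return self.lin2(self.lin1(x).relu())


class _EncoderLayer(Module):
    def __init__(self, rng: np.random.Generator, cfg: ModelConfig):
        self.attn = _Attention(rng, cfg.d_model, cfg.n_heads)
        self.ffn = _FFN(rng, cfg.d_model, cfg.ffn_dim)
        self.ln1 = LayerNorm(cfg.d_model)
        self.ln2 = LayerNorm(cfg.d_model)

    def __call__(self, x: Tensor) -> Tensor:
        t = self.ln1(x)
        x = x + self.attn(t, t, t)
        return x + self.ffn(self.ln2(x))


class _DecoderLayer(Module):
    def __init__(self, rng: np.random.Generator, cfg: ModelConfig):
        self.self_attn = _Attention(rng, cfg.d_model, cfg.n_heads)
        self.cross_attn = _Attention(rng, cfg.d_model, cfg.n_heads)
        self.ffn = _FFN(rng, cfg.d_model, cfg.ffn_dim)
        self.ln1 = LayerNorm(cfg.d_model)
        self.ln2 = LayerNorm(cfg.d_model)
        self.ln3 = LayerNorm(cfg.d_model)

    def __call__(self, q: Tensor, memory: Tensor,
                 bias: Tensor | None) -> Tensor:
        t = self.ln1(q)
        q = q + self.self_attn(t, t, t, bias=bias)
        q = q + self.cross_attn(self.ln2(q), memory, memory)
        return q + self.ffn(self.ln3(q))


class _Conv(Module):
    def __init__(self, rng: np.random.Generator, c_in: int, c_out: int):
        fan_in, fan_out = c_in * 9, c_out * 9
        bound = np.sqrt(6.0 / (fan_in + fan_out))
        self.weight = Parameter(rng.uniform(-bound, bound, (c_out, c_in, 3, 3)))
        self.bias = Parameter(np.zeros(c_out))

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=2, padding=1)


class RelationDetector(Module):
    """The full mini detector; see the module docstring for the layout."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        cfg = config
        self.config = cfg
        d = cfg.d_model
        self.conv1 = _Conv(rng, 3, max(16, d // 4))
        self.conv2 = _Conv(rng, max(16, d // 4), max(32, d // 2))
        self.conv3 = _Conv(rng, max(32, d // 2), d)
        self.backbone_ln = LayerNorm(d)
        self.encoder_layers = [_EncoderLayer(rng, cfg)
                               for _ in range(cfg.n_encoder_layers)]
        self.memory_ln = LayerNorm(d)
        # encoder-side proposal heads (two-stage selection)
        self.enc_class_head = Linear(rng, d, cfg.n_classes + 1)
        self.enc_box_head = MLP(rng, [d, d, 4])
        self.query_proj = Linear(rng, d, d)
        self.match_query_embed = Parameter(rng.normal(0.0, 1.0,
                                                      (cfg.n_matching_queries, d)))
        self.hybrid_query_embed = Parameter(rng.normal(0.0, 1.0,
                                                       (cfg.n_hybrid_candidates, d)))
        self.decoder_layers = [_DecoderLayer(rng, cfg)
                               for _ in range(cfg.n_decoder_layers)]
        self.out_ln = LayerNorm(d)
        self.class_head = Linear(rng, d, cfg.n_classes + 1)
        self.box_head = MLP(rng, [d, d, 4])
        # zero-init box-head outputs (layers start as identity refinements of
        # their reference boxes) and bias object logits toward the focal
        # prior so early training is not swamped by negatives
        for head in (self.enc_box_head, self.box_head):
            head.layers[-1].weight.data[:] = 0.0
            head.layers[-1].bias.data[:] = 0.0
        for head in (self.enc_class_head, self.class_head):
            head.bias.data[:cfg.n_classes] = -3.0
        # relation parameters: near-neutral start (small W, offset at eps)
        rp = cfg.relation
        self.relation_W = Parameter(rng.uniform(-1e-3, 1e-3, (rp.embed_dim, rp.M)))
        self.relation_A = Parameter(np.full(rp.M, rp.eps))
        # token grid side after three stride-2 convs
        self.grid = cfg.image_size // 8
        self.pos_encoding = sine_position_encoding(self.grid, self.grid, d)
        # per-token anchor logits: proposal boxes are predicted as offsets
        # from each token's own grid cell (center at the cell, size ~1.5 cells)
        g = self.grid
        ys, xs = np.meshgrid(np.arange(g), np.arange(g), indexing="ij")
        cx = (xs.reshape(-1) + 0.5) / g
        cy = (ys.reshape(-1) + 0.5) / g
        wh = np.full(g * g, 1.5 / g)
        self.anchor_logits = np.log(np.stack(
            [cx, cy, wh, wh], axis=-1) / (1.0 - np.stack([cx, cy, wh, wh], axis=-1)))

    # -- encoder -------------------------------------------------------
    def encode(self, images: np.ndarray) -> Tensor:
        """Images ``(B, H, W, 3)`` uint8/float -> memory ``(B, N_tokens, d)``."""
        x = np.asarray(images, dtype=np.float64)
        if x.max() > 1.5:
            x = x / 255.0
        x = Tensor((x - 0.5).transpose(0, 3, 1, 2))
        h = conv2d(x, self.conv1.weight, self.conv1.bias, 2, 1).relu()
        h = conv2d(h, self.conv2.weight, self.conv2.bias, 2, 1).relu()
        h = conv2d(h, self.conv3.weight, self.conv3.bias, 2, 1)
        b = h.shape[0]
        tokens = h.reshape(b, self.config.d_model, self.grid * self.grid) \
            .transpose(0, 2, 1)
        tokens = self.backbone_ln(tokens) + self.pos_encoding
        for layer in self.encoder_layers:
            tokens = layer(tokens)
        return self.memory_ln(tokens)

    # -- relation bias -------------------------------------------------
    def relation_bias(self, boxes_prev: np.ndarray,
                      boxes_cur: np.ndarray) -> Tensor:
        """Per-head bias ``(B, M, N, N)`` from two batched box sets
        (stop-gradient numpy arrays, center-normalized)."""
        rp = self.config.relation
        emb = np.stack([
            sinusoidal_embed(geometry_features(bp, bc), rp)
            for bp, bc in zip(boxes_prev, boxes_cur)
        ])  # (B, N, N, 4d)
        bias = (Tensor(emb) @ self.relation_W + self.relation_A).maximum(rp.eps)
        return bias.transpose(0, 3, 1, 2)

    # -- proposals -----------------------------------------------------
    def _proposals(self, memory: Tensor) -> tuple[Tensor, Tensor]:
        logits = self.enc_class_head(memory)  # (B, N_tok, C+1)
        boxes = (self.enc_box_head(memory) + self.anchor_logits).sigmoid()
        return logits, boxes  # (B, N_tok, 4)

    def _select_stream(self, memory: Tensor, enc_logits: Tensor,
                       enc_boxes: Tensor, n_queries: int,
                       query_embed: Parameter) -> tuple[Tensor, np.ndarray]:
        """Top-k token selection -> (initial queries (B,N,d), B_0 (B,N,4))."""
        b = memory.shape[0]
        scores = 1.0 / (1.0 + np.exp(-enc_logits.data[..., :self.config.n_classes]))
        token_score = scores.max(axis=-1)  # (B, N_tok)
        top = np.argsort(-token_score, axis=-1, kind="stable")[:, :n_queries]
        batch_idx = np.arange(b)[:, None]
        content = self.query_proj(memory[batch_idx, top])
        q0 = content + query_embed
        b0 = enc_boxes.data[batch_idx, top]  # stop-gradient reference boxes
        return q0, b0

    # -- decoder -------------------------------------------------------
    def _box_from_query(self, t: Tensor, reference: np.ndarray) -> Tensor:
        if not self.config.box_delta:
            return self.box_head(t).sigmoid()
        ref = np.clip(reference, 1e-4, 1.0 - 1e-4)
        ref_logit = np.log(ref / (1.0 - ref))  # stop-gradient running reference
        return (self.box_head(t) + ref_logit).sigmoid()

    def _run_decoder(self, q: Tensor, memory: Tensor, b0: np.ndarray,
                     relation_biased: bool) -> list[LayerOutput]:
        eps = 1e-4  # keep reference boxes non-degenerate for the geometry log
        reference = np.clip(b0, eps, 1.0)
        history = [reference, reference]
        outputs: list[LayerOutput] = []
        for layer in self.decoder_layers:
            bias = None
            if relation_biased:
                bias = self.relation_bias(history[-2], history[-1])
            q = layer(q, memory, bias)
            t = self.out_ln(q)
            boxes = self._box_from_query(t, reference)
            logits = self.class_head(t)
            outputs.append(LayerOutput(queries=q, boxes=boxes, class_logits=logits))
            reference = np.clip(boxes.data, eps, 1.0)
            history.append(reference)
        return outputs

    def decode_layer(self, layer_index: int, q: Tensor, memory: Tensor,
                     boxes_prev: np.ndarray, boxes_cur: np.ndarray,
                     relation_biased: bool = True) -> LayerOutput:
        """Run a single decoder layer explicitly (analysis/testing hook)."""
        layer = self.decoder_layers[layer_index]
        bias = self.relation_bias(boxes_prev, boxes_cur) if relation_biased else None
        q = layer(q, memory, bias)
        t = self.out_ln(q)
        return LayerOutput(queries=q, boxes=self._box_from_query(t, boxes_cur),
                           class_logits=self.class_head(t))

    # -- public forward passes -----------------------------------------
    def forward_train(self, images: np.ndarray) -> dict:
        """Both streams, all layers, plus the encoder proposal outputs."""
        if len(images) == 0:
            return {"matching": [], "hybrid": [], "encoder": None}
        memory = self.encode(images)
        enc_logits, enc_boxes = self._proposals(memory)
        q_m, b0_m = self._select_stream(memory, enc_logits, enc_boxes,
                                        self.config.n_matching_queries,
                                        self.match_query_embed)
        q_h, b0_h = self._select_stream(memory, enc_logits, enc_boxes,
                                        self.config.n_hybrid_candidates,
                                        self.hybrid_query_embed)
        return {
            "matching": self._run_decoder(q_m, memory, b0_m, relation_biased=True),
            "hybrid": self._run_decoder(q_h, memory, b0_h, relation_biased=False),
            "encoder": (enc_logits, enc_boxes),
        }

    def forward_inference(self, images: np.ndarray) -> LayerOutput:
        """Final matching-stream layer only (hybrid queries are skipped)."""
        memory = self.encode(images)
        enc_logits, enc_boxes = self._proposals(memory)
        q_m, b0_m = self._select_stream(memory, enc_logits, enc_boxes,
                                        self.config.n_matching_queries,
                                        self.match_query_embed)
        return self._run_decoder(q_m, memory, b0_m, relation_biased=True)[-1]


def build_model(config: ModelConfig, seed: int = 0) -> RelationDetector:
    """Deterministically initialized detector for the given configuration."""
    return RelationDetector(config, seed=seed)


def predict(
    model: RelationDetector,
    images: np.ndarray | list[np.ndarray],
    image_ids: list[int],
    image_sizes: list[tuple[int, int]] | None = None,
    score_keep: int = 300,
    batch_size: int = 16,
) -> PredictionSet:
    """Inference on a list of images -> scored corner-absolute predictions.

    One record per matching query (best non-background class under the
    per-class sigmoid), then the top ``score_keep`` records per image.
    """
    records: list[PredictionRecord] = []
    n_classes = model.config.n_classes
    if len(image_ids) == 0:
        return PredictionSet(records=[])
    images = np.asarray(images)
    if image_sizes is None:
        image_sizes = [(im.shape[1], im.shape[0]) for im in images]
    for start in range(0, len(image_ids), batch_size):
        batch = images[start:start + batch_size]
        out = model.forward_inference(batch)
        probs = 1.0 / (1.0 + np.exp(-out.class_logits.data[..., :n_classes]))
        boxes = out.boxes.data
        for bi, image_id in enumerate(image_ids[start:start + batch_size]):
            iw, ih = image_sizes[start + bi]
            best_class = probs[bi].argmax(axis=-1)
            best_score = probs[bi].max(axis=-1)
            order = np.argsort(-best_score, kind="stable")[:score_keep]
            for qi in order:
                cx, cy, w, h = boxes[bi, qi]
                w = max(w, 1e-4)
                h = max(h, 1e-4)
                box = convert_box(
                    BoundingBox(cx, cy, w, h, CENTER_NORMALIZED),
                    CORNER_ABSOLUTE, (iw, ih))
                records.append(PredictionRecord(
                    image_id=int(image_id),
                    category_id=int(best_class[qi]) + 1,
                    box=box,
                    score=float(best_score[qi])))
    return PredictionSet(records=records)


# -- checkpointing ----------------------------------------------------------

def save_checkpoint(model: RelationDetector, path) -> None:
    """Single-file checkpoint: config JSON + parameter arrays (npz)."""
    params = {k: p.data for k, p in model.named_parameters().items()}
    cfg = json.dumps({"version": 1, "config": model.config.to_dict()})
    np.savez(path, __meta__=np.frombuffer(cfg.encode(), dtype=np.uint8), **params)


def load_checkpoint(path) -> RelationDetector:
    with np.load(path) as payload:
        meta = json.loads(bytes(payload["__meta__"]).decode())
        cfg_dict = meta["config"]
        cfg_dict["relation"] = RelationParams(**cfg_dict["relation"])
        model = RelationDetector(ModelConfig(**cfg_dict), seed=0)
        named = model.named_parameters()
        for key, param in named.items():
            param.data = np.asarray(payload[key], dtype=np.float64)
    return model
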