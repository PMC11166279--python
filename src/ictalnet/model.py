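"""The hybrid CNN / light multi-head self-attention seizure detector.

Architecture, front to back:

* **pre-CNN** — three 3x3 convolutions (16 maps each; strides 1, 1, 2), each
  followed by GELU, batch normalisation and dropout.  Extracts short-term
  local time-frequency patterns and halves the spatial extent.
* **two transformer stages**, stacked and alternating, each:
  an entry 3x3 stride-2 convolution raising depth to the stage dimension
  with layer normalisation, then a block of

  - *local perception unit* (LPU): ``X' = Conv3x3(X) + X`` — a residual
    convolution that replaces positional encoding while preserving
    translation invariance;
  - *light multi-head self-attention* (LMHSA): queries come from all
    ``L = H x W`` tokens, but keys and values from the ``L'`` tokens of a
    stride-2 depthwise-separable reduction of the map, shrinking the
    attention score matrix from ``L x L`` to ``L x L'`` (~4x fewer entries);
  - *residual feed-forward network* (RFFN): 1x1 conv (expand), depthwise
    3x3, 1x1 conv (project) with a skip connection.

* **fusion head** — global average pooling, a fully-connected layer to two
  logits, and log-softmax; the ictal probability is thresholded (default
  0.5, ties resolve to ictal).

Feature maps are NCHW: depth D in the channel axis, H the frequency extent
and W the time extent of the spectrogram.  All convolutions use "same"
padding with ceil output semantics for strides, so a (23, 129, 59)
spectrogram flows 129x59 -> 65x30 (pre-CNN) -> 33x15 (stage 1) -> 17x8
(stage 2) before pooling.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .autodiff import Tensor
from . import nn
from .preprocessing import Spectrogram


@dataclass
class ModelConfig:
    in_channels: int = 23
    pre_cnn_channels: int = 16
    pre_cnn_strides: tuple[int, int, int] = (1, 1, 2)
    stage_dims: tuple[int, ...] = (32, 64)
    blocks_per_stage: tuple[int, ...] = (1, 1)
    n_heads: int = 8
    dropout: float = 0.25
    rffn_expansion: int = 4
    scale_by_sqrt: bool = True      # softmax(QK^T / sqrt(d_k)); False -> literal / d_k
    conv_gelu_bn_order: str = "conv-gelu-bn"  # or "conv-bn-gelu"
    threshold: float = 0.5
    init_std: float = 0.02
    dtype: str = "float64"          # "float32" roughly halves CPU training time
    seed: int = 0

    def __post_init__(self) -> None:
        for dim in self.stage_dims:
            if dim % self.n_heads:
                raise ValueError(f"stage dim {dim} not divisible by n_heads {self.n_heads}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.conv_gelu_bn_order not in ("conv-gelu-bn", "conv-bn-gelu"):
            raise ValueError(f"unknown order {self.conv_gelu_bn_order}")


class PreCNN(nn.Module):
    """Three 3x3 conv layers (16 maps each), strides (1, 1, 2), GELU + BN + dropout."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator,
                 dropout_rng: np.random.Generator):
        c = cfg.pre_cnn_channels
        ins = (cfg.in_channels, c, c)
        self.order = cfg.conv_gelu_bn_order
        self.convs = [nn.Conv2d(ci, c, 3, rng, stride=s, std=cfg.init_std)
                      for ci, s in zip(ins, cfg.pre_cnn_strides)]
        self.norms = [nn.BatchNorm2d(c) for _ in range(3)]
        self.drops = [nn.Dropout(cfg.dropout, dropout_rng) for _ in range(3)]

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[2] < 3 or x.shape[3] < 3:
            raise ValueError(f"spatial extent {x.shape[2]}x{x.shape[3]} below the 3x3 kernel")
        for conv, bn, drop in zip(self.convs, self.norms, self.drops):
            x = conv(x)
            if self.order == "conv-gelu-bn":
                x = bn(x.gelu())
            else:
                x = bn(x).gelu()
            x = drop(x)
        return x


class LocalPerceptionUnit(nn.Module):
    """Residual 3x3 depth-preserving convolution: X' = Conv(X) + X."""

    def __init__(self, dim: int, rng: np.random.Generator, std: float = 0.02):
        self.conv = nn.Conv2d(dim, dim, 3, rng, std=std)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(x) + x


class LMHSA(nn.Module):
    """Light multi-head self-attention with stride-2 depthwise-separable K/V reduction.

    With ``reduce=False`` the K/V source is the unreduced map and the layer is
    exactly dense multi-head self-attention — the configuration the oracle
    equivalence tests use.
    """

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator,
                 reduce: bool = True, scale_by_sqrt: bool = True, std: float = 0.02):
        if dim % n_heads:
            raise ValueError(f"dim {dim} not divisible by n_heads {n_heads}")
        self.dim = dim
        self.n_heads = n_heads
        self.reduce = reduce
        self.scale_by_sqrt = scale_by_sqrt
        self.reduction = nn.DepthwiseSeparableConv2d(dim, 3, rng, stride=2, std=std)
        self.q_proj = nn.Linear(dim, dim, rng, std=std)
        self.k_proj = nn.Linear(dim, dim, rng, std=std)
        self.v_proj = nn.Linear(dim, dim, rng, std=std)
        self.out_proj = nn.Linear(dim, dim, rng, std=std)
        self.last_attention: np.ndarray | None = None  # (B, heads, L, L') diagnostics

    @staticmethod
    def _tokens(x: Tensor) -> Tensor:
        b, d, h, w = x.shape
        return x.reshape(b, d, h * w).transpose(0, 2, 1)  # (B, L, D)

    def forward(self, x: Tensor) -> Tensor:
        b, d, h, w = x.shape
        q_tokens = self._tokens(x)
        kv_map = self.reduction(x) if self.reduce else x
        kv_tokens = self._tokens(kv_map)
        L, Lr = h * w, kv_map.shape[2] * kv_map.shape[3]
        dk = d // self.n_heads

        def heads(t: Tensor, n_tokens: int) -> Tensor:
            return t.reshape(b, n_tokens, self.n_heads, dk).transpose(0, 2, 1, 3)

        q = heads(self.q_proj(q_tokens), L)
        k = heads(self.k_proj(kv_tokens), Lr)
        v = heads(self.v_proj(kv_tokens), Lr)
        scale = 1.0 / math.sqrt(dk) if self.scale_by_sqrt else 1.0 / dk
        scores = (q @ k.transpose(0, 1, 3, 2)) * scale
        attn = scores.softmax(axis=-1)
        self.last_attention = attn.data
        mixed = attn @ v                                 # (B, heads, L, dk)
        mixed = mixed.transpose(0, 2, 1, 3).reshape(b, L, d)
        out = self.out_proj(mixed)
        return out.transpose(0, 2, 1).reshape(b, d, h, w)


class RFFN(nn.Module):
    """Residual feed-forward network: 1x1 expand -> depthwise 3x3 -> 1x1 project, + skip.

    GELU follows the first 1x1 and the depthwise convolution.  ``forward``
    adds the input itself as the skip; a block applying pre-LN passes the
    normalised map as ``x`` and the unnormalised one as ``residual``.
    """

    def __init__(self, dim: int, expansion: int, rng: np.random.Generator, std: float = 0.02):
        hidden = dim * expansion
        self.expand = nn.Conv2d(dim, hidden, 1, rng, std=std)
        self.depthwise = nn.Conv2d(hidden, hidden, 3, rng, groups=hidden, std=std)
        self.project = nn.Conv2d(hidden, dim, 1, rng, std=std)

    def forward(self, x: Tensor, residual: Tensor | None = None) -> Tensor:
        residual = x if residual is None else residual
        y = self.expand(x).gelu()
        y = self.depthwise(y).gelu()
        return self.project(y) + residual


class TransformerBlock(nn.Module):
    """LPU -> pre-LN LMHSA with residual -> pre-LN RFFN with residual."""

    def __init__(self, dim: int, cfg: ModelConfig, rng: np.random.Generator):
        self.lpu = LocalPerceptionUnit(dim, rng, std=cfg.init_std)
        self.ln_attn = nn.LayerNorm2d(dim)
        self.attn = LMHSA(dim, cfg.n_heads, rng, scale_by_sqrt=cfg.scale_by_sqrt,
                          std=cfg.init_std)
        self.ln_ffn = nn.LayerNorm2d(dim)
        self.ffn = RFFN(dim, cfg.rffn_expansion, rng, std=cfg.init_std)

    def forward(self, x: Tensor) -> Tensor:
        x = self.lpu(x)
        x = self.attn(self.ln_attn(x)) + x
        x = self.ffn(self.ln_ffn(x), residual=x)
        return x


class TransformerStage(nn.Module):
    """Entry 3x3 stride-2 conv to the stage dimension + LN, then the blocks."""

    def __init__(self, dim_in: int, dim_out: int, n_blocks: int, cfg: ModelConfig,
                 rng: np.random.Generator):
        self.entry = nn.Conv2d(dim_in, dim_out, 3, rng, stride=2, std=cfg.init_std)
        self.norm = nn.LayerNorm2d(dim_out)
        self.blocks = [TransformerBlock(dim_out, cfg, rng) for _ in range(n_blocks)]

    def forward(self, x: Tensor) -> Tensor:
        x = self.norm(self.entry(x))
        for block in self.blocks:
            x = block(x)
        return x


class SeizureDetector(nn.Module):
    """pre-CNN -> alternating transformer stages -> global pool -> 2-way log-softmax."""

    def __init__(self, cfg: ModelConfig | None = None):
        self.cfg = cfg = cfg or ModelConfig()
        rng = np.random.default_rng(cfg.seed)
        dropout_rng = np.random.default_rng([cfg.seed, 1])
        self.pre_cnn = PreCNN(cfg, rng, dropout_rng)
        dims = (cfg.pre_cnn_channels,) + tuple(cfg.stage_dims)
        self.stages = [TransformerStage(dims[i], dims[i + 1], cfg.blocks_per_stage[i],
                                        cfg, rng)
                       for i in range(len(cfg.stage_dims))]
        self.head = nn.Linear(dims[-1], 2, rng, std=cfg.init_std)
        if cfg.dtype != "float64":
            for p in self.parameters():
                p.data = p.data.astype(cfg.dtype)

    def features(self, x: Tensor) -> Tensor:
        x = self.pre_cnn(x)
        for stage in self.stages:
            x = stage(x)
        return x

    def forward(self, x: Tensor | np.ndarray) -> Tensor:
        """Batched spectrograms (B, C, F, T) -> log-probability pairs (B, 2)."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=self.cfg.dtype))
        if x.ndim == 3:
            x = x.reshape(1, *x.shape)
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"input depth {x.shape[1]} does not match configured {self.cfg.in_channels}")
        fmap = self.features(x)
        pooled = fmap.mean(axis=(2, 3))          # global average pool -> (B, D)
        logits = self.head(pooled)
        return logits.log_softmax(axis=-1)

    def predict(self, spectrograms: list[Spectrogram] | np.ndarray,
                threshold: float | None = None, batch_size: int = 32) -> np.ndarray:
        """Hard labels for a stack of spectrograms (inference mode)."""
        scores = self.score(spectrograms, batch_size=batch_size)
        theta = self.cfg.threshold if threshold is None else threshold
        return classify_scores(scores, theta)

    def score(self, spectrograms, batch_size: int = 32) -> np.ndarray:
        """Ictal probabilities exp(log p1), computed in inference mode."""
        was_training = self.training
        self.eval()
        try:
            arr = _stack(spectrograms)
            out = []
            for i in range(0, len(arr), batch_size):
                log_p = self.forward(arr[i:i + batch_size])
                out.append(np.exp(log_p.data[:, 1]))
            return np.concatenate(out) if out else np.empty(0)
        finally:
            self.train(was_training)


def _stack(spectrograms) -> np.ndarray:
    if isinstance(spectrograms, np.ndarray):
        return spectrograms
    return np.stack([s.values if isinstance(s, Spectrogram) else np.asarray(s)
                     for s in spectrograms])


def classify(log_probs: np.ndarray | Tensor, threshold: float = 0.5) -> np.ndarray:
    """Binarize log-probability pairs: label 1 iff exp(log p1) >= threshold."""
    if isinstance(log_probs, Tensor):
        log_probs = log_probs.data
    log_probs = np.asarray(log_probs)
    return classify_scores(np.exp(log_probs[..., 1]), threshold)


def classify_scores(p1: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    return (np.asarray(p1) >= threshold).astype(int)  # tie resolves to ictal


def save_checkpoint(model: SeizureDetector, path: str | Path) -> None:
    """Flat named-parameter archive (.npz) with a JSON config sidecar."""
    path = Path(path)
    with open(path, "wb") as fh:
        np.savez(fh, **model.state_dict())
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(asdict(model.cfg), indent=2, sort_keys=True))


def load_checkpoint(path: str | Path) -> SeizureDetector:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    raw = json.loads(sidecar.read_text())
    for key in ("pre_cnn_strides", "stage_dims", "blocks_per_stage"):
        raw[key] = tuple(raw[key])
    model = SeizureDetector(ModelConfig(**raw))
    with np.load(path) as data:
        model.load_state_dict(dict(data))
    return model
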