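"""The two contact-prediction branches and their ensemble.

* **Sequence-attention module** — the sequence profile goes through instance
  norm, a 1D convolution and a bidirectional LSTM, then multi-head sequence
  attention; the attention output is tiled to 2D and concatenated with the
  preprocessed coevolution tensor (instance norm, ReLU, 1x1 convolution to
  twice the trunk width, Maxout halving it); a four-block residual trunk with
  squeeze-and-excitation and a final 1x1 convolution + sigmoid produce the
  L x L contact probability map.

* **Regional-attention module** — the tiled profile is concatenated with the
  coevolution tensor at the input; after the same 2D preprocessing and
  residual trunk, a convolution reduces to the pre-attention width, windowed
  regional attention is applied, and a 1x1 convolution + sigmoid emits the
  map.

Either module can be built without its attention layer (the no-attention
baseline variant). The final prediction is the elementwise average of the two
module outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.special import expit

from .nn.tensor import Tensor, cat
from .nn.modules import (
    Module, Conv1d, Conv2d, InstanceNorm, BiLSTM, SqueezeExcite, maxout,
)
from .attention import (
    Attention1DLayer, RegionalAttentionLayer, Attention1DWeights,
    RegionalAttentionWeights, AttentionRecord, tile_tensor,
)
from .features import ContactMap, FeatureSet

__all__ = [
    "ModelConfig", "PredictionOutput", "SequenceModule", "RegionalModule",
    "build_model", "ensemble_predict", "symmetrize", "maxout_reduce",
    "squeeze_excite", "save_model", "load_model",
]


@dataclass
class ModelConfig:
    """Every architectural hyperparameter, with full-scale defaults.

    ``module`` selects the branch ("sequence" or "regional");
    ``use_attention=False`` gives the no-attention baseline variant of that
    branch. ``tiny()`` is a desk-scale preset for CPU work; ``full_scale()``
    mirrors the full-scale sizes (441 coevolution channels, trunk width 64,
    block repeats 3-4-6-3, 4 heads, window 5).
    """

    module: str = "sequence"
    use_attention: bool = True
    plm_channels: int = 441
    pssm_dim: int = 20
    conv1d_width: int = 64
    conv1d_kernel: int = 5
    lstm_hidden: int = 64
    n_heads: int = 4
    d_att: int = 32
    region_n: int = 5
    d_att2d: int = 32
    pre_attention_width: int = 32
    trunk_width: int = 64
    block_repeats: tuple[int, ...] = (3, 4, 6, 3)
    se_ratio: int = 16
    init_seed: int = 0

    def __post_init__(self):
        if self.module not in ("sequence", "regional"):
            raise ValueError(f"unknown module {self.module!r}")
        if any(r < 1 for r in self.block_repeats):
            raise ValueError("block repeats must all be >= 1")
        if self.region_n % 2 == 0:
            raise ValueError("region size must be odd")
        self.block_repeats = tuple(self.block_repeats)

    @property
    def variant(self) -> str:
        return self.module if self.use_attention else "baseline"

    @classmethod
    def full_scale(cls, module: str = "sequence", **kw) -> "ModelConfig":
        return cls(module=module, **kw)

    @classmethod
    def tiny(cls, module: str = "sequence", **kw) -> "ModelConfig":
        defaults = dict(
            module=module, plm_channels=16, conv1d_width=8, conv1d_kernel=5,
            lstm_hidden=8, n_heads=4, d_att=4, region_n=5, d_att2d=8,
            pre_attention_width=16, trunk_width=16, block_repeats=(1, 1, 1, 1),
            se_ratio=4)
        defaults.update(kw)
        return cls(**defaults)


@dataclass
class PredictionOutput:
    contacts: ContactMap                      # probability kind, L x L
    attention: AttentionRecord | None = None


# ---------------------------------------------------------------------------
# Building blocks

class ResidualBlock(Module):
    """(instance norm -> ReLU -> 3x3 conv) x repeats, 1x1 shortcut, SE gate."""

    def __init__(self, c_in: int, width: int, repeats: int, se_ratio: int,
                 rng: np.random.Generator):
        self.norms: list[Module] = []
        self.convs: list[Module] = []
        c = c_in
        for _ in range(repeats):
            self.norms.append(InstanceNorm(c))
            self.convs.append(Conv2d(c, width, 3, rng))
            c = width
        self.shortcut = Conv2d(c_in, width, 1, rng)
        self.se = SqueezeExcite(width, se_ratio, rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = x
        for norm, conv in zip(self.norms, self.convs):
            h = conv(norm(h).relu())
        return self.se(h + self.shortcut(x))


class ResidualStack(Module):
    def __init__(self, c_in: int, width: int, repeats: tuple[int, ...],
                 se_ratio: int, rng: np.random.Generator):
        blocks = []
        c = c_in
        for r in repeats:
            blocks.append(ResidualBlock(c, width, r, se_ratio, rng))
            c = width
        self.blocks = blocks

    def __call__(self, x: Tensor) -> Tensor:
        for block in self.blocks:
            x = block(x)
        return x


class _Preprocess2d(Module):
    """Instance norm -> ReLU -> 1x1 conv (2 * trunk) -> Maxout (trunk)."""

    def __init__(self, c_in: int, trunk_width: int, rng: np.random.Generator):
        self.norm = InstanceNorm(c_in)
        self.conv = Conv2d(c_in, 2 * trunk_width, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return maxout(self.conv(self.norm(x).relu()))


# ---------------------------------------------------------------------------
# Prediction branches

class SequenceModule(Module):
    """Sequence-attention branch (or its no-attention baseline)."""

    def __init__(self, config: ModelConfig):
        if config.module != "sequence":
            raise ValueError("config.module must be 'sequence'")
        self.config = config
        rng = np.random.default_rng(config.init_seed)
        c = config
        self.norm1d = InstanceNorm(c.pssm_dim)
        self.conv1d = Conv1d(c.pssm_dim, c.conv1d_width, c.conv1d_kernel, rng)
        self.lstm = BiLSTM(c.conv1d_width, c.lstm_hidden, rng)
        enc_width = 2 * c.lstm_hidden
        if c.use_attention:
            self.attn = Attention1DLayer(enc_width, c.n_heads, c.d_att, rng)
            tiled_width = 2 * c.n_heads * c.d_att
        else:
            self.attn = None
            tiled_width = 2 * enc_width
        self.pre2d = _Preprocess2d(c.plm_channels, c.trunk_width, rng)
        self.trunk = ResidualStack(c.trunk_width + tiled_width, c.trunk_width,
                                   c.block_repeats, c.se_ratio, rng)
        self.out_conv = Conv2d(c.trunk_width, 1, 1, rng)

    def forward_logits(self, fs: FeatureSet, capture: bool = False
                       ) -> tuple[Tensor, AttentionRecord | None]:
        L = fs.length
        x = self.conv1d(self.norm1d(Tensor(fs.pssm.values))).relu()
        x = self.lstm(x)
        record = None
        if self.attn is not None:
            x, w = self.attn(x)
            if capture:
                record = AttentionRecord(sequence=Attention1DWeights(w_att=w),
                                         variant=self.config.variant)
        tiled = tile_tensor(x)
        y = self.pre2d(Tensor(fs.plm.values))
        h = self.trunk(cat([y, tiled], axis=-1))
        return self.out_conv(h).reshape(L, L), record

    def predict(self, fs: FeatureSet, capture: bool = False) -> PredictionOutput:
        logits, record = self.forward_logits(fs, capture=capture)
        probs = 1.0 / (1.0 + np.exp(-logits.data))
        return PredictionOutput(
            contacts=ContactMap(values=probs, kind="probability"),
            attention=record)


class RegionalModule(Module):
    """Regional-attention branch (or its no-attention baseline)."""

    def __init__(self, config: ModelConfig):
        if config.module != "regional":
            raise ValueError("config.module must be 'regional'")
        self.config = config
        rng = np.random.default_rng(config.init_seed)
        c = config
        in_width = c.plm_channels + 2 * c.pssm_dim
        self.pre2d = _Preprocess2d(in_width, c.trunk_width, rng)
        self.trunk = ResidualStack(c.trunk_width, c.trunk_width,
                                   c.block_repeats, c.se_ratio, rng)
        self.pre_attn_conv = Conv2d(c.trunk_width, c.pre_attention_width, 3, rng)
        if c.use_attention:
            self.attn = RegionalAttentionLayer(
                c.pre_attention_width, c.n_heads, c.d_att2d,
                c.pre_attention_width, c.region_n, rng)
        else:
            self.attn = None
        self.out_conv = Conv2d(c.pre_attention_width, 1, 1, rng)

    def forward_logits(self, fs: FeatureSet, capture: bool = False
                       ) -> tuple[Tensor, AttentionRecord | None]:
        L = fs.length
        tiled = tile_tensor(Tensor(fs.pssm.values))
        h = self.pre2d(cat([Tensor(fs.plm.values), tiled], axis=-1))
        h = self.trunk(h)
        h = self.pre_attn_conv(h)
        record = None
        if self.attn is not None:
            h, w, inb = self.attn(h)
            if capture:
                record = AttentionRecord(
                    regional=RegionalAttentionWeights(weights=w, inbounds=inb),
                    variant=self.config.variant)
        return self.out_conv(h).reshape(L, L), record

    def predict(self, fs: FeatureSet, capture: bool = False) -> PredictionOutput:
        logits, record = self.forward_logits(fs, capture=capture)
        probs = 1.0 / (1.0 + np.exp(-logits.data))
        return PredictionOutput(
            contacts=ContactMap(values=probs, kind="probability"),
            attention=record)


def build_model(config: ModelConfig) -> SequenceModule | RegionalModule:
    return (SequenceModule(config) if config.module == "sequence"
            else RegionalModule(config))


# ---------------------------------------------------------------------------
# Map-level operations

def ensemble_predict(a: ContactMap, b: ContactMap) -> ContactMap:
    """Elementwise average of the two module predictions."""
    if a.kind != "probability" or b.kind != "probability":
        raise ValueError("ensemble requires probability-kind maps")
    if a.length != b.length:
        raise ValueError(f"length mismatch: {a.length} vs {b.length}")
    return ContactMap(values=0.5 * (a.values + b.values), kind="probability")


def symmetrize(m: ContactMap) -> ContactMap:
    """(M + M^T) / 2; applied before ranking and evaluation."""
    return ContactMap(values=0.5 * (m.values + m.values.T), kind=m.kind,
                      validity=m.validity)


def maxout_reduce(f: np.ndarray) -> np.ndarray:
    """Pairwise channel max over the last axis: 2m channels -> m."""
    f = np.asarray(f, dtype=np.float64)
    if f.shape[-1] % 2 != 0:
        raise ValueError(f"maxout needs an even channel count, got {f.shape[-1]}")
    return np.maximum(f[..., 0::2], f[..., 1::2])


@dataclass
class SqueezeExciteParams:
    w1: np.ndarray  # (c, mid)
    b1: np.ndarray
    w2: np.ndarray  # (mid, c)
    b2: np.ndarray


def squeeze_excite(f: np.ndarray, params: SqueezeExciteParams) -> np.ndarray:
    """Channel recalibration: global mean -> bottleneck MLP -> sigmoid gate."""
    f = np.asarray(f, dtype=np.float64)
    if f.shape[-1] != params.w1.shape[0]:
        raise ValueError("channel count does not match parameters")
    axes = tuple(range(f.ndim - 1))
    z = f.mean(axis=axes)
    hidden = np.maximum(z @ params.w1 + params.b1, 0.0)
    gate = expit(hidden @ params.w2 + params.b2)
    return f * gate


# ---------------------------------------------------------------------------
# Checkpoints

def save_model(model: SequenceModule | RegionalModule, path: str | Path) -> None:
    """Serialize the weights as keyed arrays with the config as metadata."""
    arrays = {name: p.data for name, p in model.named_parameters()}
    cfg = asdict(model.config)
    cfg["block_repeats"] = list(cfg["block_repeats"])
    arrays["__config__"] = np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path: str | Path) -> SequenceModule | RegionalModule:
    with np.load(path) as data:
        cfg = json.loads(bytes(data["__config__"]).decode())
        cfg["block_repeats"] = tuple(cfg["block_repeats"])
        model = build_model(ModelConfig(**cfg))
        params = dict(model.named_parameters())
        for name in data.files:
            if name == "__config__":
                continue
            if name not in params:
                raise ValueError(f"unexpected parameter {name!r} in checkpoint")
            params[name].data = data[name].astype(np.float64)
    return model
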