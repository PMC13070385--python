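"""The sequence-to-track network: a simplified Enformer-style architecture.

The trunk is a convolutional stem, a pooling conv tower reaching 128-fold
(more generally ``bin_size``-fold) resolution reduction, a stack of
self-attention blocks, a center crop and an optional final pointwise
convolution.  One or more linear "heads" with softplus output map trunk
features to per-track Poisson rates.

Two architecture ablations are first-class configuration switches:

* ``include_attention_linear`` — presence of the post-attention output
  projection inside every attention block;
* ``include_final_pointwise`` — presence of the channel-doubling pointwise
  convolution between the attention stack and the heads.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .layers import (ConvBlock, Conv1d, Dense, Dropout, Module, Residual,
                     Sequential, SoftmaxPool, TransformerBlock)


def exponential_linspace_int(start, end, num, divisible_by=1):
    """Exponentially spaced integers rounded to a multiple of divisible_by."""
    def at(i):
        return int(round(start * (end / start) ** (i / (num - 1)) / divisible_by)) * divisible_by
    return [at(i) for i in range(num)]


@dataclasses.dataclass
class ModelConfig:
    """Architecture hyperparameters.

    The defaults reproduce the full published geometry (196,608 bp input,
    114,688 bp crop, 128 bp bins, 1536 trunk channels, 11 attention blocks,
    a 5313-track human head).  ``tiny()`` and ``desk()`` presets give
    CPU-friendly models with the same structure.
    """

    input_length: int = 196_608
    bin_size: int = 128
    crop_length: int = 114_688
    n_conv_blocks: int = 7
    n_attention_blocks: int = 11
    n_heads: int = 8
    channels: int = 1536
    include_attention_linear: bool = True
    include_final_pointwise: bool = True
    head_track_counts: tuple = (5313,)
    dropout_rate: float = 0.4
    positional_scheme: str = "enformer_basis"
    key_size: int | None = None
    stem_kernel: int = 15
    tower_kernel: int = 5

    def __post_init__(self):
        self.head_track_counts = tuple(self.head_track_counts)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self):
        if self.input_length % self.bin_size or self.crop_length % self.bin_size:
            raise ValueError(
                "input_length and crop_length must be multiples of bin_size "
                f"(got {self.input_length}, {self.crop_length}, bin {self.bin_size})")
        if self.crop_length > self.input_length:
            raise ValueError(
                f"crop_length {self.crop_length} exceeds input_length {self.input_length}")
        if (self.input_length - self.crop_length) % 2:
            raise ValueError("input_length - crop_length must be even for a centered crop")
        if 2 ** self.n_conv_blocks != self.bin_size:
            raise ValueError(
                f"total pooling factor 2^{self.n_conv_blocks} = {2 ** self.n_conv_blocks} "
                f"must equal bin_size {self.bin_size}")
        if self.n_attention_blocks < 1:
            raise ValueError("n_attention_blocks must be >= 1")
        if any(n < 1 for n in self.head_track_counts) or not self.head_track_counts:
            raise ValueError("every head track count must be >= 1")
        if self.channels % 2 or (self.channels // 2) % self.n_heads:
            raise ValueError("channels must be even and channels/2 divisible by n_heads")
        if self.positional_scheme not in ("enformer_basis", "simple_relative_bias"):
            raise ValueError(f"unknown positional_scheme {self.positional_scheme}")

    @property
    def n_bins(self):
        return self.crop_length // self.bin_size

    @property
    def seq_bins(self):
        return self.input_length // self.bin_size

    @property
    def head_input_channels(self):
        return 2 * self.channels if self.include_final_pointwise else self.channels

    @property
    def tower_filters(self):
        div = max(1, self.channels // 12)
        return exponential_linspace_int(
            self.channels // 2, self.channels, self.n_conv_blocks - 1, div)

    # -- presets ------------------------------------------------------------
    @classmethod
    def full_scale(cls, head_track_counts=(5313,), **kw):
        return cls(head_track_counts=head_track_counts, **kw)

    @classmethod
    def desk(cls, head_track_counts=(8,), **kw):
        defaults = dict(input_length=4096, crop_length=2048, bin_size=128,
                        n_conv_blocks=7, n_attention_blocks=2, n_heads=2,
                        channels=48, dropout_rate=0.05,
                        positional_scheme="simple_relative_bias",
                        head_track_counts=head_track_counts)
        defaults.update(kw)
        return cls(**defaults)

    @classmethod
    def tiny(cls, head_track_counts=(4,), **kw):
        defaults = dict(input_length=1024, crop_length=512, bin_size=64,
                        n_conv_blocks=6, n_attention_blocks=2, n_heads=2,
                        channels=24, dropout_rate=0.0, stem_kernel=11,
                        positional_scheme="simple_relative_bias",
                        head_track_counts=head_track_counts)
        defaults.update(kw)
        return cls(**defaults)

    def to_dict(self):
        d = dataclasses.asdict(self)
        d["head_track_counts"] = list(self.head_track_counts)
        return d

    @classmethod
    def from_dict(cls, d):
        return cls(**{k: (tuple(v) if k == "head_track_counts" else v)
                      for k, v in d.items()})


@dataclasses.dataclass
class ParameterSummary:
    trainable_count: int
    per_component_counts: dict

    @property
    def millions(self):
        return round(self.trainable_count / 1e6)


class TrackPredictor(Module):
    """Trunk + heads.  Built through :func:`build_model`."""

    def __init__(self, config: ModelConfig, seed: int):
        super().__init__()
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        C = config.channels
        half = C // 2
        # stem: conv, residual pointwise conv block, attention pooling
        self.stem = Sequential(
            Conv1d(4, half, config.stem_kernel, rng),
            Residual(ConvBlock(half, half, 1, rng)),
            SoftmaxPool(half, rng))
        # conv tower
        stages = []
        c_prev = half
        for c_out in config.tower_filters:
            stages.append(Sequential(
                ConvBlock(c_prev, c_out, config.tower_kernel, rng),
                Residual(ConvBlock(c_out, c_out, 1, rng)),
                SoftmaxPool(c_out, rng)))
            c_prev = c_out
        self.tower = Sequential(*stages)
        # attention stack
        blocks = [TransformerBlock(
            C, config.n_heads, rng,
            scheme=config.positional_scheme,
            output_projection=config.include_attention_linear,
            dropout=config.dropout_rate,
            attn_dropout=config.dropout_rate / 8,
            key_size=config.key_size,
            max_positions=config.seq_bins)
            for _ in range(config.n_attention_blocks)]
        self.attention = Sequential(*blocks)
        if config.include_final_pointwise:
            self.pointwise = ConvBlock(C, 2 * C, 1, rng)
            self.pointwise_dropout = Dropout(config.dropout_rate / 8)
        self._build_heads(config.head_track_counts, rng)

    def _build_heads(self, track_counts, rng):
        heads = [Dense(self.config.head_input_channels, n, rng) for n in track_counts]
        self.heads = Sequential(*heads)
        self.config = dataclasses.replace(self.config, head_track_counts=tuple(track_counts))

    # -- forward ------------------------------------------------------------
    def forward(self, batch, rng=None):
        """One-hot batch (B, input_length, 4) -> list of (B, n_bins, n_tracks)."""
        cfg = self.config
        x = batch if isinstance(batch, ad.Tensor) else ad.Tensor(np.asarray(batch, dtype=float))
        if x.ndim == 2:
            x = ad.reshape(x, (1,) + x.shape)
        if x.shape[1] != cfg.input_length or x.shape[2] != 4:
            raise ValueError(
                f"expected input of shape (B, {cfg.input_length}, 4), received {x.shape}")
        h = self.stem(x, rng=rng)
        h = self.tower(h, rng=rng)
        h = self.attention(h, rng=rng)
        crop_bins = (cfg.seq_bins - cfg.n_bins) // 2
        if crop_bins:
            h = h[:, crop_bins:cfg.seq_bins - crop_bins, :]
        if cfg.include_final_pointwise:
            h = self.pointwise_dropout(ad.gelu(self.pointwise(h)), rng=rng)
        return [ad.softplus(head(h)) for head in self.heads.items]

    def predict(self, batch):
        """Forward in eval mode, returning plain arrays."""
        was_training = self.training
        self.set_training(False)
        out = [t.data for t in self.forward(batch)]
        self.set_training(was_training)
        return out

    # -- bookkeeping --------------------------------------------------------
    def head_parameters(self):
        return {name: p for name, p in self.named_parameters() if name.startswith("heads.")}

    def trunk_parameters(self):
        return {name: p for name, p in self.named_parameters() if not name.startswith("heads.")}

    def trunk_checksum(self):
        h = hashlib.sha256()
        for name in sorted(self.trunk_parameters()):
            h.update(name.encode())
            h.update(np.ascontiguousarray(self.trunk_parameters()[name].data).tobytes())
        return h.hexdigest()


def build_model(config: ModelConfig, seed: int) -> TrackPredictor:
    """Instantiate the network with seed-determined initial weights."""
    config.validate()
    return TrackPredictor(config, seed)


_COMPONENTS = (("stem", "stem."), ("conv_tower", "tower."),
               ("attention_blocks", "attention."), ("pointwise", "pointwise."),
               ("heads", "heads."))


def count_parameters(model: TrackPredictor, trainable_only: bool = False) -> ParameterSummary:
    counts = {name: 0 for name, _ in _COMPONENTS}
    for pname, p in model.named_parameters():
        if trainable_only and not p.requires_grad:
            continue
        for cname, prefix in _COMPONENTS:
            if pname.startswith(prefix):
                counts[cname] += p.data.size
                break
    return ParameterSummary(int(sum(counts.values())),
                            {k: int(v) for k, v in counts.items()})


def replace_head(model: TrackPredictor, n_tracks: int, seed: int) -> TrackPredictor:
    """Drop every head and attach one freshly initialized n_tracks head.

    Trunk weights are left untouched (bitwise).
    """
    if n_tracks < 1:
        raise ValueError("n_tracks must be >= 1")
    rng = np.random.default_rng(seed)
    model._build_heads((n_tracks,), rng)
    return model


def set_trunk_frozen(model: TrackPredictor, frozen: bool) -> TrackPredictor:
    for p in model.trunk_parameters().values():
        p.requires_grad = not frozen
    for p in model.head_parameters().values():
        p.requires_grad = True
    return model


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: TrackPredictor, directory, epoch=None, parent=None,
                    extra=None):
    """Write weights (npz) plus a JSON sidecar with config and provenance."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arrays = {f"param:{n}": p.data for n, p in model.named_parameters()}
    arrays.update({f"buffer:{n}": b for n, b in model.named_buffers()})
    np.savez(directory / "weights.npz", **arrays)
    meta = {
        "config": model.config.to_dict(),
        "seed": model.seed,
        "epoch": epoch,
        "parent": str(parent) if parent else None,
        "trunk_checksum": model.trunk_checksum(),
    }
    if extra:
        meta.update(extra)
    (directory / "checkpoint.json").write_text(json.dumps(meta, indent=2))
    return directory


def load_checkpoint(directory) -> TrackPredictor:
    directory = Path(directory)
    meta = json.loads((directory / "checkpoint.json").read_text())
    config = ModelConfig.from_dict(meta["config"])
    model = build_model(config, meta["seed"])
    with np.load(directory / "weights.npz") as data:
        params = dict(model.named_parameters())
        expected = {f"param:{n}" for n in params} | {f"buffer:{n}" for n, _ in model.named_buffers()}
        if expected != set(data.files):
            raise ValueError(
                "checkpoint does not match the current architecture: "
                f"missing {sorted(expected - set(data.files))[:3]}, "
                f"unexpected {sorted(set(data.files) - expected)[:3]}")
        for key in data.files:
            kind, name = key.split(":", 1)
            if kind == "param":
                params[name].data = data[key].copy()
        buffers = dict(model.named_buffers())
        for key in data.files:
            kind, name = key.split(":", 1)
            if kind == "buffer":
                owner = model
                parts = name.split(".")
                for part in parts[:-1]:
                    owner = owner._modules[part]
                owner._buffers[parts[-1]] = data[key].copy()
    return model
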