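"""Neural-network building blocks for the sequence-to-track model.

Layers follow the published Enformer design where the architecture is not a
deliberate deviation: convolution blocks are BatchNorm -> GELU -> Conv,
pooling is learned two-fold softmax (attention) pooling, and self-attention
uses content + relative-position logits.  Sequences are carried as
(batch, length, channels) arrays throughout.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as _stats

from . import autodiff as ad
from .autodiff import Parameter, Tensor


class Module:
    """Base class: named parameter tree, train/eval mode, buffers."""

    def __init__(self):
        self._params: dict[str, Parameter] = {}
        self._modules: dict[str, "Module"] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_module(self, name, module):
        self._modules[name] = module
        object.__setattr__(self, name, module)

    def named_parameters(self, prefix=""):
        for name, p in self._params.items():
            yield f"{prefix}{name}", p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix=f"{prefix}{name}.")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix=""):
        for name, b in self._buffers.items():
            yield f"{prefix}{name}", b
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix=f"{prefix}{name}.")

    def set_training(self, flag: bool):
        self.training = flag
        for m in self._modules.values():
            m.set_training(flag)
        return self

    def n_parameters(self, trainable_only=False):
        return int(sum(p.data.size for p in self.parameters()
                       if not trainable_only or p.requires_grad))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *modules):
        super().__init__()
        self.items = list(modules)
        for i, m in enumerate(modules):
            self.register_module(str(i), m)

    def forward(self, x, **kw):
        for m in self.items:
            x = m(x, **kw)
        return x


class Residual(Module):
    def __init__(self, inner):
        super().__init__()
        self.inner = inner

    def forward(self, x, **kw):
        return x + self.inner(x, **kw)


def _he_normal(rng, fan_in, shape):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Dense(Module):
    def __init__(self, n_in, n_out, rng, bias=True):
        super().__init__()
        self.w = Parameter(_he_normal(rng, n_in, (n_in, n_out)))
        self.bias = bias
        if bias:
            self.b = Parameter(np.zeros(n_out))

    def forward(self, x, **kw):
        y = ad.matmul(x, self.w)
        return y + self.b if self.bias else y


class Conv1d(Module):
    """Same-padded 1-D convolution over (B, L, C) input."""

    def __init__(self, c_in, c_out, kernel, rng, bias=True):
        super().__init__()
        self.kernel = kernel
        self.w = Parameter(_he_normal(rng, c_in * kernel, (kernel * c_in, c_out)))
        self.b = Parameter(np.zeros(c_out)) if bias else None

    def forward(self, x, **kw):
        y = ad.matmul(ad.unfold1d(x, self.kernel), self.w)
        return y + self.b if self.b is not None else y


class BatchNorm(Module):
    """Normalizes over batch x position, so batch size 1 remains well-posed."""

    def __init__(self, channels, momentum=0.1, eps=1e-5):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self._buffers["running_mean"] = np.zeros(channels)
        self._buffers["running_var"] = np.ones(channels)

    def forward(self, x, **kw):
        if self.training:
            mu = x.mean(axis=(0, 1), keepdims=True)
            centered = x - mu
            var = ad.reduce_mean(ad.power(centered, 2.0), axis=(0, 1), keepdims=True)
            m = self.momentum
            self._buffers["running_mean"] = (
                (1 - m) * self._buffers["running_mean"] + m * mu.data.ravel())
            self._buffers["running_var"] = (
                (1 - m) * self._buffers["running_var"] + m * var.data.ravel())
            inv = ad.power(var + self.eps, -0.5)
            return centered * inv * self.gamma + self.beta
        mu = self._buffers["running_mean"]
        inv = 1.0 / np.sqrt(self._buffers["running_var"] + self.eps)
        return (x - Tensor(mu)) * Tensor(inv) * self.gamma + self.beta


class LayerNorm(Module):
    def __init__(self, dim, eps=1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))

    def forward(self, x, **kw):
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = ad.reduce_mean(ad.power(centered, 2.0), axis=-1, keepdims=True)
        return centered * ad.power(var + self.eps, -0.5) * self.gamma + self.beta


class ConvBlock(Module):
    """BatchNorm -> GELU -> Conv, the Enformer-style pre-activation block."""

    def __init__(self, c_in, c_out, kernel, rng):
        super().__init__()
        self.norm = BatchNorm(c_in)
        self.conv = Conv1d(c_in, c_out, kernel, rng)

    def forward(self, x, **kw):
        return self.conv(ad.gelu(self.norm(x)))


class SoftmaxPool(Module):
    """Learned two-fold attention pooling: per-channel softmax over each
    adjacent pair of positions, logits from a channels->channels linear map."""

    def __init__(self, channels, rng, pool_size=2, init_gain=2.0):
        super().__init__()
        self.pool_size = pool_size
        # identity*gain init biases pooling toward max-pool, as published
        self.w = Parameter(np.eye(channels) * init_gain)

    def forward(self, x, **kw):
        B, L, C = x.shape
        p = self.pool_size
        xw = ad.reshape(x, (B, L // p, p, C))
        logits = ad.matmul(xw, self.w)
        weights = ad.softmax(logits, axis=2)
        return ad.reduce_sum(xw * weights, axis=2)


class Dropout(Module):
    def __init__(self, rate):
        super().__init__()
        self.rate = rate

    def forward(self, x, rng=None, **kw):
        if not self.training or self.rate <= 0.0 or rng is None:
            return x
        mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * Tensor(mask)


# ---------------------------------------------------------------------------
# relative-position features
# ---------------------------------------------------------------------------

def positional_features(distances: np.ndarray, n_features: int, seq_length: int) -> np.ndarray:
    """Deterministic relative-position basis (exponential, central-mask and
    gamma families, each emitted symmetric and sign-modulated).

    Returns an array of shape (len(distances), n_features).
    """
    if n_features % 6 != 0:
        raise ValueError("number of positional features must be divisible by 6")
    per = n_features // 6
    ad_ = np.abs(distances).astype(float)
    feats = []
    # exponential decay at geometrically spaced half-lives
    half_lives = np.power(2.0, np.linspace(np.log2(3.0), np.log2(max(seq_length, 4)), per))
    feats.append(np.exp(-np.log(2.0) / half_lives[None, :] * ad_[:, None]))
    # central mask at doubling widths
    widths = np.power(2.0, np.arange(1, per + 1))
    feats.append((ad_[:, None] < widths[None, :]).astype(float))
    # gamma bumps tiling the range
    means = np.linspace(seq_length / per, seq_length, per)
    stddev = seq_length / per
    conc = (means / stddev) ** 2
    rate = means / stddev ** 2
    pdf = _stats.gamma.pdf(ad_[:, None] + 1e-8, conc[None, :], scale=1.0 / rate[None, :])
    pdf = pdf / pdf.max(axis=0, keepdims=True).clip(min=1e-12)
    feats.append(pdf)
    sym = np.concatenate(feats, axis=1)
    signed = sym * np.sign(distances)[:, None]
    return np.concatenate([sym, signed], axis=1)


class MultiHeadSelfAttention(Module):
    """Multi-head self-attention with relative positional logits.

    Two positional schemes are available: `enformer_basis` projects a fixed
    basis of the relative distance through a learned linear map (the published
    design, with per-head content and positional biases r_w/r_r), while
    `simple_relative_bias` learns one scalar bias per head per relative offset
    (adequate for short toy sequences).

    When `output_projection` is False the post-attention linear layer is
    omitted and the concatenated heads feed the residual sum directly; heads
    must then reconstruct the channel dimension (heads * value_size == C).
    """

    def __init__(self, channels, n_heads, rng, key_size=None, value_size=None,
                 scheme="enformer_basis", output_projection=True,
                 attn_dropout=0.05, max_positions=4096):
        super().__init__()
        if channels % n_heads != 0:
            raise ValueError("channels must be divisible by n_heads")
        self.channels = channels
        self.n_heads = n_heads
        self.key_size = key_size or min(64, channels // n_heads)
        self.value_size = value_size or channels // n_heads
        self.scheme = scheme
        self.output_projection = output_projection
        self.attn_dropout = attn_dropout
        H, dk, dv = n_heads, self.key_size, self.value_size
        self.wq = Parameter(_he_normal(rng, channels, (channels, H * dk)))
        self.wk = Parameter(_he_normal(rng, channels, (channels, H * dk)))
        self.wv = Parameter(_he_normal(rng, channels, (channels, H * dv)))
        if output_projection:
            self.wo = Parameter(_he_normal(rng, H * dv, (H * dv, channels)))
            self.bo = Parameter(np.zeros(channels))
        if scheme == "enformer_basis":
            self.n_pos_features = max(6, (channels // n_heads) // 6 * 6)
            self.wr = Parameter(_he_normal(rng, self.n_pos_features,
                                           (self.n_pos_features, H * dk)))
            self.r_w_bias = Parameter(rng.normal(0.0, 0.02, (H, dk)))
            self.r_r_bias = Parameter(rng.normal(0.0, 0.02, (H, dk)))
        elif scheme == "simple_relative_bias":
            self.rel_bias = Parameter(np.zeros((H, 2 * max_positions - 1)))
            self.max_positions = max_positions
        else:
            raise ValueError(f"unknown positional scheme: {scheme}")
        self._pos_cache = {}

    def _basis(self, n):
        if n not in self._pos_cache:
            d = np.arange(-(n - 1), n)
            self._pos_cache[n] = positional_features(d, self.n_pos_features, n)
        return self._pos_cache[n]

    def forward(self, x, rng=None, **kw):
        B, n, C = x.shape
        H, dk, dv = self.n_heads, self.key_size, self.value_size
        q = ad.reshape(ad.matmul(x, self.wq), (B, n, H, dk))
        k = ad.reshape(ad.matmul(x, self.wk), (B, n, H, dk))
        v = ad.reshape(ad.matmul(x, self.wv), (B, n, H, dv))
        scale = 1.0 / np.sqrt(dk)
        if self.scheme == "enformer_basis":
            content = ad.einsum("bihd,bjhd->bhij", q + self.r_w_bias, k)
            r = ad.reshape(ad.matmul(Tensor(self._basis(n)), self.wr), (2 * n - 1, H, dk))
            rel = ad.einsum("bihd,mhd->bhim", q + self.r_r_bias, r)
            # scatter relative offsets m = j - i + n - 1 into (i, j)
            gather = np.zeros((n, 2 * n - 1, n))
            ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
            gather[ii, jj - ii + n - 1, jj] = 1.0
            logits = (content + ad.einsum("bhim,imj->bhij", rel, Tensor(gather))) * scale
        else:
            content = ad.einsum("bihd,bjhd->bhij", q, k)
            d = np.arange(n)
            idx = d[None, :] - d[:, None] + self.max_positions - 1
            bias = ad.take_slice(self.rel_bias, (slice(None), idx))
            logits = content * scale + bias
        probs = ad.softmax(logits, axis=-1)
        if self.training and self.attn_dropout > 0 and rng is not None:
            mask = (rng.random(probs.shape) >= self.attn_dropout) / (1 - self.attn_dropout)
            probs = probs * Tensor(mask)
        out = ad.einsum("bhij,bjhd->bihd", probs, v)
        out = ad.reshape(out, (B, n, H * dv))
        if self.output_projection:
            out = ad.matmul(out, self.wo) + self.bo
        return out


class TransformerBlock(Module):
    """Pre-norm attention + feed-forward residual block (MLP width 2C)."""

    def __init__(self, channels, n_heads, rng, scheme, output_projection,
                 dropout=0.4, attn_dropout=0.05, key_size=None, max_positions=4096):
        super().__init__()
        self.norm1 = LayerNorm(channels)
        self.attn = MultiHeadSelfAttention(
            channels, n_heads, rng, key_size=key_size, scheme=scheme,
            output_projection=output_projection, attn_dropout=attn_dropout,
            max_positions=max_positions)
        self.drop1 = Dropout(dropout)
        self.norm2 = LayerNorm(channels)
        self.ff1 = Dense(channels, 2 * channels, rng)
        self.ff2 = Dense(2 * channels, channels, rng)
        self.drop2 = Dropout(dropout)

    def forward(self, x, rng=None, **kw):
        x = x + self.drop1(self.attn(self.norm1(x), rng=rng), rng=rng)
        h = ad.relu(self.drop2(self.ff1(self.norm2(x)), rng=rng))
        return x + self.drop2(self.ff2(h), rng=rng)
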