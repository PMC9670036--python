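"""Neural-network building blocks on the :mod:`patchgraph.autograd` engine.

Contains exactly the layers the pipeline needs: linear maps, layer
normalisation, 2-D convolution (via im2col), residual CNN backbones for the
patch feature extractor, the Adam optimiser, and the two learning-rate
schedules used in training (cosine annealing for contrastive pre-training,
step decay for the graph-transformer).

All parameter initialisation is driven by an explicit ``numpy.random.Generator``
so that every training run is reproducible from a single integer seed.
"""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor

DTYPE = np.float32


# --------------------------------------------------------------------- modules
class Module:
    """Base class: tracks parameters and sub-modules by attribute assignment."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, m in self._modules.items():
            out.update(m.named_parameters(prefix + name + "."))
        return out

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = self.named_parameters()
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _param(arr: np.ndarray) -> Tensor:
    return Tensor(arr.astype(DTYPE), requires_grad=True)


def he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, math.sqrt(2.0 / fan_in), size=shape)


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    x = rng.normal(0.0, std, size=shape)
    return np.clip(x, -2 * std, 2 * std)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.weight = _param(he_normal(rng, (d_in, d_out), d_in))
        self.bias = _param(np.zeros(d_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.weight = _param(np.ones(dim))
        self.bias = _param(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.weight + self.bias


class Conv2d(Module):
    """3x3-style convolution on (B, C, H, W) via im2col + matmul."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        ksize: int,
        rng: np.random.Generator,
        stride: int = 1,
        pad: int | None = None,
    ):
        super().__init__()
        if pad is None:
            pad = ksize // 2
        fan_in = c_in * ksize * ksize
        self.weight = _param(he_normal(rng, (fan_in, c_out), fan_in))
        self.bias = _param(np.zeros(c_out))
        self.ksize, self.stride, self.pad = ksize, stride, pad
        self.c_out = c_out

    def forward(self, x: Tensor) -> Tensor:
        cols, oh, ow = x.im2col(self.ksize, self.stride, self.pad)
        y = cols @ self.weight + self.bias          # (B, oh*ow, c_out)
        B = x.shape[0]
        return y.reshape(B, oh, ow, self.c_out).transpose(0, 3, 1, 2)


class ResidualBlock(Module):
    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2d(channels, channels, 3, rng)
        self.conv2 = Conv2d(channels, channels, 3, rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self.conv1(x).relu()
        h = self.conv2(h)
        return (h + x).relu()


class ResNetBackbone(Module):
    """Residual CNN over RGB patches → global-average-pooled feature vector.

    ``stage_channels``/``blocks_per_stage`` define the depth; each stage opens
    with a stride-2 convolution.  Presets:

    - ``tiny``     — 2 stages (16, 32), one block each; 32-d features.  The
      desk-scale profile every test uses.
    - ``resnet18`` — 4 stages (64, 128, 256, 512), two blocks each; 512-d
      features, the production default for real slides.
    """

    def __init__(self, stage_channels, blocks_per_stage, rng: np.random.Generator):
        super().__init__()
        self.feature_dim = stage_channels[-1]
        self.stage_channels = tuple(stage_channels)
        self.blocks_per_stage = tuple(blocks_per_stage)
        layers: list[Module] = []
        c_prev = 3
        for c, nblocks in zip(stage_channels, blocks_per_stage):
            layers.append(Conv2d(c_prev, c, 3, rng, stride=2))
            for _ in range(nblocks):
                layers.append(ResidualBlock(c, rng))
            c_prev = c
        for i, layer in enumerate(layers):
            setattr(self, f"layer{i}", layer)
        self._layers = layers

    def forward(self, x: Tensor) -> Tensor:
        h = x
        for i, layer in enumerate(self._layers):
            h = layer(h) if isinstance(layer, ResidualBlock) else layer(h).relu()
        # global average pool over the spatial grid
        return h.mean(axis=(2, 3))

    @classmethod
    def preset(cls, name: str, rng: np.random.Generator) -> "ResNetBackbone":
        presets = {
            "tiny": ((16, 32), (1, 1)),
            "resnet18": ((64, 128, 256, 512), (2, 2, 2, 2)),
        }
        if name not in presets:
            raise ValueError(f"unknown backbone preset {name!r}; choose from {sorted(presets)}")
        channels, blocks = presets[name]
        return cls(channels, blocks, rng)


class MLP(Module):
    """Two dense layers with a nonlinearity in between."""

    def __init__(self, d_in: int, d_hidden: int, d_out: int, rng, activation: str = "gelu"):
        super().__init__()
        self.fc1 = Linear(d_in, d_hidden, rng)
        self.fc2 = Linear(d_hidden, d_out, rng)
        self.activation = activation

    def forward(self, x: Tensor) -> Tensor:
        h = self.fc1(x)
        h = h.gelu() if self.activation == "gelu" else h.relu()
        return self.fc2(h)


# ------------------------------------------------------------------- optimiser
class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


# ------------------------------------------------------------------- schedules
def step_decay_lr(step: int, milestones=(30, 100), lrs=(1e-3, 1e-4, 1e-5)) -> float:
    """Piecewise-constant decay: lrs[0] until the first milestone, etc."""
    lr = lrs[0]
    for ms, v in zip(milestones, lrs[1:]):
        if step >= ms:
            lr = v
    return lr


def cosine_annealing_lr(step: int, total_steps: int, lr_max: float, lr_min: float = 0.0) -> float:
    if total_steps <= 1:
        return lr_max
    frac = min(step, total_steps - 1) / (total_steps - 1)
    return lr_min + 0.5 * (lr_max - lr_min) * (1 + math.cos(math.pi * frac))


def cross_entropy(logits: Tensor, label: int) -> Tensor:
    """Negative log-likelihood of ``label`` under softmax(logits) (1-D logits)."""
    logp = logits.log_softmax(axis=-1)
    return -logp[int(label)]
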