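"""Layers and building blocks for the 1-D encoder–decoder network.

Includes the squeeze-and-excitation (SE) channel attention, its recurrent
SE-GRU variant in which the per-channel descriptors are scanned by a
from-scratch GRU cell, and the plain / residual / sparse-residual
convolutional blocks used in the ablation grid.

The GRU gates follow the textbook formulation

    r_t = sigmoid(W_r [h_{t-1}, x_t] + b_r)
    z_t = sigmoid(W_z [h_{t-1}, x_t] + b_z)
    h~_t = tanh(W [r_t * h_{t-1}, x_t] + b)
    h_t = (1 - z_t) * h_{t-1} + z_t * h~_t

implemented literally rather than delegating to a framework cell, so the
update-gate convention is exactly the one above.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, batch_norm, concat

__all__ = [
    "Module",
    "ModuleList",
    "Conv1d",
    "ConvTranspose1d",
    "Linear",
    "BatchNorm1d",
    "GRUCell",
    "gru_step",
    "squeeze",
    "se_apply",
    "SEBlock",
    "SEGRUBlock",
    "PlainSkip",
    "PlainBlock",
    "ResidualBlock",
    "SparseResidualBlock",
    "make_block",
    "make_skip",
]


class Module:
    """Tiny module base: parameter/buffer registration and train/eval mode."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for n, p in self._params.items():
            yield f"{prefix}{n}", p
        for n, m in self._modules.items():
            yield from m.named_parameters(f"{prefix}{n}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for n, b in self._buffers.items():
            yield f"{prefix}{n}", b
        for n, m in self._modules.items():
            yield from m.named_buffers(f"{prefix}{n}.")

    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._list: list[Module] = []
        for m in modules:
            self.append(m)

    def append(self, m: Module):
        setattr(self, str(len(self._list)), m)
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __getitem__(self, i):
        return self._list[i]

    def __len__(self):
        return len(self._list)


def _param(rng: np.random.Generator, shape, scale: float) -> Tensor:
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


class Conv1d(Module):
    """Stride-1 'same' 1-D convolution (He-initialized)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.pad = kernel // 2
        self.weight = _param(rng, (out_ch, in_ch, kernel), np.sqrt(2.0 / (in_ch * kernel)))
        self.bias = (
            Tensor(np.zeros(out_ch), requires_grad=True) if bias else None
        )

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv1d(self.weight, self.bias, pad=self.pad)


class ConvTranspose1d(Module):
    """Kernel-2 stride-2 transposed convolution: doubles the length."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.weight = _param(rng, (in_ch, out_ch, 2), np.sqrt(2.0 / (in_ch * 2)))
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv_transpose1d(self.weight, self.bias)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.weight = _param(rng, (in_f, out_f), np.sqrt(2.0 / in_f))
        self.bias = Tensor(np.zeros(out_f), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class BatchNorm1d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.register_buffer("running_mean", np.zeros(channels))
        self.register_buffer("running_var", np.ones(channels))

    def __call__(self, x: Tensor) -> Tensor:
        return batch_norm(
            x, self.gamma, self.beta, self.running_mean, self.running_var,
            training=self.training, momentum=self.momentum, eps=self.eps,
        )


def gru_step(
    x_t: Tensor,
    h_prev: Tensor,
    W_r: Tensor, W_z: Tensor, W: Tensor,
    b_r: Tensor, b_z: Tensor, b: Tensor,
) -> Tensor:
    """One GRU step with the gate equations written out explicitly.

    ``x_t``: [batch, input], ``h_prev``: [batch, hidden]; weight matrices
    act on the concatenation ``[h_{t-1}, x_t]`` (shape [hidden+input,
    hidden]).
    """
    hx = concat([h_prev, x_t], axis=1)
    r_t = (hx @ W_r + b_r).sigmoid()
    z_t = (hx @ W_z + b_z).sigmoid()
    rhx = concat([r_t * h_prev, x_t], axis=1)
    h_tilde = (rhx @ W + b).tanh()
    return (1.0 - z_t) * h_prev + z_t * h_tilde


class GRUCell(Module):
    """GRU cell parameters; the recurrence itself lives in :func:`gru_step`."""

    def __init__(self, input_size: int, hidden_size: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.input_size = input_size
        self.hidden_size = hidden_size
        k = np.sqrt(1.0 / hidden_size)
        shape = (hidden_size + input_size, hidden_size)
        self.W_r = Tensor(rng.uniform(-k, k, shape), requires_grad=True)
        self.W_z = Tensor(rng.uniform(-k, k, shape), requires_grad=True)
        self.W = Tensor(rng.uniform(-k, k, shape), requires_grad=True)
        self.b_r = Tensor(np.zeros(hidden_size), requires_grad=True)
        self.b_z = Tensor(np.zeros(hidden_size), requires_grad=True)
        self.b = Tensor(np.zeros(hidden_size), requires_grad=True)

    def step(self, x_t: Tensor, h_prev: Tensor) -> Tensor:
        return gru_step(x_t, h_prev, self.W_r, self.W_z, self.W,
                        self.b_r, self.b_z, self.b)


def squeeze(x: Tensor) -> Tensor:
    """Global average pooling over length: [B,C,L] -> [B,C]."""
    return x.mean(axis=2)


def se_apply(x: Tensor, s: Tensor) -> Tensor:
    """Scale each channel of [B,C,L] by its weight in s [B,C] (or [C])."""
    if s.ndim == 1:
        s = s.reshape((1, s.shape[0], 1))
    else:
        s = s.reshape((s.shape[0], s.shape[1], 1))
    return x * s


class PlainSkip(Module):
    """Identity skip connection (no channel attention)."""

    def __call__(self, x: Tensor) -> Tensor:
        return x


class SEBlock(Module):
    """Squeeze-and-excitation: squeeze -> FC(C->C/r) -> ReLU -> FC -> sigmoid."""

    def __init__(self, channels: int, reduction: int = 8,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if channels % reduction != 0:
            raise ValueError(f"reduction {reduction} must divide channels {channels}")
        rng = rng or np.random.default_rng()
        self.fc1 = Linear(channels, channels // reduction, rng)
        self.fc2 = Linear(channels // reduction, channels, rng)

    def weights(self, x: Tensor) -> Tensor:
        z = squeeze(x)
        return self.fc2(self.fc1(z).relu()).sigmoid()

    def __call__(self, x: Tensor) -> Tensor:
        return se_apply(x, self.weights(x))


class SEGRUBlock(Module):
    """SE attention with a GRU excitation stage.

    The length-C channel descriptor from the squeeze step is scanned as a
    sequence of scalar inputs by a GRU with hidden size C/r; each hidden
    state is projected to one scalar and squashed by a sigmoid, yielding the
    per-channel weights.  The recurrence makes the weights order-sensitive,
    unlike the feed-forward SE excitation.
    """

    def __init__(self, channels: int, reduction: int = 8,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if channels % reduction != 0:
            raise ValueError(f"reduction {reduction} must divide channels {channels}")
        rng = rng or np.random.default_rng()
        self.channels = channels
        self.gru = GRUCell(1, channels // reduction, rng)
        self.proj = Linear(channels // reduction, 1, rng)

    def weights(self, x: Tensor) -> Tensor:
        z = squeeze(x)  # [B, C]
        B = z.shape[0]
        h = Tensor(np.zeros((B, self.gru.hidden_size)))
        outs = []
        for t in range(self.channels):
            h = self.gru.step(z[:, t:t + 1], h)
            outs.append(self.proj(h).sigmoid())
        return concat(outs, axis=1)  # [B, C]

    def __call__(self, x: Tensor) -> Tensor:
        return se_apply(x, self.weights(x))


class PlainBlock(Module):
    """Two conv-BN-ReLU stages (ordinary convolutional unit)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.conv1 = Conv1d(in_ch, out_ch, kernel, rng=rng)
        self.bn1 = BatchNorm1d(out_ch)
        self.conv2 = Conv1d(out_ch, out_ch, kernel, rng=rng)
        self.bn2 = BatchNorm1d(out_ch)

    def __call__(self, x: Tensor) -> Tensor:
        y = self.bn1(self.conv1(x)).relu()
        return self.bn2(self.conv2(y)).relu()


class _Projection(Module):
    """1x1 convolution used when the additive skip changes channel count."""

    def __init__(self, in_ch: int, out_ch: int, rng=None):
        super().__init__()
        self.conv = Conv1d(in_ch, out_ch, kernel=1, bias=False, rng=rng) \
            if in_ch != out_ch else None

    def __call__(self, x: Tensor) -> Tensor:
        return x if self.conv is None else self.conv(x)


class ResidualBlock(Module):
    """Ordinary residual unit: y = F(x) + h(x), out = activation(y)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.conv1 = Conv1d(in_ch, out_ch, kernel, rng=rng)
        self.bn1 = BatchNorm1d(out_ch)
        self.conv2 = Conv1d(out_ch, out_ch, kernel, rng=rng)
        self.bn2 = BatchNorm1d(out_ch)
        self.proj = _Projection(in_ch, out_ch, rng)

    def __call__(self, x: Tensor) -> Tensor:
        f = self.bn2(self.conv2(self.bn1(self.conv1(x)).relu()))
        return (f + self.proj(x)).relu()


class SparseResidualBlock(Module):
    """Sparse residual unit: an additive skip after every conv+BN stage.

    Encoder variant: two conv+BN stages, each closed by its own skip
    (y1 = BN(conv(x)) + x, y2 = BN(conv(y1)) + y1, out = ReLU(y2)).
    Decoder variant: a single conv+BN stage with one skip.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3,
                 variant: str = "encoder", rng: np.random.Generator | None = None):
        super().__init__()
        if variant not in ("encoder", "decoder"):
            raise ValueError(f"unknown variant {variant!r}")
        self.variant = variant
        self.conv1 = Conv1d(in_ch, out_ch, kernel, rng=rng)
        self.bn1 = BatchNorm1d(out_ch)
        self.proj = _Projection(in_ch, out_ch, rng)
        if variant == "encoder":
            self.conv2 = Conv1d(out_ch, out_ch, kernel, rng=rng)
            self.bn2 = BatchNorm1d(out_ch)

    def __call__(self, x: Tensor) -> Tensor:
        y1 = self.bn1(self.conv1(x)) + self.proj(x)
        if self.variant == "decoder":
            return y1.relu()
        y2 = self.bn2(self.conv2(y1)) + y1
        return y2.relu()


def make_block(block_type: str, in_ch: int, out_ch: int, kernel: int,
               variant: str, rng: np.random.Generator) -> Module:
    if block_type == "plain":
        return PlainBlock(in_ch, out_ch, kernel, rng)
    if block_type == "residual":
        return ResidualBlock(in_ch, out_ch, kernel, rng)
    if block_type == "sparse_residual":
        return SparseResidualBlock(in_ch, out_ch, kernel, variant, rng)
    raise ValueError(f"unknown block_type {block_type!r}")


def make_skip(skip_type: str, channels: int, reduction: int,
              rng: np.random.Generator) -> Module:
    if skip_type == "plain":
        return PlainSkip()
    if skip_type == "se":
        return SEBlock(channels, reduction, rng)
    if skip_type == "se_gru":
        return SEGRUBlock(channels, reduction, rng)
    raise ValueError(f"unknown skip_type {skip_type!r}")
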