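"""Neural-network layers built on :mod:`fundusgan.nd.tensor`.

Modules follow the familiar container pattern: parameters are
:class:`~fundusgan.nd.tensor.Tensor` leaves with ``requires_grad=True``,
``named_parameters`` walks submodules recursively, and ``train()`` /
``eval()`` toggle normalization behaviour. Weight initialization is
zero-mean Gaussian with std 0.02 drawn from an explicit
``numpy.random.Generator`` so every build is seedable.
"""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor

INIT_STD = 0.02


class Module:
    def __init__(self):
        self.training = True

    # -- parameter / buffer traversal ----------------------------------------
    @staticmethod
    def _walk(name: str, value):
        """Yield (qualified name, leaf) for Tensors, arrays and Modules,
        recursing through arbitrarily nested lists/tuples."""
        if isinstance(value, (Tensor, np.ndarray, Module)):
            yield name, value
        elif isinstance(value, (list, tuple)):
            for i, item in enumerate(value):
                yield from Module._walk(f"{name}.{i}", item)

    def _leaves(self, prefix: str = ""):
        for name, value in vars(self).items():
            yield from Module._walk(f"{prefix}{name}", value)

    def named_parameters(self, prefix: str = ""):
        for name, leaf in self._leaves(prefix):
            if isinstance(leaf, Tensor):
                yield name, leaf
            elif isinstance(leaf, Module):
                yield from leaf.named_parameters(f"{name}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, leaf in self._leaves(prefix):
            if isinstance(leaf, np.ndarray):
                yield name, leaf
            elif isinstance(leaf, Module):
                yield from leaf.named_buffers(f"{name}.")

    def modules(self):
        yield self
        for _, leaf in self._leaves():
            if isinstance(leaf, Module):
                yield from leaf.modules()

    # -- mode / grad management ----------------------------------------------
    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # -- (de)serialization ----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param:{k}": v.data for k, v in self.named_parameters()}
        state.update({f"buffer:{k}": v for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for key, value in state.items():
            kind, _, name = key.partition(":")
            if kind == "param":
                params[name].data = np.asarray(value, dtype=np.float32)
            else:
                # locate the owning module and overwrite the buffer in place
                obj: Module | list = self
                parts = name.split(".")
                for part in parts[:-1]:
                    obj = obj[int(part)] if isinstance(obj, (list, tuple)) else getattr(obj, part)
                setattr(obj, parts[-1], np.asarray(value, dtype=np.float32))

    def __call__(self, *args):
        return self.forward(*args)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, pad: int = 0, bias: bool = True):
        super().__init__()
        self.stride, self.pad = stride, pad
        self.weight = Tensor(
            rng.normal(0.0, INIT_STD, size=(out_ch, in_ch, kernel, kernel)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return T.conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class Norm2d(Module):
    """Per-channel feature normalization with learned affine parameters.

    Statistics are taken over the batch and spatial axes, which at the
    default batch size of 1 reduces to instance-style normalization.
    Running estimates accumulated during training are used in eval mode
    so inference is deterministic.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        gamma, beta = self.gamma, self.beta
        axes = (0, 2, 3)
        if self.training:
            mu = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu[None, :, None, None]) * ivar[None, :, None, None]
        out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
        m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
        training = self.training

        def backward(g):
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=axes))
            if beta.requires_grad:
                beta._accum(g.sum(axis=axes))
            if x.requires_grad:
                dxhat = g * gamma.data[None, :, None, None]
                iv = ivar[None, :, None, None]
                if training:
                    t1 = dxhat.sum(axis=axes, keepdims=True)
                    t2 = (dxhat * xhat).sum(axis=axes, keepdims=True)
                    x._accum(iv / m * (m * dxhat - t1 - xhat * t2))
                else:
                    x._accum(dxhat * iv)

        return Tensor._op(out.astype(np.float32), (x, gamma, beta), backward)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return T.relu(x)


class LeakyReLU(Module):
    def __init__(self, negative_slope: float = 0.2):
        super().__init__()
        self.negative_slope = negative_slope

    def forward(self, x: Tensor) -> Tensor:
        return T.leaky_relu(x, self.negative_slope)


class Tanh(Module):
    def forward(self, x: Tensor) -> Tensor:
        return T.tanh(x)


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return T.sigmoid(x)


class UpsampleNearest2(Module):
    def forward(self, x: Tensor) -> Tensor:
        return T.upsample_nearest2(x)


class ResidualBlock(Module):
    """x + F(x) with F = conv3-norm-ReLU, conv3-norm (Fig-style two-conv branch).

    With every branch parameter zeroed the block is an exact identity map.
    """

    def __init__(self, channels: int, rng: np.random.Generator, norm: bool = True):
        super().__init__()
        self.conv1 = Conv2d(channels, channels, 3, rng, pad=1)
        self.norm1 = Norm2d(channels) if norm else None
        self.conv2 = Conv2d(channels, channels, 3, rng, pad=1)
        self.norm2 = Norm2d(channels) if norm else None

    def forward(self, x: Tensor) -> Tensor:
        h = self.conv1(x)
        if self.norm1 is not None:
            h = self.norm1(h)
        h = T.relu(h)
        h = self.conv2(h)
        if self.norm2 is not None:
            h = self.norm2(h)
        return T.add(x, h)
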