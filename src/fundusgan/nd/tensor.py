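"""Reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps a float32 ndarray and records the operations
applied to it; :meth:`Tensor.backward` walks the recorded graph in
reverse topological order and accumulates gradients into ``.grad``.
Only the small set of operations needed by the image-translation
networks is provided (elementwise arithmetic, activations, 2-D
convolution via im2col, nearest-neighbour upsampling, channel
concatenation, reductions). All gradients are checked against finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "add",
    "sub",
    "mul",
    "scale",
    "square",
    "abs_",
    "log",
    "relu",
    "leaky_relu",
    "tanh",
    "sigmoid",
    "mean_all",
    "conv2d",
    "upsample_nearest2",
    "concat_channels",
]

# sigmoid outputs are clamped into the open interval (0,1) by this margin so
# that downstream log-losses stay finite even when the pre-activation saturates
SIGMOID_EPS = 1e-6


class Tensor:
    """A float32 array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _op(data: np.ndarray, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    # -- basic protocol -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    # -- autograd -------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate d(self)/d(leaf) into every reachable leaf's ``.grad``."""
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("backward() without gradient on non-scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
        # free the tape so intermediate buffers can be collected
        for node in topo:
            if node is not self:
                node._parents = ()
                node._backward = None

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    # operator sugar
    def __add__(self, other):
        return add(self, as_tensor(other))

    def __sub__(self, other):
        return sub(self, as_tensor(other))

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            return scale(self, float(other))
        return mul(self, other)

    __rmul__ = __mul__


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# elementwise ops
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    if a.data.shape != b.data.shape:
        raise ValueError(f"shape mismatch in add: {a.data.shape} vs {b.data.shape}")

    def backward(g):
        if a.requires_grad:
            a._accum(g)
        if b.requires_grad:
            b._accum(g)

    return Tensor._op(a.data + b.data, (a, b), backward)


def sub(a: Tensor, b: Tensor) -> Tensor:
    if a.data.shape != b.data.shape:
        raise ValueError(f"shape mismatch in sub: {a.data.shape} vs {b.data.shape}")

    def backward(g):
        if a.requires_grad:
            a._accum(g)
        if b.requires_grad:
            b._accum(-g)

    return Tensor._op(a.data - b.data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    if a.data.shape != b.data.shape:
        raise ValueError(f"shape mismatch in mul: {a.data.shape} vs {b.data.shape}")

    def backward(g):
        if a.requires_grad:
            a._accum(g * b.data)
        if b.requires_grad:
            b._accum(g * a.data)

    return Tensor._op(a.data * b.data, (a, b), backward)


def scale(a: Tensor, s: float) -> Tensor:
    def backward(g):
        a._accum(g * s)

    return Tensor._op(a.data * np.float32(s), (a,), backward)


def square(a: Tensor) -> Tensor:
    def backward(g):
        a._accum(g * (2.0 * a.data))

    return Tensor._op(a.data * a.data, (a,), backward)


def abs_(a: Tensor) -> Tensor:
    def backward(g):
        a._accum(g * np.sign(a.data))

    return Tensor._op(np.abs(a.data), (a,), backward)


def log(a: Tensor) -> Tensor:
    if np.any(a.data <= 0):
        raise ValueError("log() requires strictly positive input")
    out_data = np.log(a.data)

    def backward(g):
        a._accum(g / a.data)

    return Tensor._op(out_data, (a,), backward)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def backward(g):
        a._accum(g * mask)

    return Tensor._op(a.data * mask, (a,), backward)


def leaky_relu(a: Tensor, negative_slope: float = 0.2) -> Tensor:
    factor = np.where(a.data > 0, np.float32(1.0), np.float32(negative_slope))

    def backward(g):
        a._accum(g * factor)

    return Tensor._op(a.data * factor, (a,), backward)


def tanh(a: Tensor) -> Tensor:
    y = np.tanh(a.data)

    def backward(g):
        a._accum(g * (1.0 - y * y))

    return Tensor._op(y, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    """Logistic sigmoid clamped to (SIGMOID_EPS, 1 - SIGMOID_EPS)."""
    with np.errstate(over="ignore"):
        y = 1.0 / (1.0 + np.exp(-a.data))
    y = np.clip(y, SIGMOID_EPS, 1.0 - SIGMOID_EPS).astype(np.float32)

    def backward(g):
        a._accum(g * y * (1.0 - y))

    return Tensor._op(y, (a,), backward)


def mean_all(a: Tensor) -> Tensor:
    n = a.data.size

    def backward(g):
        a._accum(np.full_like(a.data, g / n))

    return Tensor._op(np.asarray(a.data.mean(), dtype=np.float32), (a,), backward)


# ---------------------------------------------------------------------------
# spatial ops (NCHW layout)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (w + 2 * pad - kw) // stride + 1
    cols = np.empty((n, c, kh, kw, ho, wo), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = x[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
    return cols.reshape(n, c * kh * kw, ho * wo), (ho, wo)


def _col2im(dcols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int, ho: int, wo: int):
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    dx = np.zeros((n, c, hp, wp), dtype=dcols.dtype)
    d6 = dcols.reshape(n, c, kh, kw, ho, wo)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += d6[:, :, i, j]
    if pad:
        dx = dx[:, :, pad : hp - pad, pad : wp - pad]
    return dx


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D cross-correlation, NCHW input, OIHW weights."""
    cout, cin, kh, kw = w.data.shape
    n, c, h, w_ = x.data.shape
    if c != cin:
        raise ValueError(f"conv2d channel mismatch: input has {c}, weight expects {cin}")
    cols, (ho, wo) = _im2col(x.data, kh, kw, stride, pad)
    wmat = w.data.reshape(cout, cin * kh * kw)
    out = np.matmul(wmat[None], cols)  # (n, cout, ho*wo)
    if b is not None:
        out += b.data.reshape(1, cout, 1)
    out = out.reshape(n, cout, ho, wo)

    def backward(g):
        gmat = g.reshape(n, cout, ho * wo)
        if w.requires_grad:
            dw = np.matmul(gmat, cols.transpose(0, 2, 1)).sum(axis=0)
            w._accum(dw.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = np.matmul(wmat.T[None], gmat)
            x._accum(_col2im(dcols, x.data.shape, kh, kw, stride, pad, ho, wo))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._op(out, parents, backward)


def upsample_nearest2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        x._accum(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    return Tensor._op(out, (x,), backward)


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    if a.data.shape[0] != b.data.shape[0] or a.data.shape[2:] != b.data.shape[2:]:
        raise ValueError("concat_channels requires matching batch and spatial dims")
    ca = a.data.shape[1]

    def backward(g):
        if a.requires_grad:
            a._accum(g[:, :ca])
        if b.requires_grad:
            b._accum(g[:, ca:])

    return Tensor._op(np.concatenate([a.data, b.data], axis=1), (a, b), backward)
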