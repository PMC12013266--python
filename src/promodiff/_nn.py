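"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This is the numerical substrate for the package's three small networks (the
diffusion noise predictor, the transformer strength regressor and the CNN
baseline).  It implements exactly the operations those models need — broadcast
arithmetic, batched matmul, embedding lookup, window gathering for 1-D
convolution, softmax, layer norm and a handful of reductions — with a
tape-based backward pass and an Adam optimizer.

The engine is deliberately eager and single-threaded; model sizes in this
package are tiny (tens of thousands of parameters) and CPU-bound NumPy matmul
dominates the runtime.  All computation is float32: at these problem sizes the
arrays are memory-bandwidth bound and single precision is ample for training.
Runs are bit-reproducible on one machine for a fixed seed.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Adam",
    "Linear",
    "Embedding",
    "LayerNorm",
    "Conv1d",
    "relu",
    "softmax",
    "dropout",
    "no_grad",
]

DTYPE = np.float32

_GRAD_ENABLED = True


def _noop() -> None:
    return None


class no_grad:
    """Context manager disabling tape construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A NumPy array plus a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[], None] = _noop
        self._prev: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(np.broadcast_to(g, self.data.shape), dtype=DTYPE)
        else:
            self.grad += g

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data: np.ndarray, parents: tuple["Tensor", ...]) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out._prev = tuple(p for p in parents if p.requires_grad) if out.requires_grad else ()
        return out

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = self._wrap(other)
        out = self._make(self.data + other.data, (self, other))

        def backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = self._make(-self.data, (self,))

        def backward():
            self._accum(-out.grad)

        out._backward = backward
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-self._wrap(other))

    def __rsub__(self, other) -> "Tensor":
        return self._wrap(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._wrap(other)
        out = self._make(self.data * other.data, (self, other))

        def backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._wrap(other)
        out = self._make(self.data / other.data, (self, other))

        def backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad / other.data, self.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-out.grad * self.data / other.data**2, other.shape)
                )

        out._backward = backward
        return out

    def __matmul__(self, other) -> "Tensor":
        other = self._wrap(other)
        out = self._make(self.data @ other.data, (self, other))

        def backward():
            g = out.grad
            if self.requires_grad:
                if other.data.ndim == 1:
                    ga = np.multiply.outer(g, other.data)
                else:
                    ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                if self.data.ndim == 1:
                    gb = np.multiply.outer(self.data, g)
                else:
                    gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.shape))

        out._backward = backward
        return out

    def pow(self, exponent: float) -> "Tensor":
        out = self._make(self.data**exponent, (self,))

        def backward():
            self._accum(out.grad * exponent * self.data ** (exponent - 1))

        out._backward = backward
        return out

    def sqrt(self) -> "Tensor":
        out = self._make(np.sqrt(self.data), (self,))

        def backward():
            self._accum(out.grad * 0.5 / out.data)

        out._backward = backward
        return out

    def abs(self) -> "Tensor":
        out = self._make(np.abs(self.data), (self,))

        def backward():
            self._accum(out.grad * np.sign(self.data))

        out._backward = backward
        return out

    # -- shape ops ------------------------------------------------------------

    def reshape(self, *shape: int) -> "Tensor":
        out = self._make(self.data.reshape(*shape), (self,))

        def backward():
            self._accum(out.grad.reshape(self.shape))

        out._backward = backward
        return out

    def transpose(self, *axes: int) -> "Tensor":
        out = self._make(self.data.transpose(*axes), (self,))
        inverse = np.argsort(axes)

        def backward():
            self._accum(out.grad.transpose(*inverse))

        out._backward = backward
        return out

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def backward():
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- autodiff driver ------------------------------------------------------

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
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
            for parent in node._prev:
                stack.append((parent, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            node._backward()
        # Backward closures capture their output tensors, forming reference
        # cycles; break them so intermediates are freed by refcounting
        # immediately instead of waiting for the cyclic collector.
        for node in topo:
            node._backward = _noop
            node._prev = ()

    def item(self) -> float:
        return float(self.data)


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


# ---------------------------------------------------------------------------
# functional ops


def relu(x: Tensor) -> Tensor:
    out = x._make(np.maximum(x.data, 0.0), (x,))

    def backward():
        x._accum(out.grad * (x.data > 0))

    out._backward = backward
    return out


def softmax(x: Tensor) -> Tensor:
    """Softmax over the last axis."""
    z = x.data - x.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=-1, keepdims=True)
    out = x._make(s, (x,))

    def backward():
        g = out.grad
        x._accum(s * (g - (g * s).sum(axis=-1, keepdims=True)))

    out._backward = backward
    return out


def dropout(x: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    if rate <= 0.0:
        return x
    keep = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * Tensor(keep)


def embedding_lookup(table: Tensor, tokens: np.ndarray) -> Tensor:
    """table[(tokens)] with scatter-add backward; tokens is an int array."""
    tokens = np.asarray(tokens)
    out = table._make(table.data[tokens], (table,))

    def backward():
        if table.grad is None:
            table.grad = np.zeros_like(table.data)
        np.add.at(
            table.grad,
            tokens.reshape(-1),
            out.grad.reshape(-1, table.data.shape[-1]),
        )

    out._backward = backward
    return out


def gather_windows(x: Tensor, idx: np.ndarray) -> Tensor:
    """x[:, idx, :] for idx of shape (L_out, K): im2col for 1-D convolution."""
    out = x._make(x.data[:, idx, :], (x,))

    def backward():
        if x.grad is None:
            x.grad = np.zeros_like(x.data)
        np.add.at(x.grad, (slice(None), idx), out.grad)

    out._backward = backward
    return out


def pad_length(x: Tensor, pad: int) -> Tensor:
    """Zero-pad axis 1 of a (B, L, C) tensor by ``pad`` on both sides."""
    if pad == 0:
        return x
    b, length, c = x.shape
    data = np.zeros((b, length + 2 * pad, c))
    data[:, pad : pad + length, :] = x.data
    out = x._make(data, (x,))

    def backward():
        x._accum(out.grad[:, pad : pad + length, :])

    out._backward = backward
    return out


# ---------------------------------------------------------------------------
# layers


class Module:
    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for value in self.__dict__.values():
            if isinstance(value, Parameter):
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state size mismatch")
        for p, s in zip(params, state):
            p.data = np.array(s, dtype=DTYPE)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = math.sqrt(1.0 / d_in)
        self.weight = Parameter(rng.uniform(-scale, scale, size=(d_in, d_out)))
        self.bias = Parameter(np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Embedding(Module):
    def __init__(self, n_tokens: int, d_model: int, rng: np.random.Generator):
        self.weight = Parameter(rng.normal(0.0, 0.02, size=(n_tokens, d_model)))

    def __call__(self, tokens: np.ndarray) -> Tensor:
        return embedding_lookup(self.weight, tokens)


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(d))
        self.beta = Parameter(np.zeros(d))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.data.mean(axis=-1, keepdims=True)
        var = x.data.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu) * inv
        out = x._make(xhat * self.gamma.data + self.beta.data, (x, self.gamma, self.beta))
        gamma, beta, eps = self.gamma, self.beta, self.eps

        def backward():
            g = out.grad
            d = x.shape[-1]
            if gamma.requires_grad:
                gamma._accum((g * xhat).reshape(-1, d).sum(axis=0))
            if beta.requires_grad:
                beta._accum(g.reshape(-1, d).sum(axis=0))
            if x.requires_grad:
                gx = g * gamma.data
                x._accum(
                    inv
                    * (
                        gx
                        - gx.mean(axis=-1, keepdims=True)
                        - xhat * (gx * xhat).mean(axis=-1, keepdims=True)
                    )
                )

        out._backward = backward
        return out


class Conv1d(Module):
    """Same-padding 1-D convolution over (batch, length, channels) tensors."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.kernel = kernel
        scale = math.sqrt(1.0 / (c_in * kernel))
        self.weight = Parameter(rng.uniform(-scale, scale, size=(kernel * c_in, c_out)))
        self.bias = Parameter(np.zeros(c_out))
        self._idx_cache: dict[int, np.ndarray] = {}

    def _window_index(self, length: int) -> np.ndarray:
        idx = self._idx_cache.get(length)
        if idx is None:
            idx = np.arange(length)[:, None] + np.arange(self.kernel)[None, :]
            self._idx_cache[length] = idx
        return idx

    def __call__(self, x: Tensor) -> Tensor:
        b, length, c = x.shape
        pad = self.kernel // 2
        cols = gather_windows(pad_length(x, pad), self._window_index(length))
        cols = cols.reshape(b, length, self.kernel * c)
        return cols @ self.weight + self.bias


class Adam:
    """Adam with bias correction; deterministic given parameter order."""

    def __init__(
        self,
        params: Iterable[Parameter],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
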