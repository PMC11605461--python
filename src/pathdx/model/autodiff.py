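"""Minimal reverse-mode automatic differentiation over NumPy arrays.

A :class:`Tensor` wraps an ndarray and records the operations producing it on
an implicit tape (the parent graph); ``backward()`` topologically sorts the
graph and accumulates gradients. Only the operations needed by the transformer
are implemented, with attention-critical primitives (softmax, layer norm,
GELU, cross-entropy) fused for numerical stability and speed.

Gradient correctness is enforced by finite-difference checks in the test
suite.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

Array = np.ndarray


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data: Array | float,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        backward: Callable[[Array], None] | None = None,
    ):
        self.data = np.asarray(data)
        self.grad: Array | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # -- graph ---------------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accumulate(self, grad: Array) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=self.data.dtype)
        else:
            self.grad += grad

    def backward(self, grad: Array | None = None) -> None:
        """Backpropagate from this tensor (defaults to d(self)/d(self)=1)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- ops -----------------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other) -> "Tensor":
        other = self._lift(other)
        out_data = self.data + other.data

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor(-self.data, parents=(self,), backward=bwd)

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)
        out_data = self.data * other.data

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    __rmul__ = __mul__

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        out_data = self.data @ other.data

        def bwd(g: Array) -> None:
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2) if other.data.ndim > 1 else np.outer(g, other.data).reshape(self.shape)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                if self.data.ndim == 1:
                    gb = np.outer(self.data, g).reshape(other.shape)
                else:
                    gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    __matmul__ = matmul

    def reshape(self, *shape: int) -> "Tensor":
        out_data = self.data.reshape(*shape)
        orig = self.shape

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g.reshape(orig))

        return Tensor(out_data, parents=(self,), backward=bwd)

    def swapaxes(self, a: int, b: int) -> "Tensor":
        out_data = np.swapaxes(self.data, a, b)

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(np.swapaxes(g, a, b))

        return Tensor(out_data, parents=(self,), backward=bwd)

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.shape

        def bwd(g: Array) -> None:
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, shape).copy())

        return Tensor(out_data, parents=(self,), backward=bwd)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def take0(self, index: int = 0) -> "Tensor":
        """Select position ``index`` along axis 1 (e.g. the [CLS] slot)."""
        out_data = self.data[:, index]

        def bwd(g: Array) -> None:
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[:, index] = g
                self._accumulate(full)

        return Tensor(out_data, parents=(self,), backward=bwd)


def gather(weight: Tensor, indices: Array) -> Tensor:
    """Row lookup ``weight[indices]`` (embedding)."""
    idx = np.asarray(indices)
    out_data = weight.data[idx]

    def bwd(g: Array) -> None:
        if weight.requires_grad:
            full = np.zeros_like(weight.data)
            np.add.at(full, idx, g)
            weight._accumulate(full)

    return Tensor(out_data, parents=(weight,), backward=bwd)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def bwd(g: Array) -> None:
        if x.requires_grad:
            dot = (g * y).sum(axis=axis, keepdims=True)
            x._accumulate(y * (g - dot))

    return Tensor(y, parents=(x,), backward=bwd)


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-6) -> Tensor:
    """Layer normalisation over the last axis."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    y = gain.data * xhat + bias.data

    def bwd(g: Array) -> None:
        if bias.requires_grad:
            bias._accumulate(_unbroadcast(g, bias.shape))
        if gain.requires_grad:
            gain._accumulate(_unbroadcast(g * xhat, gain.shape))
        if x.requires_grad:
            n = x.data.shape[-1]
            gx = g * gain.data
            dx = inv * (
                gx
                - gx.mean(axis=-1, keepdims=True)
                - xhat * (gx * xhat).mean(axis=-1, keepdims=True)
            )
            x._accumulate(dx)

    return Tensor(y, parents=(x, gain, bias), backward=bwd)


_GELU_C = float(np.sqrt(2.0 / np.pi))


def gelu(x: Tensor) -> Tensor:
    """GELU activation (tanh approximation)."""
    d = x.data
    x2 = d * d
    t = np.tanh(_GELU_C * d * (1.0 + 0.044715 * x2))
    y = 0.5 * d * (1.0 + t)

    def bwd(g: Array) -> None:
        if x.requires_grad:
            du = _GELU_C * (1.0 + 0.134145 * x2)
            dy = 0.5 * (1.0 + t) + 0.5 * d * (1.0 - t * t) * du
            x._accumulate(g * dy)

    return Tensor(y, parents=(x,), backward=bwd)


def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-np.clip(x.data, -500, 500)))

    def bwd(g: Array) -> None:
        if x.requires_grad:
            x._accumulate(g * y * (1.0 - y))

    return Tensor(y, parents=(x,), backward=bwd)


def dropout(x: Tensor, rate: float, rng: np.random.Generator | None) -> Tensor:
    """Inverted dropout; identity when ``rng is None`` (inference) or rate=0."""
    if rng is None or rate <= 0.0:
        return x
    mask = (rng.random(x.shape) >= rate).astype(x.data.dtype) / (1.0 - rate)
    return x * Tensor(mask)


def cross_entropy(logits: Tensor, targets: Array, weights: Array | None = None) -> Tensor:
    """Mean softmax cross-entropy.

    ``logits`` is (M, V), ``targets`` (M,) integer classes, optional ``weights``
    (M,) re-weight per example (used to restrict the MLM loss to selected
    positions after flattening).
    """
    t = np.asarray(targets)
    m = logits.data.shape[0]
    w = np.ones(m, dtype=logits.data.dtype) if weights is None else np.asarray(weights)
    wsum = w.sum()
    if wsum == 0:
        return Tensor(np.array(0.0, dtype=logits.data.dtype))
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=-1))
    nll = lse - z[np.arange(m), t]
    loss = (w * nll).sum() / wsum

    def bwd(g: Array) -> None:
        if logits.requires_grad:
            p = np.exp(z - lse[:, None])
            p[np.arange(m), t] -= 1.0
            logits._accumulate(g * p * (w / wsum)[:, None])

    return Tensor(np.array(loss), parents=(logits,), backward=bwd)


def bce_with_logits(logits: Tensor, labels: Array) -> Tensor:
    """Mean binary cross-entropy of ``sigmoid(logits)`` against 0/1 labels."""
    y = np.asarray(labels, dtype=logits.data.dtype)
    x = logits.data
    # stable: max(x,0) - x*y + log(1+exp(-|x|))
    loss = np.maximum(x, 0) - x * y + np.log1p(np.exp(-np.abs(x)))
    m = x.size

    def bwd(g: Array) -> None:
        if logits.requires_grad:
            p = 1.0 / (1.0 + np.exp(-x))
            logits._accumulate(g * (p - y) / m)

    return Tensor(np.array(loss.mean()), parents=(logits,), backward=bwd)
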