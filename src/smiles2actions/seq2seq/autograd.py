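"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations the transformer needs: broadcasting
add/mul, batched matmul, reshape/transpose, ReLU, softmax, layer
normalization, embedding lookup, and a fused softmax cross-entropy with
optional label smoothing.  Gradients flow through a tape of closures;
``no_grad()`` disables tape construction for inference.
"""

from __future__ import annotations

import contextlib
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = ["Tensor", "no_grad", "Adam"]

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: Tuple["Tensor", ...] = (),
        backward: Optional[Callable[[np.ndarray], None]] = None,
    ):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        topo: List[Tensor] = []
        seen = set()
        stack: List[Tuple[Tensor, bool]] = [(self, False)]
        while stack:
            t, processed = stack.pop()
            if processed:
                topo.append(t)
                continue
            if id(t) in seen:
                continue
            seen.add(id(t))
            stack.append((t, True))
            for p in t._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # ------------------------------------------------------------------
    # ops
    # ------------------------------------------------------------------

    def _make(self, data, parents, backward) -> "Tensor":
        track = _grad_enabled and any(
            p.requires_grad or p._parents or p._backward for p in parents
        )
        if not track:
            return Tensor(data)
        out = Tensor(data, parents=parents, backward=backward)
        out.requires_grad = True
        return out

    def __add__(self, other: "Tensor") -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))

        return self._make(self.data + other.data, (self, other), backward)

    def __mul__(self, other) -> "Tensor":
        if isinstance(other, (int, float)):
            c = float(other)

            def backward_scalar(g):
                self._accumulate(g * c)

            return self._make(self.data * c, (self,), backward_scalar)
        other_t: Tensor = other

        def backward(g):
            self._accumulate(_unbroadcast(g * other_t.data, self.data.shape))
            other_t._accumulate(_unbroadcast(g * self.data, other_t.data.shape))

        return self._make(self.data * other_t.data, (self, other_t), backward)

    __rmul__ = __mul__

    def matmul(self, other: "Tensor") -> "Tensor":
        def backward(g):
            ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
            gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
            self._accumulate(_unbroadcast(ga, self.data.shape))
            other._accumulate(_unbroadcast(gb, other.data.shape))

        return self._make(np.matmul(self.data, other.data), (self, other), backward)

    def reshape(self, *shape) -> "Tensor":
        old = self.data.shape

        def backward(g):
            self._accumulate(g.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes) -> "Tensor":
        inv = np.argsort(axes)

        def backward(g):
            self._accumulate(g.transpose(*inv))

        return self._make(self.data.transpose(*axes), (self,), backward)

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def backward(g):
            self._accumulate(g * mask)

        return self._make(self.data * mask, (self,), backward)

    def softmax(self, bias: Optional[np.ndarray] = None) -> "Tensor":
        """Softmax over the last axis; ``bias`` is an additive constant
        (attention mask) applied to the logits."""
        z = self.data if bias is None else self.data + bias
        z = z - z.max(axis=-1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=-1, keepdims=True)

        def backward(g):
            dot = (g * p).sum(axis=-1, keepdims=True)
            self._accumulate(p * (g - dot))

        return self._make(p, (self,), backward)

    def layer_norm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5) -> "Tensor":
        mu = self.data.mean(axis=-1, keepdims=True)
        var = self.data.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (self.data - mu) * inv
        d = self.data.shape[-1]

        def backward(g):
            gx = g * gamma.data
            gxhat_sum = gx.sum(axis=-1, keepdims=True)
            gxhat_dot = (gx * xhat).sum(axis=-1, keepdims=True)
            self._accumulate(inv * (gx - gxhat_sum / d - xhat * gxhat_dot / d))
            gamma._accumulate(
                _unbroadcast(g * xhat, gamma.data.shape)
            )
            beta._accumulate(_unbroadcast(g, beta.data.shape))

        return self._make(xhat * gamma.data + beta.data, (self, gamma, beta), backward)

    def embedding(self, ids: np.ndarray) -> "Tensor":
        """Row gather: self is the (V, D) table, ids an integer array."""
        table = self

        def backward(g):
            gt = np.zeros_like(table.data)
            np.add.at(gt, ids.reshape(-1), g.reshape(-1, g.shape[-1]))
            table._accumulate(gt)

        return self._make(table.data[ids], (table,), backward)

    def cross_entropy(
        self,
        targets: np.ndarray,
        mask: np.ndarray,
        label_smoothing: float = 0.0,
    ) -> "Tensor":
        """Mean masked softmax cross-entropy; self is (N, V) logits.

        With label smoothing s, the target distribution mixes (1-s) on
        the gold class with s/(V-1) on the rest; s = 0 reproduces plain
        categorical cross-entropy.
        """
        logits = self.data
        n, v = logits.shape
        z = logits - logits.max(axis=-1, keepdims=True)
        logsumexp = np.log(np.exp(z).sum(axis=-1, keepdims=True))
        logp = z - logsumexp
        s = float(label_smoothing)
        denom = max(mask.sum(), 1.0)
        gold = logp[np.arange(n), targets]
        if s == 0.0:
            loss = -(gold * mask).sum() / denom
        else:
            off = (logp.sum(axis=-1) - gold) * (s / (v - 1))
            loss = -(((1 - s) * gold + off) * mask).sum() / denom

        def backward(g):
            p = np.exp(logp)
            target_dist = np.full_like(p, s / (v - 1))
            target_dist[np.arange(n), targets] = 1.0 - s
            grad = (p - target_dist) * mask[:, None] / denom
            self._accumulate(g * grad)

        return self._make(np.float32(loss), (self,), backward)


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(
        self,
        params: Sequence[Tensor],
        lr: float = 1e-3,
        betas: Tuple[float, float] = (0.9, 0.98),
        eps: float = 1e-9,
        clip_norm: Optional[float] = 1.0,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self, lr: Optional[float] = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        if self.clip_norm is not None:
            total = np.sqrt(
                sum(float((p.grad ** 2).sum()) for p in self.params if p.grad is not None)
            )
            scale = min(1.0, self.clip_norm / (total + 1e-12))
        else:
            scale = 1.0
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad * scale
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)
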