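"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough tensor calculus to express and train an encoder–decoder
transformer: broadcasting elementwise arithmetic, batched matmul,
embedding lookup, softmax, layer normalization, and a fused masked
cross-entropy head. Float32 throughout; gradients accumulate on leaves
with ``requires_grad=True``.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcasted gradient back to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        # list of (parent_tensor, grad_fn) pairs; grad_fn maps out-grad to
        # the parent's grad contribution
        self._parents: list = []

    @property
    def shape(self):
        return self.data.shape

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() needs a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent, _ in node._parents:
                if id(parent) not in seen:
                    stack.append((parent, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node.grad is None:
                continue
            for parent, fn in node._parents:
                g = fn(node.grad)
                if parent.grad is None:
                    parent.grad = g.astype(np.float32)
                else:
                    parent.grad = parent.grad + g

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data)
        out._parents = [(self, lambda g: _unbroadcast(g, self.shape)),
                        (other, lambda g: _unbroadcast(g, other.shape))]
        return out

    __radd__ = __add__

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            out = Tensor(self.data * other)
            out._parents = [(self, lambda g: g * other)]
            return out
        out = Tensor(self.data * other.data)
        out._parents = [
            (self, lambda g: _unbroadcast(g * other.data, self.shape)),
            (other, lambda g: _unbroadcast(g * self.data, other.shape))]
        return out

    __rmul__ = __mul__

    def __matmul__(self, other):
        out = Tensor(self.data @ other.data)
        a, b = self.data, other.data
        out._parents = [
            (self, lambda g: _unbroadcast(g @ b.swapaxes(-1, -2), self.shape)),
            (other, lambda g: _unbroadcast(a.swapaxes(-1, -2) @ g, other.shape))]
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape))
        orig = self.data.shape
        out._parents = [(self, lambda g: g.reshape(orig))]
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(*axes))
        inv = np.argsort(axes)
        out._parents = [(self, lambda g: g.transpose(*inv))]
        return out


def dropout(x: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; call only during training."""
    if rate <= 0.0:
        return x
    keep = (rng.random(x.data.shape) >= rate) / (1.0 - rate)
    keep = keep.astype(np.float32)
    out = Tensor(x.data * keep)
    out._parents = [(x, lambda g: g * keep)]
    return out


def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0))
    mask = x.data > 0
    out._parents = [(x, lambda g: g * mask)]
    return out


def embedding(weight: Tensor, ids: np.ndarray) -> Tensor:
    """Row gather: out[...] = weight[ids[...]]."""
    out = Tensor(weight.data[ids])

    def grad_fn(g):
        gw = np.zeros_like(weight.data)
        np.add.at(gw, ids.ravel(), g.reshape(-1, weight.data.shape[1]))
        return gw

    out._parents = [(weight, grad_fn)]
    return out


def softmax(x: Tensor) -> Tensor:
    """Softmax over the last axis."""
    z = x.data - x.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=-1, keepdims=True)
    out = Tensor(y)
    out._parents = [(x, lambda g: (g - (g * y).sum(axis=-1, keepdims=True)) * y)]
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               eps: float = 1e-5) -> Tensor:
    """Normalize the last axis, then scale and shift."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = Tensor(xhat * gamma.data + beta.data)
    d = x.data.shape[-1]

    def grad_x(g):
        gx = g * gamma.data
        return inv * (gx - gx.mean(axis=-1, keepdims=True)
                      - xhat * (gx * xhat).mean(axis=-1, keepdims=True))

    out._parents = [
        (x, grad_x),
        (gamma, lambda g: _unbroadcast(g * xhat, gamma.shape)),
        (beta, lambda g: _unbroadcast(g, beta.shape))]
    return out


def cross_entropy_logits(logits: Tensor, targets: np.ndarray,
                         mask: np.ndarray) -> tuple[Tensor, float, float]:
    """Masked mean cross entropy over (N, V) logits.

    Returns (loss tensor, token accuracy, total log-likelihood) — the
    extras feed perplexity and early stopping without a second pass.
    """
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=-1, keepdims=True)
    n = logits.data.shape[0]
    logp = z - np.log(e.sum(axis=-1, keepdims=True))
    nll = -logp[np.arange(n), targets]
    denom = max(mask.sum(), 1.0)
    loss_val = (nll * mask).sum() / denom
    out = Tensor(loss_val)

    def grad_fn(g):
        grad = p.copy()
        grad[np.arange(n), targets] -= 1.0
        return g * grad * (mask / denom)[:, None]

    out._parents = [(logits, grad_fn)]
    correct = ((logits.data.argmax(axis=-1) == targets) * mask).sum()
    acc = float(correct / denom)
    total_ll = float(-(nll * mask).sum())
    return out, acc, total_ll


class Adam:
    """Adam with global-norm gradient clipping."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.98), eps: float = 1e-9, clip: float = 1.0):
        self.params = params
        self.lr, self.betas, self.eps, self.clip = lr, betas, eps, clip
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        norm = np.sqrt(sum(float((p.grad ** 2).sum())
                           for p in self.params if p.grad is not None))
        scale = self.clip / norm if norm > self.clip else 1.0
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad * scale
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
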