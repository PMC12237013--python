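"""A small reverse-mode automatic-differentiation engine over numpy.

Supports exactly the operations the message-passing layers need: dense
linear algebra, elementwise nonlinearities, row gathering, segment
(scatter) sums, and softmax-style compositions. Gradients accumulate into
``Tensor.grad`` after calling :meth:`Tensor.backward` on a scalar.

The engine is deliberately tiny — no broadcasting beyond what the layers
use (full-shape elementwise ops, row-vector bias addition), float64
throughout, single-threaded determinism.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "gather_rows", "segment_sum", "segment_softmax",
           "concat", "relu", "leaky_relu", "exp", "log", "cross_entropy"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """Node of the computation tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # -- graph mechanics ---------------------------------------------------

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: "Tensor"):
            stack = [(t, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    topo.append(node)
                    continue
                if id(node) in seen or not node.requires_grad:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node._parents:
                    stack.append((p, False))

        visit(self)
        for t in topo:
            t.grad = np.zeros_like(t.data)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- operators ---------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g, other.data.shape)
        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self.grad += -g
        out._backward = bwd
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g * other.data, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g * self.data, other.data.shape)
        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g / other.data, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(
                    -g * self.data / other.data ** 2, other.data.shape)
        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self.grad += g @ other.data.T
            if other.requires_grad:
                other.grad += self.data.T @ g
        out._backward = bwd
        return out

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self.grad += np.full_like(self.data, float(g))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self.grad += np.broadcast_to(gg, self.data.shape)
        out._backward = bwd
        return out

    def mean(self):
        return self.sum() * (1.0 / self.data.size)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())


# -- functional ops --------------------------------------------------------

def relu(t: Tensor) -> Tensor:
    out = Tensor(np.maximum(t.data, 0.0), parents=(t,))

    def bwd(g):
        if t.requires_grad:
            t.grad += g * (t.data > 0)
    out._backward = bwd
    return out


def leaky_relu(t: Tensor, slope: float = 0.2) -> Tensor:
    out = Tensor(np.where(t.data > 0, t.data, slope * t.data), parents=(t,))

    def bwd(g):
        if t.requires_grad:
            t.grad += g * np.where(t.data > 0, 1.0, slope)
    out._backward = bwd
    return out


def exp(t: Tensor) -> Tensor:
    data = np.exp(t.data)
    out = Tensor(data, parents=(t,))

    # closure captures the data array, not `out`: keeps the tape acyclic
    # so epoch graphs free by reference counting
    def bwd(g):
        if t.requires_grad:
            t.grad += g * data
    out._backward = bwd
    return out


def log(t: Tensor) -> Tensor:
    out = Tensor(np.log(t.data), parents=(t,))

    def bwd(g):
        if t.requires_grad:
            t.grad += g / t.data
    out._backward = bwd
    return out


def gather_rows(t: Tensor, idx: np.ndarray) -> Tensor:
    """Select rows ``t[idx]``; gradient scatter-adds back."""
    idx = np.asarray(idx, dtype=np.int64)
    out = Tensor(t.data[idx], parents=(t,))

    def bwd(g):
        if t.requires_grad:
            np.add.at(t.grad, idx, g)
    out._backward = bwd
    return out


def segment_sum(t: Tensor, seg: np.ndarray, n_segments: int) -> Tensor:
    """Sum rows of ``t`` into ``n_segments`` buckets given by ``seg``."""
    seg = np.asarray(seg, dtype=np.int64)
    shape = (n_segments,) + t.data.shape[1:]
    data = np.zeros(shape, dtype=np.float64)
    np.add.at(data, seg, t.data)
    out = Tensor(data, parents=(t,))

    def bwd(g):
        if t.requires_grad:
            t.grad += g[seg]
    out._backward = bwd
    return out


def segment_softmax(scores: Tensor, seg: np.ndarray, n_segments: int,
                    scatter=None) -> Tensor:
    """Softmax of per-edge scores within each target segment.

    The per-segment max is treated as a constant shift (softmax is
    shift-invariant, so the gradient is unaffected). When ``scatter`` — a
    constant (n_segments, E) summation matrix — is given, the segment sum
    and the re-expansion run as sparse products instead of index ops.
    """
    seg = np.asarray(seg, dtype=np.int64)
    mx = np.full((n_segments,) + scores.data.shape[1:], -np.inf)
    np.maximum.at(mx, seg, scores.data)
    mx = np.where(np.isfinite(mx), mx, 0.0)
    shifted = scores - Tensor(mx[seg])
    e = exp(shifted)
    if scatter is None:
        denom = segment_sum(e, seg, n_segments)
        return e / gather_rows(denom, seg)
    denom = spmm(scatter, e)
    return e / spmm(scatter.T, denom)


def spmm(M, t: Tensor) -> Tensor:
    """Multiply a constant (sparse) matrix with a Tensor: ``M @ t``.

    The backward pass is ``M.T @ grad``. With a CSR gather/scatter matrix
    this implements row gathering and segment summation far faster than
    ``np.add.at`` on large edge lists; the transpose is taken once by the
    caller-side cache, not here, so ``M`` may be any object exposing
    ``@`` and ``.T``.
    """
    out = Tensor(M @ t.data, parents=(t,))

    def bwd(g):
        if t.requires_grad:
            t.grad += M.T @ g
    out._backward = bwd
    return out


def reshape(t: Tensor, shape: tuple[int, ...]) -> Tensor:
    out = Tensor(t.data.reshape(shape), parents=(t,))

    def bwd(g):
        if t.requires_grad:
            t.grad += g.reshape(t.data.shape)
    out._backward = bwd
    return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors))
    splits = np.cumsum([d.shape[axis] for d in datas])[:-1]

    def bwd(g):
        pieces = np.split(g, splits, axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t.grad += piece
    out._backward = bwd
    return out


def cross_entropy(logits: Tensor, y: np.ndarray,
                  weights: np.ndarray | None = None) -> Tensor:
    """Mean cross-entropy of (N, C) logits against integer labels.

    ``weights`` are optional per-row weights (e.g., class weighting),
    normalized to mean 1 before use.
    """
    y = np.asarray(y, dtype=np.int64)
    n, c = logits.shape
    mx = logits.data.max(axis=1, keepdims=True)  # constant shift
    shifted = logits - Tensor(mx)
    lse = log(exp(shifted).sum(axis=1, keepdims=True))
    onehot = np.zeros((n, c))
    onehot[np.arange(n), y] = 1.0
    # nll_i = lse_i - z_{i, y_i}
    nll = lse.sum(axis=1) - (shifted * Tensor(onehot)).sum(axis=1)
    if weights is not None:
        w = np.asarray(weights, dtype=np.float64)
        w = w / w.mean()
        return (nll * Tensor(w)).mean()
    return nll.mean()


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 3e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
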