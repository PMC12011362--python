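"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the peptide models need: broadcasted
arithmetic, batched matmul, reductions, softmax, the usual activations,
concatenation/reshaping and integer-array gathering (for token embeddings).
Gradients are accumulated into ``Tensor.grad`` by :meth:`Tensor.backward`;
every intermediate retains its gradient, which is what lets the training
loop read the gradient at an arbitrary perturbation site for adversarial
training.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "concatenate", "stack", "AdamW"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over prepended axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were broadcast from 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _as_tensor(x) -> "Tensor":
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=np.float64))


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make numpy defer to Tensor's reflected operators (ndarray + Tensor etc.)
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward

    # ---- bookkeeping -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def zero_grad(self):
        self.grad = None

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            grad = np.ones_like(self.data)
        # iterative topological sort
        topo, seen, stack_ = [], set(), [(self, False)]
        while stack_:
            node, processed = stack_.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack_.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack_.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ---- arithmetic --------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bw(g):
            self._accum(_unbroadcast(g, self.shape))
            other._accum(_unbroadcast(g, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bw(g):
            self._accum(_unbroadcast(g * other.data, self.shape))
            other._accum(_unbroadcast(g * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def bw(g):
            self._accum(_unbroadcast(g / other.data, self.shape))
            other._accum(_unbroadcast(-g * self.data / other.data**2, other.shape))

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, _parents=(self,))
        out._backward = lambda g: self._accum(g * exponent * self.data ** (exponent - 1))
        return out

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = Tensor(np.matmul(self.data, other.data), _parents=(self, other))

        def bw(g):
            self._accum(
                _unbroadcast(np.matmul(g, np.swapaxes(other.data, -1, -2)), self.shape)
            )
            other._accum(
                _unbroadcast(np.matmul(np.swapaxes(self.data, -1, -2), g), other.shape)
            )

        out._backward = bw
        return out

    # ---- reductions --------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # ---- elementwise nonlinearities ---------------------------------

    def exp(self):
        out = Tensor(np.exp(self.data), _parents=(self,))
        out._backward = lambda g: self._accum(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def sqrt(self):
        return self**0.5

    def tanh(self):
        out = Tensor(np.tanh(self.data), _parents=(self,))
        out._backward = lambda g: self._accum(g * (1.0 - out.data**2))
        return out

    def sigmoid(self):
        x = self.data
        y = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                     np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
        out = Tensor(y, _parents=(self,))
        out._backward = lambda g: self._accum(g * out.data * (1.0 - out.data))
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _parents=(self,))
        out._backward = lambda g: self._accum(g * (self.data > 0))
        return out

    def leaky_relu(self, slope: float = 0.2):
        out = Tensor(np.where(self.data > 0, self.data, slope * self.data), _parents=(self,))
        out._backward = lambda g: self._accum(g * np.where(self.data > 0, 1.0, slope))
        return out

    def elu(self, alpha: float = 1.0):
        pos = self.data > 0
        out = Tensor(
            np.where(pos, self.data, alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0)),
            _parents=(self,),
        )
        out._backward = lambda g: self._accum(g * np.where(pos, 1.0, out.data + alpha))
        return out

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes through only inside the interval."""
        out = Tensor(np.clip(self.data, lo, hi), _parents=(self,))
        inside = (self.data >= lo) & (self.data <= hi)
        out._backward = lambda g: self._accum(g * inside)
        return out

    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        y = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(y, _parents=(self,))

        def bw(g):
            self._accum(y * (g - (g * y).sum(axis=axis, keepdims=True)))

        out._backward = bw
        return out

    # ---- shape ops ---------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.shape))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _parents=(self,))
        out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    def swapaxes(self, a: int, b: int):
        out = Tensor(np.swapaxes(self.data, a, b), _parents=(self,))
        out._backward = lambda g: self._accum(np.swapaxes(g, a, b))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _parents=(self,))

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        out._backward = bw
        return out

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.shape}, grad={'set' if self.grad is not None else 'none'})"


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concatenate(tensors, axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    out._backward = bw
    return out


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), _parents=tuple(tensors))

    def bw(g):
        for i, t in enumerate(tensors):
            t._accum(np.take(g, i, axis=axis))

    out._backward = bw
    return out


class AdamW:
    """Adam with decoupled weight decay, supporting per-group learning rates."""

    def __init__(self, param_groups, betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.01):
        # param_groups: list of {"params": [Parameter, ...], "lr": float}
        self.groups = param_groups
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = {}
        self._v = {}

    def zero_grad(self):
        for g in self.groups:
            for p in g["params"]:
                p.zero_grad()

    def step(self):
        self.t += 1
        for group in self.groups:
            lr = group["lr"]
            for p in group["params"]:
                if p.grad is None:
                    continue
                k = id(p)
                m = self._m.setdefault(k, np.zeros_like(p.data))
                v = self._v.setdefault(k, np.zeros_like(p.data))
                m *= self.b1
                m += (1 - self.b1) * p.grad
                v *= self.b2
                v += (1 - self.b2) * p.grad**2
                mhat = m / (1 - self.b1**self.t)
                vhat = v / (1 - self.b2**self.t)
                p.data -= lr * (mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.data)
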