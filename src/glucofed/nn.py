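"""Minimal reverse-mode autodiff over NumPy arrays, with the layers the agent needs.

Scope is deliberately small: float64 tensors, the op set required by a
recurrent soft actor-critic (affine maps, GRU gates, tanh-squashed Gaussian
log-densities, elementwise min of twin critics), plus Adam.  Gradients are
exact and are checked against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "Adam", "Linear", "GRUCell", "concat", "minimum"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    # -- graph mechanics ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    def backward(self) -> None:
        """Backpropagate from a scalar tensor."""
        assert self.data.size == 1, "backward() requires a scalar loss"
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic --------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, (self, other))
        out._backward = lambda g: (self._accum(g), other._accum(g))
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, (self, other))
        out._backward = lambda g: (self._accum(g * other.data),
                                   other._accum(g * self.data))
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, (self, other))
        out._backward = lambda g: (
            self._accum(g / other.data),
            other._accum(-g * self.data / (other.data ** 2)),
        )
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, (self,))
        out._backward = lambda g: self._accum(g * exponent * self.data ** (exponent - 1))
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, (self, other))

        def bw(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        out._backward = bw
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], (self,))

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        out._backward = bw
        return out

    # -- nonlinearities & reductions ---------------------------------------

    def exp(self):
        out = Tensor(np.exp(self.data), (self,))
        out._backward = lambda g: self._accum(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), (self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), (self,))
        out._backward = lambda g: self._accum(g * (1.0 - out.data ** 2))
        return out

    def sigmoid(self):
        out = Tensor(1.0 / (1.0 + np.exp(-self.data)), (self,))
        out._backward = lambda g: self._accum(g * out.data * (1.0 - out.data))
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), (self,))
        out._backward = lambda g: self._accum(g * (self.data > 0))
        return out

    def softplus(self):
        # log(1 + e^x), computed stably
        out = Tensor(np.logaddexp(0.0, self.data), (self,))
        out._backward = lambda g: self._accum(g / (1.0 + np.exp(-self.data)))
        return out

    def sum(self, axis=None):
        out = Tensor(self.data.sum(axis=axis), (self,))

        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                self._accum(np.broadcast_to(np.expand_dims(g, axis), self.data.shape))

        out._backward = bw
        return out

    def mean(self, axis=None):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis) * (1.0 / n)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    parts = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([p.data for p in parts], axis=axis), tuple(parts))
    sizes = [p.data.shape[axis] for p in parts]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for p, piece in zip(parts, np.split(g, splits, axis=axis)):
            p._accum(piece)

    out._backward = bw
    return out


def minimum(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise min with subgradient routed to the attaining argument."""
    out = Tensor(np.minimum(a.data, b.data), (a, b))
    mask = a.data <= b.data

    def bw(g):
        a._accum(g * mask)
        b._accum(g * (~mask))

    out._backward = bw
    return out


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Adam:
    """Standard Adam over a list of Parameters; deterministic."""

    def __init__(self, params: list[Parameter], lr: float = 3e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8):
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
            mh = self.m[i] / (1 - self.b1 ** self.t)
            vh = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mh / (np.sqrt(vh) + self.eps)


def _init_weight(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=(fan_in, fan_out))


class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 weight_scale: float = 1.0):
        self.W = Parameter(weight_scale * _init_weight(rng, n_in, n_out))
        self.b = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def forward_np(self, x: np.ndarray) -> np.ndarray:
        return x @ self.W.data + self.b.data

    def parameters(self) -> list[Parameter]:
        return [self.W, self.b]

    @staticmethod
    def param_count(n_in: int, n_out: int) -> int:
        return n_in * n_out + n_out


class GRUCell:
    """Single GRU layer applied one time step at a time.

    Gates (x: input, h: previous hidden):
        z = sigma(x Wz + h Uz + bz)
        r = sigma(x Wr + h Ur + br)
        n = tanh(x Wn + r * (h Un) + bn)
        h' = (1 - z) * n + z * h
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.n_in, self.n_hidden = n_in, n_hidden
        make = lambda a, b: Parameter(_init_weight(rng, a, b))
        self.Wz, self.Uz = make(n_in, n_hidden), make(n_hidden, n_hidden)
        self.Wr, self.Ur = make(n_in, n_hidden), make(n_hidden, n_hidden)
        self.Wn, self.Un = make(n_in, n_hidden), make(n_hidden, n_hidden)
        self.bz = Parameter(np.zeros(n_hidden))
        self.br = Parameter(np.zeros(n_hidden))
        self.bn = Parameter(np.zeros(n_hidden))

    def __call__(self, x: Tensor, h: Tensor) -> Tensor:
        z = (x @ self.Wz + h @ self.Uz + self.bz).sigmoid()
        r = (x @ self.Wr + h @ self.Ur + self.br).sigmoid()
        n = (x @ self.Wn + r * (h @ self.Un) + self.bn).tanh()
        return (1.0 - z) * n + z * h

    def forward_np(self, x: np.ndarray, h: np.ndarray) -> np.ndarray:
        sig = lambda v: 1.0 / (1.0 + np.exp(-v))
        z = sig(x @ self.Wz.data + h @ self.Uz.data + self.bz.data)
        r = sig(x @ self.Wr.data + h @ self.Ur.data + self.br.data)
        n = np.tanh(x @ self.Wn.data + r * (h @ self.Un.data) + self.bn.data)
        return (1.0 - z) * n + z * h

    def parameters(self) -> list[Parameter]:
        return [self.Wz, self.Uz, self.Wr, self.Ur, self.Wn, self.Un,
                self.bz, self.br, self.bn]

    @staticmethod
    def param_count(n_in: int, n_hidden: int) -> int:
        return 3 * (n_in * n_hidden + n_hidden * n_hidden + n_hidden)
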