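"""A compact reverse-mode automatic-differentiation engine over numpy.

Just enough tensor calculus for a small detection transformer: broadcasting
elementwise arithmetic, batched matmul, reductions, indexing/gather, softmax
building blocks and a strided 2-D convolution primitive. Arrays are float64
throughout; graphs are built eagerly and freed after ``backward``.

Not a general deep-learning framework: no views with aliasing semantics, no
higher-order gradients, no GPU. Kept deliberately small so every gradient rule
is auditable; the test suite checks each primitive against central finite
differences.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

Array = np.ndarray


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum ``grad`` down to ``shape`` to undo numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: tuple["Tensor", ...] = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Array | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[Array], None] | None = None
        self._parents = _parents

    # ------------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # ------------------------------------------------------------------
    def backward(self, grad: Array | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
        # free the graph; leaf grads stay
        for node in topo:
            if node._backward is not None:
                node._parents = ()
                node._backward = None
                if node is not self:
                    node.grad = None

    def _accumulate(self, grad: Array) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- helpers --------------------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def _make(data: Array, parents: Sequence["Tensor"],
              backward: Callable[[Array], None]) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req,
                     _parents=tuple(p for p in parents if p.requires_grad))
        if req:
            out._backward = backward
        return out

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        a, b = self, other

        def backward(g: Array) -> None:
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.shape))

        return self._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g: Array) -> None:
            a._accumulate(-g)

        return self._make(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        a, b = self, other

        def backward(g: Array) -> None:
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.shape))

        return self._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        a, b = self, other

        def backward(g: Array) -> None:
            if a.requires_grad:
                a._accumulate(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-g * a.data / (b.data ** 2), b.shape))

        return self._make(a.data / b.data, (a, b), backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        a = self
        e = float(exponent)

        def backward(g: Array) -> None:
            a._accumulate(g * e * a.data ** (e - 1.0))

        return self._make(a.data ** e, (a,), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        a, b = self, other

        def backward(g: Array) -> None:
            if a.requires_grad:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                a._accumulate(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                b._accumulate(_unbroadcast(gb, b.shape))

        return self._make(np.matmul(a.data, b.data), (a, b), backward)

    # -- elementwise nonlinearities -------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward(g: Array) -> None:
            a._accumulate(g * out_data)

        return self._make(out_data, (a,), backward)

    def log(self):
        a = self

        def backward(g: Array) -> None:
            a._accumulate(g / a.data)

        return self._make(np.log(a.data), (a,), backward)

    def sqrt(self):
        return self ** 0.5

    def abs(self):
        a = self

        def backward(g: Array) -> None:
            a._accumulate(g * np.sign(a.data))

        return self._make(np.abs(a.data), (a,), backward)

    def relu(self):
        a = self
        mask = a.data > 0

        def backward(g: Array) -> None:
            a._accumulate(g * mask)

        return self._make(a.data * mask, (a,), backward)

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))

        def backward(g: Array) -> None:
            a._accumulate(g * out_data * (1.0 - out_data))

        return self._make(out_data, (a,), backward)

    def maximum(self, other):
        """Elementwise max; at exact ties the gradient goes to ``self``."""
        other = self._lift(other)
        a, b = self, other
        take_a = a.data >= b.data

        def backward(g: Array) -> None:
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * take_a, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * ~take_a, b.shape))

        return self._make(np.maximum(a.data, b.data), (a, b), backward)

    def minimum(self, other):
        other = self._lift(other)
        a, b = self, other
        take_a = a.data <= b.data

        def backward(g: Array) -> None:
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * take_a, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * ~take_a, b.shape))

        return self._make(np.minimum(a.data, b.data), (a, b), backward)

    def clamp(self, lo: float | None = None, hi: float | None = None):
        out = self
        if lo is not None:
            out = out.maximum(lo)
        if hi is not None:
            out = out.minimum(hi)
        return out

    # -- reductions / shaping -------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def backward(g: Array) -> None:
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.shape).copy())

        return self._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.shape

        def backward(g: Array) -> None:
            a._accumulate(g.reshape(old))

        return self._make(a.data.reshape(shape), (a,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = np.argsort(axes)

        def backward(g: Array) -> None:
            a._accumulate(g.transpose(inv))

        return self._make(a.data.transpose(axes), (a,), backward)

    def __getitem__(self, idx):
        a = self
        has_arrays = any(isinstance(i, (np.ndarray, list)) for i in
                         (idx if isinstance(idx, tuple) else (idx,)))

        def backward(g: Array) -> None:
            full = np.zeros_like(a.data)
            if has_arrays:
                np.add.at(full, idx, g)
            else:
                full[idx] += g
            a._accumulate(full)

        return self._make(a.data[idx], (a,), backward)


# ---------------------------------------------------------------------------
# free functions
# ---------------------------------------------------------------------------

def concatenate(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g: Array) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(x.data.max(axis=axis, keepdims=True))  # constant, no grad
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution: ``x`` (B,C,H,W), ``w`` (O,C,kh,kw) -> (B,O,Ho,Wo)."""
    s, p = int(stride), int(padding)
    kh, kw = w.shape[2], w.shape[3]
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::s, ::s]  # (B,C,Ho,Wo,kh,kw)
    out_data = np.einsum("bchwij,ocij->bohw", win, w.data, optimize=True)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]
    parents = [x, w] + ([b] if b is not None else [])
    ho, wo = out_data.shape[2], out_data.shape[3]

    def backward(g: Array) -> None:
        if w.requires_grad:
            w._accumulate(np.einsum("bchwij,bohw->ocij", win, g, optimize=True))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dwin = np.einsum("ocij,bohw->bchwij", w.data, g, optimize=True)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += dwin[:, :, :, :, i, j]
            if p > 0:
                dxp = dxp[:, :, p:-p, p:-p]
            x._accumulate(dxp)

    return Tensor._make(out_data, parents, backward)


# ---------------------------------------------------------------------------
# modules, parameters, optimizer
# ---------------------------------------------------------------------------

class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal parameter container with recursive discovery."""

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        seen: set[int] = set()

        def visit(obj) -> None:
            if isinstance(obj, Parameter):
                if id(obj) not in seen:
                    seen.add(id(obj))
                    out.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    visit(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    visit(v)
            elif isinstance(obj, dict):
                for v in obj.values():
                    visit(v)

        visit(self)
        return out

    def named_parameters(self, prefix: str = "") -> dict[str, Parameter]:
        out: dict[str, Parameter] = {}

        def visit(obj, name: str) -> None:
            if isinstance(obj, Parameter):
                out[name] = obj
            elif isinstance(obj, Module):
                for k, v in vars(obj).items():
                    visit(v, f"{name}.{k}" if name else k)
            elif isinstance(obj, (list, tuple)):
                for i, v in enumerate(obj):
                    visit(v, f"{name}.{i}")
            elif isinstance(obj, dict):
                for k, v in obj.items():
                    visit(v, f"{name}.{k}")

        visit(self, prefix)
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


def xavier_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                   shape: tuple[int, ...]) -> Array:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=shape)


class Linear(Module):
    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int,
                 bias: bool = True):
        self.weight = Parameter(xavier_uniform(rng, d_in, d_out, (d_in, d_out)))
        self.bias = Parameter(np.zeros(d_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return self.gamma * (centered / (var + self.eps).sqrt()) + self.beta


class MLP(Module):
    """Stack of Linear+ReLU layers with a linear output layer."""

    def __init__(self, rng: np.random.Generator, dims: Sequence[int]):
        self.layers = [Linear(rng, a, b) for a, b in zip(dims[:-1], dims[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers[:-1]:
            x = layer(x).relu()
        return self.layers[-1](x)


class Adam:
    """Adam with decoupled weight decay (AdamW)."""

    def __init__(self, params: Iterable[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            update = (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            if self.weight_decay:
                update = update + self.weight_decay * p.data
            p.data -= self.lr * update

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
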