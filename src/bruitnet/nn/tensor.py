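"""A minimal reverse-mode autodiff engine on numpy arrays.

Just enough machinery to train the bruit classifier on a CPU: elementwise
arithmetic with broadcasting, matmul, reductions, ReLU/sigmoid/exp/log,
and fused primitives for 3x3 same-convolution, 2x2 max-pooling, and batch
normalization (each with a hand-derived backward pass verified against
numerical gradients in the test suite).

All data is float32.  Gradients accumulate into ``Tensor.grad``; call
``Tensor.backward()`` on a scalar loss.
"""

from __future__ import annotations

import gc
from contextlib import contextmanager

import numpy as np

# The autodiff graph holds only child->parent references (no cycles), so the
# cyclic collector gains nothing from scanning it; frequent generation-2
# passes over thousands of live numpy arrays dominate runtime otherwise.
gc.set_threshold(100_000, 50, 50)

__all__ = ["Tensor", "no_grad", "conv3x3", "maxpool2x2", "batchnorm2d"]

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _result(data, parents, backward):
        needs = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=needs)
        if needs:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar")
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
            for p in node._parents:
                if p._backward is not None or p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free graph references as we go
                node._backward = None
                node._parents = ()

    # -- helpers -----------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor._result(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor._result(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._result(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor._result(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, exponent: float):
        def backward(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1))

        return Tensor._result(self.data**exponent, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        return Tensor._result(self.data @ other.data, (self, other), backward)

    # -- nonlinearities ----------------------------------------------------

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor._result(self.data * mask, (self,), backward)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * s * (1.0 - s))

        return Tensor._result(s, (self,), backward)

    def exp(self):
        e = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * e)

        return Tensor._result(e, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return Tensor._result(np.log(self.data), (self,), backward)

    def sqrt(self):
        return self**0.5

    # -- reductions & shape ------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.data.shape))

        return Tensor._result(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), backward
        )

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else axis
            count = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def max(self, axis: int, keepdims: bool = False):
        """Max over one axis; ties share gradient equally."""
        m = self.data.max(axis=axis, keepdims=True)
        mask = (self.data == m).astype(np.float32)
        mask /= mask.sum(axis=axis, keepdims=True)

        def backward(g):
            if self.requires_grad:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(mask * gg)

        out = m if keepdims else np.squeeze(m, axis=axis)
        return Tensor._result(out, (self,), backward)

    def reshape(self, *shape):
        old = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old))

        return Tensor._result(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes):
        inverse = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.transpose(*inverse))

        return Tensor._result(self.data.transpose(*axes), (self,), backward)


# -- fused primitives ------------------------------------------------------


def _im2col(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*9) patches of a 1-padded input."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    # win: (N, C, H, W, 3, 3) -> (N, H, W, C, 3, 3)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n * h * w, c * 9)


def _conv3x3_raw(x: np.ndarray, w: np.ndarray, cols: np.ndarray | None = None):
    n, c, h, wd = x.shape
    o = w.shape[0]
    if cols is None:
        cols = _im2col(x)
    out = cols @ w.reshape(o, c * 9).T
    return out.reshape(n, h, wd, o).transpose(0, 3, 1, 2), cols


def conv3x3(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Same-padding 3x3 convolution, stride 1.

    ``x``: (N, C, H, W); ``weight``: (O, C, 3, 3); ``bias``: (O,).
    """
    n, c, h, w = x.data.shape
    o = weight.data.shape[0]
    out, cols = _conv3x3_raw(x.data, weight.data)
    out += bias.data[None, :, None, None]

    def backward(g):
        g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * h * w, o)
        if bias.requires_grad:
            bias._accumulate(g2.sum(axis=0))
        if weight.requires_grad:
            weight._accumulate((g2.T @ cols).reshape(o, c, 3, 3))
        if x.requires_grad:
            # grad wrt input = same-conv of g with spatially flipped,
            # in/out-swapped kernels
            w_flip = weight.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
            gx, _ = _conv3x3_raw(g, np.ascontiguousarray(w_flip))
            x._accumulate(gx)

    return Tensor._result(out, (x, weight, bias), backward)


def maxpool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2; odd trailing rows/columns are dropped."""
    n, c, h, w = x.data.shape
    h2, w2 = h // 2, w // 2
    xc = x.data[:, :, : h2 * 2, : w2 * 2]
    patches = xc.reshape(n, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
        n, c, h2, w2, 4
    )
    arg = patches.argmax(axis=-1)
    out = np.take_along_axis(patches, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        gp = np.zeros((n, c, h2, w2, 4), dtype=np.float32)
        np.put_along_axis(gp, arg[..., None], g[..., None], axis=-1)
        gx = np.zeros_like(x.data)
        gx[:, :, : h2 * 2, : w2 * 2] = (
            gp.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
                n, c, h2 * 2, w2 * 2
            )
        )
        x._accumulate(gx)

    return Tensor._result(out, (x,), backward)


def batchnorm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Batch normalization over (N, H, W) per channel.

    In training mode uses batch statistics and updates the running buffers in
    place (biased variance); in eval mode normalizes with the running buffers.
    """
    if training:
        axes = (0, 2, 3)
        m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
        ivar = 1.0 / np.sqrt(var + eps)
        xhat = (x.data - mu[None, :, None, None]) * ivar[None, :, None, None]
        out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

        def backward(g):
            gsum = g.sum(axis=axes)
            gxhat_sum = (g * xhat).sum(axis=axes)
            if beta.requires_grad:
                beta._accumulate(gsum)
            if gamma.requires_grad:
                gamma._accumulate(gxhat_sum)
            if x.requires_grad:
                coef = (gamma.data * ivar / m)[None, :, None, None]
                gx = coef * (
                    m * g
                    - gsum[None, :, None, None]
                    - xhat * gxhat_sum[None, :, None, None]
                )
                x._accumulate(gx.astype(np.float32))

        return Tensor._result(out.astype(np.float32), (x, gamma, beta), backward)

    scale = gamma.data / np.sqrt(running_var + eps)
    out = scale[None, :, None, None] * (x.data - running_mean[None, :, None, None])
    out += beta.data[None, :, None, None]

    def backward_eval(g):
        axes = (0, 2, 3)
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=axes))
        if gamma.requires_grad:
            xhat = (x.data - running_mean[None, :, None, None]) / np.sqrt(
                running_var + eps
            )[None, :, None, None]
            gamma._accumulate((g * xhat).sum(axis=axes))
        if x.requires_grad:
            x._accumulate(g * scale[None, :, None, None])

    return Tensor._result(out.astype(np.float32), (x, gamma, beta), backward_eval)
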