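"""A compact reverse-mode autodiff engine for volumetric CNNs.

Tensors wrap float64 numpy arrays with channel-first layout ``(C, X, Y, Z)``
and record the operations that produced them; :meth:`Tensor.backward` runs
the reverse sweep over the recorded graph.  Only the operations needed by a
3-D encoder-decoder segmentation network are provided: same-size and
strided 3-D convolution, nearest-neighbour and zero-stuffing upsampling,
channel concatenation, elementwise add, ReLU, sigmoid and dropout.

Convolution is evaluated as a sum of 27 (or 1) shifted GEMMs — one
``tensordot`` per kernel offset — which keeps memory flat and runs through
BLAS; the same decomposition gives the weight and input gradients.  All
gradients are verified against central finite differences in the test
suite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = [
    "Tensor",
    "conv3d",
    "relu",
    "sigmoid",
    "add",
    "concat",
    "upsample_nearest",
    "upsample_zeros",
    "dropout",
    "instance_norm",
]


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse sweep from this tensor, seeding with ``grad``."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() on a non-scalar tensor needs an explicit seed grad")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs are deep at paper-scale grids
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
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _offsets(k: int):
    return [(i, j, l) for i in range(k) for j in range(k) for l in range(k)]


def conv3d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1) -> Tensor:
    """3-D convolution with 'same' zero padding.

    ``x`` is (Cin, X, Y, Z); ``w`` is (Cout, Cin, k, k, k) with k odd
    (1 or 3 in practice); output spatial size is the input size divided by
    ``stride`` (axes must be divisible).
    """
    cin, X, Y, Z = x.shape
    cout, cin_w, k, _, _ = w.shape
    if cin_w != cin:
        raise ValueError(f"conv3d channel mismatch: input has {cin}, kernel expects {cin_w}")
    if stride > 1 and any(n % stride for n in (X, Y, Z)):
        raise ValueError(f"spatial size {(X, Y, Z)} not divisible by stride {stride}")
    pad = k // 2
    shape_out = (X // stride, Y // stride, Z // stride)

    xp = np.pad(x.data, ((0, 0),) + ((pad, pad),) * 3) if pad else x.data
    out = np.zeros((cout,) + shape_out)
    if b is not None:
        out += b.data.reshape(-1, 1, 1, 1)
    segs = {}
    for i, j, l in _offsets(k):
        seg = xp[
            :,
            i : i + (shape_out[0] - 1) * stride + 1 : stride,
            j : j + (shape_out[1] - 1) * stride + 1 : stride,
            l : l + (shape_out[2] - 1) * stride + 1 : stride,
        ]
        segs[(i, j, l)] = seg
        out += np.tensordot(w.data[:, :, i, j, l], seg, axes=(1, 0))

    parents = (x, w) if b is None else (x, w, b)

    def backward(g: np.ndarray) -> None:
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(1, 2, 3)))
        if w.requires_grad:
            gw = np.empty_like(w.data)
            for i, j, l in _offsets(k):
                gw[:, :, i, j, l] = np.tensordot(g, segs[(i, j, l)], axes=([1, 2, 3], [1, 2, 3]))
            w._accumulate(gw)
        if x.requires_grad:
            gxp = np.zeros((cin, X + 2 * pad, Y + 2 * pad, Z + 2 * pad))
            for i, j, l in _offsets(k):
                gxp[
                    :,
                    i : i + (shape_out[0] - 1) * stride + 1 : stride,
                    j : j + (shape_out[1] - 1) * stride + 1 : stride,
                    l : l + (shape_out[2] - 1) * stride + 1 : stride,
                ] += np.tensordot(w.data[:, :, i, j, l], g, axes=(0, 0))
            x._accumulate(gxp[:, pad : pad + X, pad : pad + Y, pad : pad + Z] if pad else gxp)

    return Tensor(out, parents=parents, backward=backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return Tensor(x.data * mask, parents=(x,), backward=backward)


def sigmoid(x: Tensor) -> Tensor:
    # logits are clamped to +/-40 so the derivative never underflows to an
    # exact zero; a dead-zero gradient would permanently stall Adam, whose
    # updates are otherwise invariant to gradient scale
    s = expit(np.clip(x.data, -40.0, 40.0))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * s * (1.0 - s))

    return Tensor(s, parents=(x,), backward=backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    if a.shape != b.shape:
        raise ValueError(f"add shape mismatch: {a.shape} vs {b.shape}")

    def backward(g):
        if a.requires_grad:
            a._accumulate(g)
        if b.requires_grad:
            b._accumulate(g)

    return Tensor(a.data + b.data, parents=(a, b), backward=backward)


def concat(a: Tensor, b: Tensor) -> Tensor:
    """Concatenate along the channel axis."""
    ca = a.shape[0]

    def backward(g):
        if a.requires_grad:
            a._accumulate(g[:ca])
        if b.requires_grad:
            b._accumulate(g[ca:])

    return Tensor(np.concatenate([a.data, b.data], axis=0), parents=(a, b), backward=backward)


def upsample_nearest(x: Tensor, factor: int = 2) -> Tensor:
    """Nearest-neighbour spatial upsampling by an integer factor."""
    f = factor
    out = x.data.repeat(f, axis=1).repeat(f, axis=2).repeat(f, axis=3)
    c, X, Y, Z = x.shape

    def backward(g):
        if x.requires_grad:
            x._accumulate(g.reshape(c, X, f, Y, f, Z, f).sum(axis=(2, 4, 6)))

    return Tensor(out, parents=(x,), backward=backward)


def upsample_zeros(x: Tensor, factor: int = 2) -> Tensor:
    """Zero-stuffing upsampling; followed by a conv it realizes a transposed
    convolution."""
    f = factor
    c, X, Y, Z = x.shape
    out = np.zeros((c, X * f, Y * f, Z * f))
    out[:, ::f, ::f, ::f] = x.data

    def backward(g):
        if x.requires_grad:
            x._accumulate(g[:, ::f, ::f, ::f])

    return Tensor(out, parents=(x,), backward=backward)


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-channel normalization over the spatial axes with affine params.

    ``gamma``/``beta`` have shape (C,).  Keeps activation variance flat
    through the depth of the network, which a normalization-free stack of
    residual blocks does not.
    """
    mu = x.data.mean(axis=(1, 2, 3), keepdims=True)
    var = x.data.var(axis=(1, 2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    gcol = gamma.data.reshape(-1, 1, 1, 1)
    out = gcol * xhat + beta.data.reshape(-1, 1, 1, 1)

    def backward(g):
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(1, 2, 3)))
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(1, 2, 3)))
        if x.requires_grad:
            gx = g * gcol
            m1 = gx.mean(axis=(1, 2, 3), keepdims=True)
            m2 = (gx * xhat).mean(axis=(1, 2, 3), keepdims=True)
            x._accumulate(inv * (gx - m1 - xhat * m2))

    return Tensor(out, parents=(x, gamma, beta), backward=backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or p == 0."""
    if not training or p <= 0:
        return x
    keep = (rng.random(x.shape) >= p) / (1.0 - p)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * keep)

    return Tensor(x.data * keep, parents=(x,), backward=backward)
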