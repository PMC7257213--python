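"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for a 3D encoder–decoder segmentation network run
at batch size 1: tensors are float32 numpy arrays shaped ``(C, Z, Y, X)``
(channels first, no batch axis), and the op set is 3D convolution (1^3
and 3^3 kernels, 'same' padding), leaky ReLU, instance normalization,
2x max pooling, 2x nearest-neighbour upsampling, channel concatenation,
elementwise add, and a fused softmax cross-entropy + soft-Dice loss.

Gradients flow through a tape of closures built as the forward pass
runs; ``backward(loss)`` walks the tape in reverse topological order.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "backward", "Adam"]


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad", "name")

    def __init__(self, data, parents=(), backward_fn=None, requires_grad=False, name=""):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.parents = tuple(parents)
        self._backward = backward_fn
        self.requires_grad = requires_grad or any(p.requires_grad for p in self.parents)
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def accumulate(self, g) -> None:
        if self.grad is None:
            self.grad = np.asarray(g, dtype=np.float32).copy()
        else:
            self.grad += g


def backward(loss: Tensor, seed: float = 1.0) -> None:
    """Reverse-mode sweep from a scalar loss; fills ``.grad`` on leaves."""
    topo: list[Tensor] = []
    seen: set[int] = set()
    stack = [(loss, False)]
    while stack:
        node, expanded = stack.pop()
        if id(node) in seen:
            continue
        if expanded:
            seen.add(id(node))
            topo.append(node)
            continue
        stack.append((node, True))
        for p in node.parents:
            if id(p) not in seen and p.requires_grad:
                stack.append((p, False))
    loss.accumulate(np.full_like(loss.data, seed))
    for node in reversed(topo):
        if node._backward is not None and node.grad is not None:
            node._backward(node.grad)


# --- convolution ------------------------------------------------------------


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(C, Z, Y, X) -> (Z*Y*X, C*k^3) patch matrix, 'same' padding."""
    c = x.shape[0]
    if k == 1:
        return x.reshape(c, -1).T
    pad = k // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))
    # (C, Z, Y, X, k, k, k) -> (Z, Y, X, C, k, k, k)
    win = win.transpose(1, 2, 3, 0, 4, 5, 6)
    return win.reshape(-1, c * k * k * k)


def _conv_raw(x: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Correlate (C,Z,Y,X) with (O,C,k,k,k); returns (out, cached patches)."""
    o, c, k = w.shape[0], w.shape[1], w.shape[2]
    cols = _im2col(x, k)
    out = cols @ w.reshape(o, -1).T.astype(np.float32)
    spatial = x.shape[1:]
    return out.T.reshape(o, *spatial), cols


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """'Same' 3D convolution (correlation); kernel size 1 or 3."""
    o, c, k = w.shape[0], w.shape[1], w.shape[2]
    out_data, cols = _conv_raw(x.data, w.data)
    if b is not None:
        out_data = out_data + b.data.reshape(o, 1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, parents=parents)

    def _bwd(g: np.ndarray) -> None:
        gmat = g.reshape(o, -1).T  # (N, O)
        if w.requires_grad:
            w.accumulate((gmat.T @ cols).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b.accumulate(g.sum(axis=(1, 2, 3)))
        if x.requires_grad:
            if k == 1:
                dx = (gmat @ w.data.reshape(o, -1)).T.reshape(x.data.shape)
            else:
                # full gradient = convolution of g with the flipped kernel
                w_flip = w.data.transpose(1, 0, 2, 3, 4)[:, :, ::-1, ::-1, ::-1]
                dx, _ = _conv_raw(g, np.ascontiguousarray(w_flip))
            x.accumulate(dx)

    out._backward = _bwd
    return out


# --- pointwise / normalization ----------------------------------------------


def leaky_relu(x: Tensor, slope: float = 0.01) -> Tensor:
    mask = x.data > 0
    out = Tensor(np.where(mask, x.data, slope * x.data), parents=(x,))

    def _bwd(g: np.ndarray) -> None:
        if x.requires_grad:
            x.accumulate(np.where(mask, g, slope * g))

    out._backward = _bwd
    return out


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-channel normalization over the spatial axes."""
    axes = (1, 2, 3)
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    gshape = gamma.data.reshape(-1, 1, 1, 1)
    out = Tensor(gshape * xhat + beta.data.reshape(-1, 1, 1, 1), parents=(x, gamma, beta))
    n = float(np.prod(x.data.shape[1:]))

    def _bwd(g: np.ndarray) -> None:
        if gamma.requires_grad:
            gamma.accumulate((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta.accumulate(g.sum(axis=axes))
        if x.requires_grad:
            dxhat = g * gshape
            dx = (
                dxhat
                - dxhat.mean(axis=axes, keepdims=True)
                - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True)
            ) * inv
            x.accumulate(dx)

    out._backward = _bwd
    return out


# --- structure ops ----------------------------------------------------------


def add(x: Tensor, y: Tensor) -> Tensor:
    out = Tensor(x.data + y.data, parents=(x, y))

    def _bwd(g: np.ndarray) -> None:
        if x.requires_grad:
            x.accumulate(g)
        if y.requires_grad:
            y.accumulate(g)

    out._backward = _bwd
    return out


def concat(x: Tensor, y: Tensor) -> Tensor:
    """Concatenate along the channel axis."""
    cx = x.data.shape[0]
    out = Tensor(np.concatenate([x.data, y.data], axis=0), parents=(x, y))

    def _bwd(g: np.ndarray) -> None:
        if x.requires_grad:
            x.accumulate(g[:cx])
        if y.requires_grad:
            y.accumulate(g[cx:])

    out._backward = _bwd
    return out


def maxpool2(x: Tensor) -> Tensor:
    c, z, y, w_ = x.data.shape
    blocks = (
        x.data.reshape(c, z // 2, 2, y // 2, 2, w_ // 2, 2)
        .transpose(0, 1, 3, 5, 2, 4, 6)
        .reshape(c, z // 2, y // 2, w_ // 2, 8)
    )
    arg = blocks.argmax(axis=-1)
    out = Tensor(np.take_along_axis(blocks, arg[..., None], axis=-1)[..., 0], parents=(x,))

    def _bwd(g: np.ndarray) -> None:
        if x.requires_grad:
            db = np.zeros_like(blocks)
            np.put_along_axis(db, arg[..., None], g[..., None], axis=-1)
            dx = (
                db.reshape(c, z // 2, y // 2, w_ // 2, 2, 2, 2)
                .transpose(0, 1, 4, 2, 5, 3, 6)
                .reshape(c, z, y, w_)
            )
            x.accumulate(dx)

    out._backward = _bwd
    return out


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling along every spatial axis."""
    d = x.data.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)
    out = Tensor(d, parents=(x,))
    c, z, y, w_ = x.data.shape

    def _bwd(g: np.ndarray) -> None:
        if x.requires_grad:
            dx = g.reshape(c, z, 2, y, 2, w_, 2).sum(axis=(2, 4, 6))
            x.accumulate(dx)

    out._backward = _bwd
    return out


# --- loss -------------------------------------------------------------------


def softmax_ce_dice(logits: Tensor, target_fg: np.ndarray, eps: float = 1e-6) -> Tensor:
    """Equally-weighted voxel cross-entropy + soft-Dice loss.

    ``logits`` has shape (2, Z, Y, X); ``target_fg`` is a boolean
    foreground mask.  The gradient with respect to the logits is
    injected analytically (softmax never appears as a graph node).
    """
    g_fg = np.asarray(target_fg, dtype=np.float32)
    z = logits.data - logits.data.max(axis=0, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=0, keepdims=True)
    p0, p1 = p[0], p[1]
    n = g_fg.size

    ce = -(g_fg * np.log(p1 + 1e-12) + (1.0 - g_fg) * np.log(p0 + 1e-12)).mean()
    inter = float((p1 * g_fg).sum())
    denom = float(p1.sum() + g_fg.sum()) + eps
    dice = (2.0 * inter + eps) / denom
    loss_val = ce + (1.0 - dice)
    out = Tensor(np.float32(loss_val), parents=(logits,))

    def _bwd(grad: np.ndarray) -> None:
        if not logits.requires_grad:
            return
        onehot = np.stack([1.0 - g_fg, g_fg])
        d_ce = (p - onehot) / n
        # d(1 - dice)/dp1, then chain through the softmax
        d_p1 = -(2.0 * g_fg * denom - (2.0 * inter + eps)) / (denom * denom)
        d_logit1 = d_p1 * p1 * (1.0 - p1)
        d_logit0 = -d_p1 * p1 * p0
        d_dice = np.stack([d_logit0, d_logit1])
        logits.accumulate(float(grad) * (d_ce + d_dice))

    out._backward = _bwd
    return out


def softmax_fg(logits: np.ndarray) -> np.ndarray:
    """Foreground-class softmax probability of a (2, ...) logit array."""
    z = logits - logits.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e[1] / e.sum(axis=0)


# --- optimizer --------------------------------------------------------------


class Adam:
    """Standard Adam on a dict of parameter tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float = 5e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None
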