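"""Reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps a float32 numpy array and records the operations that
produced it; :meth:`Tensor.backward` runs reverse-mode accumulation over the
recorded tape.  Only the operations the network builders in this package need
are provided (convolution, grouped convolution, 2x2 transpose convolution,
batch normalization, pooling, resizing, crops, softmax and the weighted
cross-entropy loss).  Convolutions are im2col/col2im based; the col2im scatter
uses per-sample ``np.bincount`` which is the fastest pure-numpy route.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "Parameter",
    "conv2d",
    "conv_transpose2x2",
    "batch_norm",
    "relu",
    "add",
    "center_crop",
    "upsample_nearest",
    "resize_nearest",
    "max_pool2d",
    "global_avg_pool",
    "linear",
    "softmax",
    "weighted_cross_entropy",
]


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self._parents = tuple(parents)
        self._backward = backward
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in self._parents
        )

    @property
    def shape(self):
        return self.data.shape

    def backward(self):
        """Accumulate gradients of ``self`` (summed) into every ancestor."""
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

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.asarray(g, dtype=np.float32).copy()
        else:
            self.grad += g

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


class Parameter(Tensor):
    """Trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _same_pad_amount(size: int, k: int, s: int) -> tuple[int, int]:
    out = -(-size // s)  # ceil
    total = max(0, (out - 1) * s + k - size)
    return total // 2, total - total // 2


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1,
           padding: str = "valid", groups: int = 1) -> Tensor:
    """2-D (optionally grouped) cross-correlation, NCHW layout.

    ``w`` has shape (out_ch, in_ch // groups, kh, kw).
    """
    B, C, H, W = x.data.shape
    O, Cg, kh, kw = w.data.shape
    G = groups
    if C != Cg * G or O % G:
        raise ValueError("channel/group mismatch in conv2d")
    s = stride
    if padding == "same":
        pt, pb = _same_pad_amount(H, kh, s)
        pl, pr = _same_pad_amount(W, kw, s)
    elif padding == "valid":
        pt = pb = pl = pr = 0
    else:  # pragma: no cover
        raise ValueError(f"unknown padding {padding!r}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (pt, pb), (pl, pr))) if pt or pb or pl or pr else x.data
    Hp, Wp = xp.shape[2], xp.shape[3]
    oh = (Hp - kh) // s + 1
    ow = (Wp - kw) // s + 1
    if oh < 1 or ow < 1:
        raise ValueError(f"conv2d: input {H}x{W} too small for kernel {kh}x{kw}")
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]
    # (B, C, oh, ow, kh, kw) -> (B, P, C*kh*kw)
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        B, oh * ow, C * kh * kw
    )
    colsg = cols.reshape(B, oh * ow, G, Cg * kh * kw)
    Wm = w.data.reshape(G, O // G, Cg * kh * kw)
    y = np.einsum("bpgc,goc->bpgo", colsg, Wm, optimize=True)
    y = np.ascontiguousarray(y.reshape(B, oh, ow, O).transpose(0, 3, 1, 2))
    if b is not None:
        y = y + b.data[None, :, None, None]

    parents = (x, w) if b is None else (x, w, b)

    def backward(dy):
        dyc = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(
            B, oh * ow, G, O // G
        )
        if w.requires_grad:
            dW = np.einsum("bpgo,bpgc->goc", dyc, colsg, optimize=True)
            w._accumulate(dW.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accumulate(dy.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = np.einsum("bpgo,goc->bpgc", dyc, Wm, optimize=True).reshape(
                B, oh * ow, C * kh * kw
            )
            # scatter columns back into the padded input
            ii = (np.arange(oh) * s)[:, None, None, None, None]
            jj = (np.arange(ow) * s)[None, :, None, None, None]
            cc = np.arange(C)[None, None, :, None, None]
            uu = np.arange(kh)[None, None, None, :, None]
            vv = np.arange(kw)[None, None, None, None, :]
            flat = ((cc * Hp + ii + uu) * Wp + jj + vv).reshape(
                oh * ow, C * kh * kw
            )
            n = C * Hp * Wp
            dxp = np.empty((B, n), dtype=np.float32)
            fr = flat.ravel()
            for bi in range(B):
                dxp[bi] = np.bincount(fr, weights=dcols[bi].ravel(), minlength=n)
            dxp = dxp.reshape(B, C, Hp, Wp)
            x._accumulate(dxp[:, :, pt:Hp - pb or None, pl:Wp - pr or None])

    return Tensor(y, parents, backward)


def conv_transpose2x2(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """2x2 stride-2 transpose convolution (exact size doubling).

    ``w`` has shape (in_ch, out_ch, 2, 2).
    """
    B, C, H, W = x.data.shape
    Cw, O, kh, kw = w.data.shape
    if Cw != C or kh != 2 or kw != 2:
        raise ValueError("conv_transpose2x2 expects (in_ch, out_ch, 2, 2) weights")
    y = np.einsum("bcij,copq->boipjq", x.data, w.data, optimize=True)
    y = y.reshape(B, O, 2 * H, 2 * W)
    if b is not None:
        y = y + b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)

    def backward(dy):
        dyb = dy.reshape(B, O, H, 2, W, 2)
        if w.requires_grad:
            w._accumulate(np.einsum("bcij,boipjq->copq", x.data, dyb, optimize=True))
        if b is not None and b.requires_grad:
            b._accumulate(dy.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            x._accumulate(np.einsum("boipjq,copq->bcij", dyb, w.data, optimize=True))

    return Tensor(y, parents, backward)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, running_mean: np.ndarray,
               running_var: np.ndarray, training: bool, momentum: float = 0.1,
               eps: float = 1e-5) -> Tensor:
    """Channel-wise batch normalization (NCHW). Running stats update in place."""
    xd = x.data
    if training:
        mu = xd.mean(axis=(0, 2, 3))
        var = xd.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    ivstd = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mu[None, :, None, None]) * ivstd[None, :, None, None]
    y = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(dy):
        if gamma.requires_grad:
            gamma._accumulate((dy * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accumulate(dy.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            g = gamma.data[None, :, None, None]
            if training:
                N = xd.shape[0] * xd.shape[2] * xd.shape[3]
                dxhat = dy * g
                iv = ivstd[None, :, None, None]
                t1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
                t2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
                dx = (dxhat - t1 / N - xhat * t2 / N) * iv
            else:
                dx = dy * g * ivstd[None, :, None, None]
            x._accumulate(dx)

    return Tensor(y, (x, gamma, beta), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    y = x.data * mask

    def backward(dy):
        if x.requires_grad:
            x._accumulate(dy * mask)

    return Tensor(y, (x,), backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    if a.data.shape != b.data.shape:
        raise ValueError(f"add: shape mismatch {a.data.shape} vs {b.data.shape}")
    y = a.data + b.data

    def backward(dy):
        if a.requires_grad:
            a._accumulate(dy)
        if b.requires_grad:
            b._accumulate(dy)

    return Tensor(y, (a, b), backward)


def center_crop(x: Tensor, height: int, width: int | None = None) -> Tensor:
    """Centered spatial crop; offsets floor((size - side) / 2)."""
    width = height if width is None else width
    B, C, H, W = x.data.shape
    if H < height or W < width:
        raise ValueError(f"center_crop: {H}x{W} smaller than {height}x{width}")
    r0 = (H - height) // 2
    c0 = (W - width) // 2
    y = x.data[:, :, r0:r0 + height, c0:c0 + width]

    def backward(dy):
        if x.requires_grad:
            dx = np.zeros_like(x.data)
            dx[:, :, r0:r0 + height, c0:c0 + width] = dy
            x._accumulate(dx)

    return Tensor(y.copy(), (x,), backward)


def upsample_nearest(x: Tensor, factor: int = 2) -> Tensor:
    f = int(factor)
    y = x.data.repeat(f, axis=2).repeat(f, axis=3)

    def backward(dy):
        if x.requires_grad:
            B, C, H, W = x.data.shape
            x._accumulate(dy.reshape(B, C, H, f, W, f).sum(axis=(3, 5)))

    return Tensor(y, (x,), backward)


def resize_nearest(x: Tensor, height: int, width: int) -> Tensor:
    """Nearest-neighbor resize to an arbitrary spatial size."""
    B, C, H, W = x.data.shape
    ri = np.minimum((np.arange(height) * H) // height, H - 1)
    ci = np.minimum((np.arange(width) * W) // width, W - 1)
    y = x.data[:, :, ri[:, None], ci[None, :]]

    def backward(dy):
        if x.requires_grad:
            dx = np.zeros((B, C, H * W), dtype=np.float32)
            flat = (ri[:, None] * W + ci[None, :]).ravel()
            dyf = dy.reshape(B, C, -1)
            for bi in range(B):
                for cj in range(C):
                    dx[bi, cj] = np.bincount(flat, weights=dyf[bi, cj], minlength=H * W)
            x._accumulate(dx.reshape(B, C, H, W))

    return Tensor(y, (x,), backward)


def max_pool2d(x: Tensor, kernel: int = 3, stride: int = 2) -> Tensor:
    """Same-padded max pooling."""
    B, C, H, W = x.data.shape
    k, s = kernel, stride
    pt, pb = _same_pad_amount(H, k, s)
    pl, pr = _same_pad_amount(W, k, s)
    xp = np.pad(x.data, ((0, 0), (0, 0), (pt, pb), (pl, pr)),
                constant_values=-np.inf)
    Hp, Wp = xp.shape[2], xp.shape[3]
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
    oh, ow = win.shape[2], win.shape[3]
    wf = win.reshape(B, C, oh, ow, k * k)
    idx = wf.argmax(axis=-1)
    y = np.take_along_axis(wf, idx[..., None], axis=-1)[..., 0]

    def backward(dy):
        if x.requires_grad:
            ui, vi = np.divmod(idx, k)
            ii = np.arange(oh)[None, None, :, None] * s + ui
            jj = np.arange(ow)[None, None, None, :] * s + vi
            flat = (ii * Wp + jj).reshape(B, C, -1)
            n = Hp * Wp
            dxp = np.zeros((B, C, n), dtype=np.float32)
            dyf = dy.reshape(B, C, -1)
            for bi in range(B):
                for cj in range(C):
                    dxp[bi, cj] = np.bincount(flat[bi, cj], weights=dyf[bi, cj],
                                              minlength=n)
            dxp = dxp.reshape(B, C, Hp, Wp)
            x._accumulate(dxp[:, :, pt:Hp - pb or None, pl:Wp - pr or None])

    return Tensor(y, (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    B, C, H, W = x.data.shape
    y = x.data.mean(axis=(2, 3))

    def backward(dy):
        if x.requires_grad:
            x._accumulate(np.broadcast_to(dy[:, :, None, None] / (H * W),
                                          x.data.shape))

    return Tensor(y, (x,), backward)


def linear(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """Affine layer; ``w`` has shape (out, in)."""
    y = x.data @ w.data.T
    if b is not None:
        y = y + b.data
    parents = (x, w) if b is None else (x, w, b)

    def backward(dy):
        if w.requires_grad:
            w._accumulate(dy.T @ x.data)
        if b is not None and b.requires_grad:
            b._accumulate(dy.sum(axis=0))
        if x.requires_grad:
            x._accumulate(dy @ w.data)

    return Tensor(y, parents, backward)


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    e = np.exp(x.data - m)
    y = e / e.sum(axis=axis, keepdims=True)

    def backward(dy):
        if x.requires_grad:
            s = (dy * y).sum(axis=axis, keepdims=True)
            x._accumulate(y * (dy - s))

    return Tensor(y, (x,), backward)


def weighted_cross_entropy(probs: Tensor, target: np.ndarray,
                           weight_table: np.ndarray,
                           eps: float = 1e-7) -> Tensor:
    """Mean of ``w[true, predicted] * (-ln p_true)`` over all elements.

    ``probs`` holds class probabilities on axis 1 (either (B, K) or
    (B, K, H, W)); ``target`` holds integer class labels with the class axis
    removed.  ``weight_table[t, c]`` weights a true class ``t`` predicted as
    ``c``; the prediction is the argmax with ties resolved to the *highest*
    class index (consistent with inclusive foreground thresholding).  The
    weights multiply the loss only; they are treated as constants in the
    gradient.
    """
    p = probs.data
    K = p.shape[1]
    t = np.asarray(target)
    # tie-break argmax toward the highest class index
    pred = (K - 1) - np.argmax(p[:, ::-1, ...], axis=1)
    wt = np.asarray(weight_table, dtype=np.float32)[t, pred]
    tk = np.expand_dims(t, 1)
    pt = np.take_along_axis(p, tk, axis=1)[:, 0, ...]
    ptc = np.maximum(pt, eps)
    n = wt.size
    loss = float((wt * -np.log(ptc)).sum() / n)

    def backward(dy):
        if probs.requires_grad:
            dp = np.zeros_like(p)
            g = np.where(pt > eps, -wt / ptc, 0.0).astype(np.float32) * (dy / n)
            np.put_along_axis(dp, tk, np.expand_dims(g, 1), axis=1)
            probs._accumulate(dp)

    return Tensor(loss, (probs,), backward)
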