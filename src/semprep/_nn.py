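"""Minimal numpy autodiff-free CNN building blocks.

Hand-written forward/backward passes for the handful of layer types the
segmenter needs: same-padded convolutions (im2col), 2x2 max pooling,
nearest-neighbour upsampling, channel concatenation, ReLU, and a
per-pixel softmax cross-entropy head.  Arrays are NCHW float32.

Backward of a convolution w.r.t. its input is computed as a full
convolution of the output gradient with the spatially flipped,
channel-transposed kernel, which reuses the same im2col path.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "conv_forward",
    "conv_backward",
    "relu_forward",
    "relu_backward",
    "maxpool2_forward",
    "maxpool2_backward",
    "upsample2_forward",
    "upsample2_backward",
    "softmax",
    "softmax_ce",
    "Adadelta",
    "clip_grad_norm",
]


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N, H*W, C*k*k) column matrix for stride-1 conv."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (k, k), axis=(2, 3))  # (N, C, H, W, k, k)
    n, c, h, w = win.shape[:4]
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * w, c * k * k), (h, w)


def conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """Stride-1, same-padded convolution.  W is (c_out, c_in, k, k)."""
    c_out, c_in, k, _ = W.shape
    cols, (h, w) = _im2col(x, k, pad=k // 2)
    out = cols @ W.reshape(c_out, -1).T + b
    out = out.reshape(x.shape[0], h, w, c_out).transpose(0, 3, 1, 2)
    return out, (cols, x.shape)


def conv_backward(dout: np.ndarray, W: np.ndarray, cache):
    cols, x_shape = cache
    n, c_out, h, w = dout.shape
    dflat = dout.transpose(0, 2, 3, 1).reshape(n, h * w, c_out)
    dW = np.einsum("nhc,nhk->ck", dflat, cols).reshape(W.shape)
    db = dflat.sum(axis=(0, 1))
    # dx = full-conv of dout with flipped, channel-transposed kernel
    W_rot = W[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (c_in, c_out, k, k)
    dx, _ = conv_forward(dout, W_rot, np.zeros(W_rot.shape[0], dtype=W.dtype))
    return dx, dW, db


def relu_forward(x: np.ndarray):
    out = np.maximum(x, 0)
    return out, x > 0


def relu_backward(dout: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return dout * mask


def maxpool2_forward(x: np.ndarray):
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2 needs even spatial dims, got {(h, w)}")
    r = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    r = r.reshape(n, c, h // 2, w // 2, 4)
    idx = r.argmax(axis=-1)
    out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
    return out, (idx, x.shape)


def maxpool2_backward(dout: np.ndarray, cache) -> np.ndarray:
    idx, x_shape = cache
    n, c, h, w = x_shape
    dr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
    np.put_along_axis(dr, idx[..., None], dout[..., None], axis=-1)
    dr = dr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return dr.reshape(n, c, h, w)


def upsample2_forward(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=2).repeat(2, axis=3)


def upsample2_backward(dout: np.ndarray) -> np.ndarray:
    n, c, h, w = dout.shape
    return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def batchnorm_forward(x: np.ndarray, g: np.ndarray, b: np.ndarray,
                      running: dict, training: bool, momentum: float = 0.1,
                      eps: float = 1e-5):
    """Per-channel batch normalization with affine params.

    Training batches use their own statistics and update the running
    mean/variance; inference uses the running statistics — so inputs
    far from the training distribution genuinely shift the activations
    (the model stays sensitive to acquisition drift, it is not made
    invariant to it).
    """
    gc = g[None, :, None, None]
    bc = b[None, :, None, None]
    if training:
        mu = x.mean(axis=(0, 2, 3), keepdims=True)
        var = x.var(axis=(0, 2, 3), keepdims=True)
        running["mean"] = (1 - momentum) * running["mean"] + momentum * mu[0, :, 0, 0]
        running["var"] = (1 - momentum) * running["var"] + momentum * var[0, :, 0, 0]
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x - mu) * inv
        return xhat * gc + bc, (xhat, inv, g)
    mu = running["mean"][None, :, None, None]
    var = running["var"][None, :, None, None]
    xhat = (x - mu) / np.sqrt(var + eps)
    return xhat * gc + bc, None


def batchnorm_backward(dout: np.ndarray, cache):
    xhat, inv, g = cache
    dg = (dout * xhat).sum(axis=(0, 2, 3))
    db = dout.sum(axis=(0, 2, 3))
    dxhat = dout * g[None, :, None, None]
    m = dxhat.mean(axis=(0, 2, 3), keepdims=True)
    mx = (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
    dx = inv * (dxhat - m - xhat * mx)
    return dx, dg, db


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_ce(logits: np.ndarray, labels: np.ndarray):
    """Mean per-pixel categorical cross-entropy and its logit gradient.

    ``logits`` is (N, C, H, W); ``labels`` integer (N, H, W).
    """
    p = softmax(logits, axis=1)
    n, c, h, w = logits.shape
    onehot = np.zeros_like(p)
    np.put_along_axis(onehot, labels[:, None, :, :], 1.0, axis=1)
    eps = 1e-12
    loss = float(-(onehot * np.log(p + eps)).sum() / (n * h * w))
    dlogits = (p - onehot) / (n * h * w)
    return loss, dlogits


def clip_grad_norm(grads: list[np.ndarray], max_norm: float) -> float:
    """In-place global L2-norm gradient clipping; returns the pre-clip norm."""
    total = float(np.sqrt(sum(float((g * g).sum()) for g in grads)))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for g in grads:
            g *= scale
    return total


class Adadelta:
    """Adadelta optimizer (rho 0.9, eps 1e-6 defaults) over a parameter list."""

    def __init__(self, params: list[np.ndarray], rho: float = 0.9,
                 eps: float = 1e-6, lr: float = 1.0):
        self.params = params
        self.rho, self.eps, self.lr = rho, eps, lr
        self._eg2 = [np.zeros_like(p) for p in params]
        self._edx2 = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        rho, eps = self.rho, self.eps
        for p, g, eg2, edx2 in zip(self.params, grads, self._eg2, self._edx2):
            eg2 *= rho
            eg2 += (1 - rho) * g * g
            dx = -np.sqrt(edx2 + eps) / np.sqrt(eg2 + eps) * g
            edx2 *= rho
            edx2 += (1 - rho) * dx * dx
            p += self.lr * dx
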