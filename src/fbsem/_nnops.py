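"""Minimal CNN building blocks (forward + reverse-mode backward) in numpy.

Only what the residual learning unit needs: 3x3 same-padding convolution,
per-channel batch normalization with affine parameters, ReLU, and an Adam
optimizer. Tensors are (B, C, H, W) float64. Every backward pass is exercised
by finite-difference gradient checks in the test suite.
"""

from __future__ import annotations

import numpy as np

_BN_EPS = 1e-5


# ---------------------------------------------------------------- convolution
def _im2col3(x: np.ndarray) -> np.ndarray:
    """(B, C, H, W) -> (B, C*9, H*W) patches of the zero-padded input."""
    B, C, H, W = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    cols = np.empty((B, C, 9, H, W), dtype=x.dtype)
    k = 0
    for di in range(3):
        for dj in range(3):
            cols[:, :, k] = xp[:, :, di : di + H, dj : dj + W]
            k += 1
    return cols.reshape(B, C * 9, H * W)


def conv3_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """3x3 convolution, stride 1, zero padding 1.

    W has shape (C_out, C_in, 3, 3); returns ((B, C_out, H, W), cache).
    """
    B, C, H, Wd = x.shape
    cols = _im2col3(x)
    Wmat = W.reshape(W.shape[0], -1)  # (C_out, C_in*9)
    out = np.matmul(Wmat, cols) + b[None, :, None]
    # cache the input only; patches are recomputed in backward (memory over time)
    return out.reshape(B, W.shape[0], H, Wd), x


def conv3_backward(dout: np.ndarray, W: np.ndarray, cache):
    """Returns (dx, dW, db)."""
    x = cache
    cols = _im2col3(x)
    B, C, H, Wd = x.shape
    Cout = W.shape[0]
    dmat = dout.reshape(B, Cout, H * Wd)
    Wmat = W.reshape(Cout, -1)
    dW = np.einsum("bop,bcp->oc", dmat, cols).reshape(W.shape)
    db = dout.sum(axis=(0, 2, 3))
    dcols = np.matmul(Wmat.T, dmat).reshape(B, C, 9, H, Wd)
    dxp = np.zeros((B, C, H + 2, Wd + 2), dtype=x.dtype)
    k = 0
    for di in range(3):
        for dj in range(3):
            dxp[:, :, di : di + H, dj : dj + Wd] += dcols[:, :, k]
            k += 1
    return dxp[:, :, 1 : 1 + H, 1 : 1 + Wd], dW, db


# ---------------------------------------------------------- batch normalization
def bn_forward(x, gamma, beta, running_mean, running_var, training, momentum=0.1):
    """Per-channel batch norm. In training mode uses batch statistics over
    (B, H, W) and updates the running averages in place."""
    if training:
        mean = x.mean(axis=(0, 2, 3))
        var = x.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    ivstd = 1.0 / np.sqrt(var + _BN_EPS)
    xhat = (x - mean[None, :, None, None]) * ivstd[None, :, None, None]
    out = gamma[None, :, None, None] * xhat + beta[None, :, None, None]
    return out, (xhat, ivstd, gamma, training)


def bn_backward(dout, cache):
    """Returns (dx, dgamma, dbeta)."""
    xhat, ivstd, gamma, training = cache
    dgamma = np.sum(dout * xhat, axis=(0, 2, 3))
    dbeta = dout.sum(axis=(0, 2, 3))
    dxhat = dout * gamma[None, :, None, None]
    if not training:
        return dxhat * ivstd[None, :, None, None], dgamma, dbeta
    B, C, H, W = dout.shape
    n = B * H * W
    # batch statistics depend on x: full batch-norm backward
    sum_dxhat = dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
    sum_dxhat_xhat = np.sum(dxhat * xhat, axis=(0, 2, 3))[None, :, None, None]
    dx = (ivstd[None, :, None, None] / n) * (n * dxhat - sum_dxhat - xhat * sum_dxhat_xhat)
    return dx, dgamma, dbeta


# ------------------------------------------------------------------------ relu
def relu_forward(x):
    mask = x > 0
    return x * mask, mask


def relu_backward(dout, mask):
    return dout * mask


# ------------------------------------------------------------------------ adam
class Adam:
    """Adam with the standard bias correction."""

    def __init__(self, keys, lr=0.05, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: 0.0 for k in keys}
        self.v = {k: 0.0 for k in keys}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
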