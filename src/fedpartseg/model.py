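"""Trainable segmentation network and flat parameter view.

A deliberately small two-resolution U-shaped convolutional network
(encoder conv -> 2x2 average pool -> bottleneck conv -> nearest upsample ->
skip concatenation -> decoder conv -> 1x1 classification head) implemented
directly on numpy with analytic backward passes.  Forward and backward are
exact (verified against finite differences in the test suite), and every
parameter has a stable flat position so that gradient masks and
encoder/decoder-partitioned aggregation can index into one vector.

The parameter partition exposes three groups:

* ``encoder``  — the two downsampling-path convolutions,
* ``decoder``  — the post-skip convolution,
* ``head``     — the 1x1 per-voxel classifier.

Uncertainty-aware aggregation treats ``decoder`` + ``head`` as "the
decoder", the part of the network closest to the prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["SegNet", "ParamVector", "Adam", "softmax", "save_checkpoint",
           "load_checkpoint"]


def softmax(logits, axis=1):
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# conv primitives (stride 1, zero "same" padding)

def _im2col(x, kh, kw):
    """(B,C,H,W) -> padded patch matrix (B,H,W,C*kh*kw)."""
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # (B,C,H,W,kh,kw)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))


def _col2im(dcols, xshape, kh, kw):
    """Adjoint of :func:`_im2col`: scatter-add patches back to the image."""
    B, C, H, W = xshape
    ph, pw = kh // 2, kw // 2
    dxp = np.zeros((B, C, H + 2 * ph, W + 2 * pw))
    d = dcols.reshape(B, H, W, C, kh, kw).transpose(0, 3, 1, 2, 4, 5)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i:i + H, j:j + W] += d[:, :, :, :, i, j]
    return dxp[:, :, ph:ph + H, pw:pw + W]


def _conv_forward(x, w, b):
    cout, cin, kh, kw = w.shape
    cols = _im2col(x, kh, kw)  # (B,H,W,cin,kh,kw)
    B, H, W = cols.shape[:3]
    flat = cols.reshape(B * H * W, cin * kh * kw)
    out = flat @ w.reshape(cout, -1).T + b
    return out.reshape(B, H, W, cout).transpose(0, 3, 1, 2), (flat, x.shape)


def _conv_backward(dout, w, cache):
    flat, xshape = cache
    cout, cin, kh, kw = w.shape
    B, _, H, W = dout.shape
    dflat_out = dout.transpose(0, 2, 3, 1).reshape(B * H * W, cout)
    dw = (dflat_out.T @ flat).reshape(w.shape)
    db = dflat_out.sum(axis=0)
    dcols = dflat_out @ w.reshape(cout, -1)
    dx = _col2im(dcols, xshape, kh, kw)
    return dx, dw, db


_LEAK = 0.05  # LeakyReLU slope: keeps rare-class channels trainable


def _lrelu(z):
    return np.where(z > 0, z, _LEAK * z)


def _dlrelu(z):
    return np.where(z > 0, 1.0, _LEAK)


def _avgpool2(x):
    B, C, H, W = x.shape
    return x.reshape(B, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))


def _avgpool2_backward(dy):
    return np.repeat(np.repeat(dy, 2, axis=2), 2, axis=3) / 4.0


def _upsample2(x):
    return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)


def _upsample2_backward(dy):
    B, C, H, W = dy.shape
    return dy.reshape(B, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))


# ---------------------------------------------------------------------------


@dataclass
class ParamVector:
    """Flat view of all model parameters with a named group partition."""

    values: np.ndarray            # length P, float64
    partition: dict               # group name -> positional index array
    spec: tuple                   # ((name, shape, group), ...) declaration order

    @property
    def size(self):
        return self.values.size

    def group_indices(self, *groups):
        return np.concatenate([self.partition[g] for g in groups])

    @property
    def decoder_head_idx(self):
        """Positions aggregated with uncertainty-aware weights."""
        return self.group_indices("decoder", "head")

    def copy(self):
        return ParamVector(self.values.copy(), self.partition, self.spec)


class SegNet:
    """Two-level U-shaped per-voxel classifier over ``n_classes``+1 channels."""

    # (name, group) in declaration order; shapes fixed in __init__
    _LAYOUT = (
        ("enc1_w", "encoder"), ("enc1_b", "encoder"),
        ("enc2_w", "encoder"), ("enc2_b", "encoder"),
        ("dec_w", "decoder"), ("dec_b", "decoder"),
        ("head_w", "head"), ("head_b", "head"),
    )

    def __init__(self, n_classes=4, width=6, in_channels=1, seed=0):
        self.n_classes = n_classes
        self.n_channels = n_classes + 1
        self.width = width
        self.in_channels = in_channels
        w1, w2 = width, 2 * width
        rng = np.random.default_rng(seed)
        shapes = {
            "enc1_w": (w1, in_channels, 3, 3), "enc1_b": (w1,),
            "enc2_w": (w2, w1, 3, 3), "enc2_b": (w2,),
            "dec_w": (w1, w2 + w1, 3, 3), "dec_b": (w1,),
            "head_w": (self.n_channels, w1, 1, 1), "head_b": (self.n_channels,),
        }
        self.params = {}
        for name, _group in self._LAYOUT:
            shape = shapes[name]
            if name.endswith("_b"):
                self.params[name] = np.zeros(shape)
            else:
                fan_in = int(np.prod(shape[1:]))
                self.params[name] = rng.normal(0.0, np.sqrt(2.0 / fan_in), shape)
        self._spec = tuple(
            (name, shapes[name], group) for name, group in self._LAYOUT
        )

    # -- forward / backward -------------------------------------------------

    def _as_batch(self, images):
        x = np.asarray(images, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        if x.ndim == 3:
            x = x[:, None]
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channel(s), got shape {x.shape}"
            )
        if x.shape[2] % 2 or x.shape[3] % 2:
            raise ValueError("image height and width must be even (one 2x pooling)")
        return x

    def forward(self, images, return_cache=False):
        """Per-voxel class logits of shape (B, n_classes+1, H, W)."""
        p = self.params
        x = self._as_batch(images)
        z1, c1 = _conv_forward(x, p["enc1_w"], p["enc1_b"])
        a1 = _lrelu(z1)
        pool = _avgpool2(a1)
        z2, c2 = _conv_forward(pool, p["enc2_w"], p["enc2_b"])
        a2 = _lrelu(z2)
        up = _upsample2(a2)
        cat = np.concatenate([up, a1], axis=1)
        z3, c3 = _conv_forward(cat, p["dec_w"], p["dec_b"])
        a3 = _lrelu(z3)
        logits, c4 = _conv_forward(a3, p["head_w"], p["head_b"])
        if return_cache:
            cache = (z1, c1, z2, c2, z3, c3, a3, c4)
            return logits, cache
        return logits

    def backward(self, cache, dlogits):
        """Gradients of a scalar loss given d(loss)/d(logits)."""
        p = self.params
        z1, c1, z2, c2, z3, c3, a3, c4 = cache
        grads = {}
        da3, grads["head_w"], grads["head_b"] = _conv_backward(dlogits, p["head_w"], c4)
        dz3 = da3 * _dlrelu(z3)
        dcat, grads["dec_w"], grads["dec_b"] = _conv_backward(dz3, p["dec_w"], c3)
        w2 = 2 * self.width
        dup, da1_skip = dcat[:, :w2], dcat[:, w2:]
        da2 = _upsample2_backward(dup)
        dz2 = da2 * _dlrelu(z2)
        dpool, grads["enc2_w"], grads["enc2_b"] = _conv_backward(dz2, p["enc2_w"], c2)
        da1 = _avgpool2_backward(dpool) + da1_skip
        dz1 = da1 * _dlrelu(z1)
        _, grads["enc1_w"], grads["enc1_b"] = _conv_backward(dz1, p["enc1_w"], c1)
        return grads

    def predict_proba(self, images):
        return softmax(self.forward(images), axis=1)

    def predict_labels(self, images):
        return np.argmax(self.forward(images), axis=1).astype(np.int16)

    # -- flat parameter view -------------------------------------------------

    def flatten(self) -> ParamVector:
        """Concatenate all parameters (declaration order) into one vector."""
        chunks, partition, offset = [], {"encoder": [], "decoder": [], "head": []}, 0
        for name, shape, group in self._spec:
            flat = self.params[name].ravel()
            partition[group].append(np.arange(offset, offset + flat.size))
            chunks.append(flat)
            offset += flat.size
        part = {g: np.concatenate(ix) for g, ix in partition.items()}
        return ParamVector(np.concatenate(chunks).astype(np.float64), part, self._spec)

    def flatten_grads(self, grads: dict) -> np.ndarray:
        return np.concatenate([grads[name].ravel() for name, _, _ in self._spec])

    def set_flat(self, values: np.ndarray):
        values = np.asarray(values, dtype=np.float64)
        expected = sum(int(np.prod(s)) for _, s, _ in self._spec)
        if values.size != expected:
            raise ValueError(f"expected {expected} parameters, got {values.size}")
        offset = 0
        for name, shape, _ in self._spec:
            n = int(np.prod(shape))
            self.params[name] = values[offset:offset + n].reshape(shape).copy()
            offset += n
        return self

    def unflatten(self, pv: ParamVector):
        return self.set_flat(pv.values)

    @property
    def n_params(self):
        return sum(int(np.prod(s)) for _, s, _ in self._spec)

    def clone(self):
        m = SegNet(self.n_classes, self.width, self.in_channels, seed=0)
        m.set_flat(self.flatten().values)
        return m

    def config(self):
        return {
            "n_classes": self.n_classes,
            "width": self.width,
            "in_channels": self.in_channels,
        }


class Adam:
    """Adam optimizer over the flat parameter vector.

    The default inner optimizer for local training: the per-position second
    moments equalise gradient scales between the rarely active head
    channels of small organs and the rest of the network, which plain SGD
    conditions poorly on these losses.
    """

    def __init__(self, n_params, lr=0.02, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = np.zeros(n_params)
        self.v = np.zeros(n_params)
        self.t = 0

    def step(self, model, grad, lr_scale=1.0):
        self.t += 1
        self.m = self.beta1 * self.m + (1 - self.beta1) * grad
        self.v = self.beta2 * self.v + (1 - self.beta2) * grad * grad
        mhat = self.m / (1 - self.beta1 ** self.t)
        vhat = self.v / (1 - self.beta2 ** self.t)
        delta = self.lr * lr_scale * mhat / (np.sqrt(vhat) + self.eps)
        model.set_flat(model.flatten().values - delta)


def save_checkpoint(path, model: SegNet):
    """Persist parameter values + partition metadata + a config hash."""
    pv = model.flatten()
    cfg = model.config()
    np.savez_compressed(
        path,
        values=pv.values,
        encoder_idx=pv.partition["encoder"],
        decoder_idx=pv.partition["decoder"],
        head_idx=pv.partition["head"],
        n_classes=cfg["n_classes"],
        width=cfg["width"],
        in_channels=cfg["in_channels"],
        config_hash=hash(tuple(sorted(cfg.items()))) % (2**31),
    )


def load_checkpoint(path) -> SegNet:
    with np.load(path) as z:
        m = SegNet(int(z["n_classes"]), int(z["width"]), int(z["in_channels"]))
        m.set_flat(z["values"])
    return m
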