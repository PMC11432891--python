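"""Minimal differentiable-network substrate on autograd-wrapped numpy.

Parameters are nested dicts of float arrays ("pytrees"); forward functions are
pure functions of (params, inputs), which keeps every model in this package
deterministic and picklable as plain ``.npz`` checkpoints.  Convolutions are
expressed as sums over kernel-offset slices so that reverse-mode autograd sees
only padded slicing, ``einsum`` and broadcasting — all of which it supports
exactly.
"""

from __future__ import annotations

import autograd.numpy as anp
import numpy as np
from autograd import value_and_grad

DTYPE = np.float32


# ---------------------------------------------------------------------------
# pytree helpers
# ---------------------------------------------------------------------------

def tree_map(fn, tree):
    if isinstance(tree, dict):
        return {k: tree_map(fn, v) for k, v in tree.items()}
    if isinstance(tree, (list, tuple)):
        return type(tree)(tree_map(fn, v) for v in tree)
    return fn(tree)


def tree_leaves(tree, prefix=""):
    """Yield (dotted_path, leaf) pairs in deterministic (sorted-key) order."""
    if isinstance(tree, dict):
        for k in sorted(tree):
            yield from tree_leaves(tree[k], f"{prefix}{k}." if prefix or True else k)
        return
    if isinstance(tree, (list, tuple)):
        for i, v in enumerate(tree):
            yield from tree_leaves(v, f"{prefix}{i}.")
        return
    yield prefix[:-1], tree


def tree_size(tree) -> int:
    return int(sum(np.asarray(leaf).size for _, leaf in tree_leaves(tree)))


def tree_flatten(tree):
    """Flatten to a single float64 vector plus an unflatten closure."""
    paths, leaves = [], []
    for p, leaf in tree_leaves(tree):
        paths.append(p)
        leaves.append(np.asarray(leaf))
    shapes = [l.shape for l in leaves]
    sizes = [l.size for l in leaves]
    flat = np.concatenate([l.ravel().astype(np.float64) for l in leaves]) if leaves else np.zeros(0)

    def unflatten(vec):
        out = {}
        ofs = 0
        for p, shp, sz in zip(paths, shapes, sizes):
            chunk = np.asarray(vec[ofs:ofs + sz], dtype=DTYPE).reshape(shp)
            ofs += sz
            node = out
            keys = p.split(".")
            for k in keys[:-1]:
                node = node.setdefault(k, {})
            node[keys[-1]] = chunk
        return out

    return flat, unflatten


# ---------------------------------------------------------------------------
# initialisers
# ---------------------------------------------------------------------------

def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape).astype(DTYPE)


def linear_init(rng, din, dout):
    return {"W": glorot(rng, din, dout, (din, dout)), "b": np.zeros(dout, DTYPE)}


def conv_init(rng, cin, cout, k=3):
    fan_in, fan_out = cin * k * k, cout * k * k
    return {"W": glorot(rng, fan_in, fan_out, (k, k, cin, cout)),
            "b": np.zeros(cout, DTYPE)}


def layernorm_init(dim):
    return {"gamma": np.ones(dim, DTYPE), "beta": np.zeros(dim, DTYPE)}


# ---------------------------------------------------------------------------
# layers (all pure functions of params)
# ---------------------------------------------------------------------------

def linear(p, x):
    return anp.matmul(x, p["W"]) + p["b"]


from autograd.extend import defvjp, primitive


@primitive
def _im2col(x, k, stride, pad):
    """(B, C, H, W) -> (B, k*k*C, Ho, Wo) sliding patches, 'same'-padded."""
    B, C, H, W = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    Ho = (H - 1) // stride + 1 if pad else (H - k) // stride + 1
    Wo = (W - 1) // stride + 1 if pad else (W - k) // stride + 1
    return np.concatenate(
        [xp[:, :, di:di + stride * Ho:stride, dj:dj + stride * Wo:stride]
         for di in range(k) for dj in range(k)], axis=1)


def _im2col_vjp(ans, x, k, stride, pad):
    B, C, H, W = x.shape
    Ho, Wo = ans.shape[2], ans.shape[3]

    def back(g):
        gx = np.zeros((B, C, H + 2 * pad, W + 2 * pad), dtype=g.dtype)
        n = 0
        for di in range(k):
            for dj in range(k):
                gx[:, :, di:di + stride * Ho:stride,
                   dj:dj + stride * Wo:stride] += g[:, n * C:(n + 1) * C]
                n += 1
        return gx[:, :, pad:pad + H, pad:pad + W] if pad else gx

    return back


defvjp(_im2col, _im2col_vjp)


def conv2d(p, x, stride: int = 1):
    """NCHW conv with 'same' padding, as an im2col matmul (BLAS-backed)."""
    k = p["W"].shape[0]
    O = p["W"].shape[3]
    B, C, H, W = x.shape
    pad = (k - 1) // 2
    cols = _im2col(x, k, stride, pad)                       # (B, k*k*C, Ho, Wo)
    Ho, Wo = cols.shape[2], cols.shape[3]
    cols = anp.reshape(anp.transpose(cols, (0, 2, 3, 1)), (B * Ho * Wo, k * k * C))
    W2 = anp.reshape(p["W"], (k * k * C, O))                # (di, dj, c) major
    y = anp.matmul(cols, W2) + p["b"]
    return anp.transpose(anp.reshape(y, (B, Ho, Wo, O)), (0, 3, 1, 2))


def conv1x1(p, x):
    # x: (B, C, H, W); W: (C, O)
    B, C, H, W = x.shape
    y = anp.matmul(anp.reshape(anp.transpose(x, (0, 2, 3, 1)), (B * H * W, C)),
                   p["W"]) + p["b"]
    return anp.transpose(anp.reshape(y, (B, H, W, p["W"].shape[1])), (0, 3, 1, 2))


def upsample2(x):
    """Nearest-neighbour x2 upsampling (NCHW), autograd-safe."""
    B, C, H, W = x.shape
    x = anp.reshape(x, (B, C, H, 1, W, 1))
    x = x * anp.ones((1, 1, 1, 2, 1, 2), dtype=DTYPE)
    return anp.reshape(x, (B, C, 2 * H, 2 * W))


def relu(x):
    # mask-multiply instead of maximum: the comparison is untraced, so the
    # backward pass is a plain elementwise product
    return x * (x > 0)


def layernorm(p, x, eps: float = 1e-5):
    mu = anp.mean(x, axis=-1, keepdims=True)
    var = anp.mean((x - mu) ** 2, axis=-1, keepdims=True)
    return p["gamma"] * (x - mu) / anp.sqrt(var + eps) + p["beta"]


def softmax(x, axis=-1):
    x = x - anp.max(x, axis=axis, keepdims=True)
    e = anp.exp(x)
    return e / anp.sum(e, axis=axis, keepdims=True)


def log_softmax(x, axis=-1):
    x = x - anp.max(x, axis=axis, keepdims=True)
    return x - anp.log(anp.sum(anp.exp(x), axis=axis, keepdims=True))


def cross_entropy(logits, labels, axis=1):
    """Mean CE over all non-class axes. labels: integer array."""
    logp = log_softmax(logits, axis=axis)
    lab = np.asarray(labels)
    C = logp.shape[axis]
    eye = np.eye(C, dtype=DTYPE)
    if logits.ndim == 2:          # (B, C)
        onehot = eye[lab]
    elif logits.ndim == 4:        # (B, C, H, W); dense one-hot avoids the
        onehot = np.moveaxis(eye[lab], -1, 1)   # slow scatter-add backward
    else:
        raise ValueError(f"unsupported logits rank {logits.ndim}")
    return -anp.sum(logp * onehot) / (lab.size)


# ---------------------------------------------------------------------------
# AdamW
# ---------------------------------------------------------------------------

class AdamW:
    """Decoupled-weight-decay Adam over a flattened parameter pytree."""

    def __init__(self, params, lr: float = 1e-3, weight_decay: float = 1e-2,
                 betas=(0.9, 0.999), eps: float = 1e-8, no_decay_paths=()):
        flat, self._unflatten = tree_flatten(params)
        self.theta = flat
        self.m = np.zeros_like(flat)
        self.v = np.zeros_like(flat)
        self.t = 0
        self.lr, self.wd, self.betas, self.eps = lr, weight_decay, betas, eps
        # weight decay is skipped on masks / norm gains, as is conventional
        self.decay_mask = np.ones_like(flat)
        if no_decay_paths:
            ofs = 0
            for p, leaf in tree_leaves(params):
                sz = np.asarray(leaf).size
                if any(p.startswith(nd) or nd in p for nd in no_decay_paths):
                    self.decay_mask[ofs:ofs + sz] = 0.0
                ofs += sz

    @property
    def params(self):
        return self._unflatten(self.theta)

    def step(self, grads) -> None:
        g, _ = tree_flatten(grads)
        if not np.all(np.isfinite(g)):
            raise FloatingPointError("non-finite gradient")
        b1, b2 = self.betas
        self.t += 1
        self.m = b1 * self.m + (1 - b1) * g
        self.v = b2 * self.v + (1 - b2) * g * g
        mh = self.m / (1 - b1 ** self.t)
        vh = self.v / (1 - b2 ** self.t)
        self.theta = self.theta - self.lr * (mh / (np.sqrt(vh) + self.eps)
                                             + self.wd * self.decay_mask * self.theta)


def loss_and_grad(loss_fn):
    """value_and_grad wrapper keeping the pytree structure of params."""
    return value_and_grad(loss_fn)
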