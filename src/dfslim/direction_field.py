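"""Directional-field ground truth, learned field head, and pixel rectification.

The ground-truth field assigns every tissue pixel m the unit vector from its
nearest same-class boundary pixel b toward m (inward orientation):
``D(m) = (m - b) / |m - b|``; background pixels and boundary pixels themselves
carry (0, 0).  A boundary pixel is a tissue pixel with at least one
4-connected neighbour of a different class (pixels on the image border count
as boundary).  Rectification iterates

    F_i(p) = F_{i-1}(p_x + D(p)_x, p_y + D(p)_y),   i = 1..N,

sampling bilinearly at the displaced location with border clamping — features
just inside a region's rim are pulled inward, which snaps mislabelled
boundary pixels to the class of the adjacent interior.  Coordinates are
(x = column, y = row), 0-based, pixel centres at integers; field channel 0 is
the x-component, channel 1 the y-component.
"""

from __future__ import annotations

import autograd.numpy as anp
import numpy as np
from autograd.extend import defvjp, primitive
from autograd.tracer import getval
from scipy import ndimage

from . import nn


# ---------------------------------------------------------------------------
# ground truth field
# ---------------------------------------------------------------------------

def boundary_pixels(mask: np.ndarray, cls: int) -> np.ndarray:
    """Boolean map of class-``cls`` pixels with a 4-neighbour of another class."""
    region = mask == cls
    padded = np.pad(mask, 1, constant_values=-1)
    differs = np.zeros_like(region)
    for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        nb = padded[1 + dy:1 + dy + mask.shape[0], 1 + dx:1 + dx + mask.shape[1]]
        differs |= nb != mask
    return region & differs


def gt_direction_field(mask: np.ndarray) -> np.ndarray:
    """Ground-truth 2-channel direction field of an integer label mask.

    Returns float array (2, H, W); per-pixel magnitude is exactly 0 (background
    and boundary pixels) or 1 (interior tissue pixels).  The nearest boundary
    pixel is found per class region via an exact Euclidean distance transform
    with nearest-site indices; distance ties resolve to the transform's first
    site.
    """
    mask = np.asarray(mask)
    H, W = mask.shape
    field = np.zeros((2, H, W), np.float64)
    for cls in np.unique(mask):
        if cls == 0:
            continue
        region = mask == cls
        bnd = boundary_pixels(mask, int(cls))
        if not bnd.any():
            continue
        _, (by, bx) = ndimage.distance_transform_edt(~bnd, return_indices=True)
        yy, xx = np.mgrid[0:H, 0:W]
        interior = region & ~bnd
        dy = (yy - by)[interior].astype(np.float64)
        dx = (xx - bx)[interior].astype(np.float64)
        norm = np.hypot(dx, dy)
        norm[norm == 0] = 1.0
        field[0][interior] = dx / norm
        field[1][interior] = dy / norm
    return field


# ---------------------------------------------------------------------------
# learned field head
# ---------------------------------------------------------------------------

def df_head_init(rng: np.random.Generator, in_channels: int = 64) -> dict:
    return {"W": nn.glorot(rng, in_channels, 2, (in_channels, 2)),
            "b": np.zeros(2, nn.DTYPE)}


def df_head(params: dict, features):
    """1x1 convolution mapping 64 feature channels to a 2-channel field."""
    in_ch = params["W"].shape[0]
    got = features.shape[-3]
    if got != in_ch:
        raise ValueError(f"df_head expects {in_ch} channels, got {got}")
    return nn.conv1x1(params, features)


def field_loss(pred, gt, tissue_mask):
    """Mean squared field error over tissue pixels (background excluded)."""
    m = np.asarray(tissue_mask, nn.DTYPE)
    n = float(m.sum())
    if n == 0:
        return 0.0
    if pred.ndim == 4:
        m = m[:, None] if m.ndim == 3 else m[None, None]
    else:
        m = m[None]
    return anp.sum(((pred - gt) ** 2) * m) / (2.0 * n)


# ---------------------------------------------------------------------------
# rectification
# ---------------------------------------------------------------------------

def _corners(F_shape, xs, ys):
    B, C, H, W = F_shape
    xs = np.clip(xs, 0.0, W - 1.0)
    ys = np.clip(ys, 0.0, H - 1.0)
    x0 = np.floor(xs).astype(np.intp)
    y0 = np.floor(ys).astype(np.intp)
    x1 = np.minimum(x0 + 1, W - 1)
    y1 = np.minimum(y0 + 1, H - 1)
    wx = (xs - x0)[:, None]
    wy = (ys - y0)[:, None]
    return x0, y0, x1, y1, wx, wy


def _gather_corners(F, x0, y0, x1, y1):
    bidx = np.arange(F.shape[0])[:, None, None, None]
    cidx = np.arange(F.shape[1])[None, :, None, None]
    f00 = F[bidx, cidx, y0[:, None], x0[:, None]]
    f01 = F[bidx, cidx, y0[:, None], x1[:, None]]
    f10 = F[bidx, cidx, y1[:, None], x0[:, None]]
    f11 = F[bidx, cidx, y1[:, None], x1[:, None]]
    return f00, f01, f10, f11


@primitive
def _bilinear_sample(F, xs, ys):
    """Sample (B, C, H, W) feature maps at (B, H, W) float coords, clamped.

    A hand-differentiated primitive: the reverse pass scatters through
    ``bincount`` instead of autograd's generic (and slow) indexed-add.
    """
    x0, y0, x1, y1, wx, wy = _corners(F.shape, xs, ys)
    f00, f01, f10, f11 = _gather_corners(F, x0, y0, x1, y1)
    return ((1 - wy) * ((1 - wx) * f00 + wx * f01)
            + wy * ((1 - wx) * f10 + wx * f11))


def _bilinear_vjp_F(ans, F, xs, ys):
    B, C, H, W = F.shape
    x0, y0, x1, y1, wx, wy = _corners(F.shape, xs, ys)
    base = (np.arange(B)[:, None, None, None] * C
            + np.arange(C)[None, :, None, None]) * (H * W)

    def scatter(g):
        out = np.zeros(B * C * H * W)
        for yi, xi, w in ((y0, x0, (1 - wy) * (1 - wx)), (y0, x1, (1 - wy) * wx),
                          (y1, x0, wy * (1 - wx)), (y1, x1, wy * wx)):
            idx = base + yi[:, None] * W + xi[:, None]
            out += np.bincount(idx.ravel(),
                               weights=(g * w).ravel().astype(np.float64),
                               minlength=out.size)
        return out.reshape(F.shape).astype(F.dtype)

    return scatter


def _grad_wrt_coord(F, xs, ys, horizontal):
    x0, y0, x1, y1, wx, wy = _corners(F.shape, xs, ys)
    f00, f01, f10, f11 = _gather_corners(F, x0, y0, x1, y1)
    if horizontal:
        return (1 - wy) * (f01 - f00) + wy * (f11 - f10)
    return (1 - wx) * (f10 - f00) + wx * (f11 - f01)


def _bilinear_vjp_xs(ans, F, xs, ys):
    d = _grad_wrt_coord(F, xs, ys, True)
    inside = ((xs > 0) & (xs < F.shape[3] - 1)).astype(F.dtype)
    return lambda g: np.sum(g * d, axis=1) * inside


def _bilinear_vjp_ys(ans, F, xs, ys):
    d = _grad_wrt_coord(F, xs, ys, False)
    inside = ((ys > 0) & (ys < F.shape[2] - 1)).astype(F.dtype)
    return lambda g: np.sum(g * d, axis=1) * inside


defvjp(_bilinear_sample, _bilinear_vjp_F, _bilinear_vjp_xs, _bilinear_vjp_ys)


def rectify(F0, D, N: int = 5):
    """Iteratively re-sample F along the fixed direction field D, N times.

    F0: (C, H, W) or (B, C, H, W); D: (2, H, W) or (B, 2, H, W).
    N = 0 or an all-zero field return F0 unchanged (integer-coordinate
    bilinear sampling is exact).

    The field acts as a constant displacement: gradients flow through the
    sampled features, while the field head itself is trained by its own
    supervision loss rather than through the resampling coordinates.
    """
    squeeze = F0.ndim == 3
    if squeeze:
        F0 = F0[None]
    D = getval(D)
    if D.ndim == 3:
        D = D[None]
    B, C, H, W = F0.shape
    if D.shape[-2:] != (H, W) or D.shape[-3] != 2:
        raise ValueError(f"field shape {D.shape} does not match features {F0.shape}")
    if D.shape[0] == 1 and B > 1:
        D = np.broadcast_to(D, (B,) + D.shape[1:])
    yy, xx = np.mgrid[0:H, 0:W].astype(nn.DTYPE)
    xs = xx[None] + D[:, 0]
    ys = yy[None] + D[:, 1]
    F = F0
    for _ in range(N):
        F = _bilinear_sample(F, xs, ys)
    return F[0] if squeeze else F


# ---------------------------------------------------------------------------
# fusion
# ---------------------------------------------------------------------------

def fuse_init(rng: np.random.Generator, n_classes: int) -> dict:
    """1x1 fusion classifier over [FN, FN'] initialised to pass FN through,
    so an untrained DF branch reproduces the plain classifier exactly."""
    W = np.zeros((2 * n_classes, n_classes), nn.DTYPE)
    W[:n_classes] = np.eye(n_classes, dtype=nn.DTYPE)
    return {"W": W, "b": np.zeros(n_classes, nn.DTYPE)}


def fuse_and_classify(params: dict, FN, FNp):
    """Concatenate FN and FN' channel-wise and apply the 1x1 classifier."""
    if FN.shape != FNp.shape:
        raise ValueError(f"grid mismatch: {FN.shape} vs {FNp.shape}")
    cat = anp.concatenate([FN, FNp], axis=-3)
    return nn.conv1x1(params, cat)
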