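"""Synthetic data with the structure the method assumes.

Two families:

* **Cardiac phantoms** — 2-D short-axis-like images with a bright ventricular
  cavity (LV-like, class 3), a mid-grey myocardial ring strictly between
  cavity and background (MYO-like, class 2) and an adjacent crescent
  (RV-like, class 1) on a dark background, with Gaussian boundary blur and
  additive noise emulating the blurred tissue boundaries and acquisition
  noise of cine-MR.  Labels are the pre-blur geometry.
* **Planted-importance tasks** — tiny token-classification problems in which
  the label is carried *only* through a known subset of searchable
  dimensions (MHSA head dims, MLP hidden dims, or patches), so a correct
  importance ranking is known a priori and search recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import autograd.numpy as anp
import numpy as np
from scipy import ndimage

from . import nn
from .config import SearchSpaceConfig
from .masked_transformer import MaskSet, masked_mhsa_forward, masked_patch_forward

# class labels
BG, RV, MYO, LV = 0, 1, 2, 3

# intensity means (image values in [0, 1])
_INTENS = {BG: 0.15, RV: 0.55, MYO: 0.40, LV: 0.80}

# generator's own class-area design bounds, as fractions of the image
# (used by the Monte-Carlo self-check, not enforced per sample)
CLASS_AREA_BOUNDS = {RV: (0.005, 0.12), MYO: (0.015, 0.14), LV: (0.015, 0.12)}


@dataclass
class PhantomSample:
    image: np.ndarray      # (H, W) float in [0, 1]
    labels: np.ndarray     # (H, W) int in {0..3}
    meta: dict = field(default_factory=dict)


def _ellipse(size: int, cy, cx, ry, rx, angle=0.0) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    ca, sa = np.cos(angle), np.sin(angle)
    u = (xx - cx) * ca + (yy - cy) * sa
    v = -(xx - cx) * sa + (yy - cy) * ca
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def generate_phantom(seed: int, size: int = 64, noise_sigma: float = 0.08,
                     blur_sigma: float = 1.0) -> PhantomSample:
    """Draw one cardiac-like phantom; bit-identical under the same arguments.

    Degenerate geometries (too-thin ring, crescent clipped away) are rejected
    and resampled from the same stream.
    """
    if size < 32:
        raise ValueError("phantom size must be >= 32")
    rng = np.random.default_rng(seed)
    for _attempt in range(64):
        cy, cx = (size / 2 + rng.uniform(-0.06, 0.06) * size for _ in range(2))
        r_lv = rng.uniform(0.10, 0.15) * size
        th = rng.uniform(0.06, 0.10) * size
        ecc = rng.uniform(0.85, 1.18)
        ang = rng.uniform(0, np.pi)
        theta = rng.uniform(0, 2 * np.pi)
        r_rv = rng.uniform(0.10, 0.15) * size
        r_myo = r_lv + th
        dist = r_myo + 0.55 * r_rv
        rv_cy, rv_cx = cy + dist * np.sin(theta), cx + dist * np.cos(theta)

        lv = _ellipse(size, cy, cx, r_lv * ecc, r_lv / ecc, ang)
        myo_full = _ellipse(size, cy, cx, r_myo * ecc, r_myo / ecc, ang)
        rv_disk = _ellipse(size, rv_cy, rv_cx, r_rv, r_rv * rng.uniform(0.8, 1.1))
        labels = np.zeros((size, size), np.int64)
        labels[rv_disk & ~myo_full] = RV
        labels[myo_full & ~lv] = MYO
        labels[lv] = LV
        # rejection: all three classes present with sane areas, ring intact
        areas = {c: (labels == c).mean() for c in (RV, MYO, LV)}
        if min(areas.values()) < 0.004:
            continue
        ring = labels == MYO
        if ndimage.binary_dilation(labels == LV)[~(ring | (labels == LV))].any():
            continue  # LV touches non-ring: ring not closed
        break
    else:
        raise RuntimeError("could not sample a valid phantom geometry")

    img = np.full((size, size), _INTENS[BG])
    for c in (RV, MYO, LV):
        img[labels == c] = _INTENS[c] + rng.uniform(-0.05, 0.05)
    if blur_sigma > 0:
        img = ndimage.gaussian_filter(img, blur_sigma)
    if noise_sigma > 0:
        img = img + rng.normal(0, noise_sigma, img.shape)
    img = np.clip(img, 0.0, 1.0)
    meta = {"seed": int(seed), "size": int(size), "center": (float(cy), float(cx)),
            "radii": {"lv": float(r_lv), "myo": float(r_myo), "rv": float(r_rv)},
            "noise_sigma": float(noise_sigma), "blur_sigma": float(blur_sigma)}
    return PhantomSample(img.astype(np.float64), labels, meta)


def generate_dataset(seed: int, n: int, split=(7, 1, 2), size: int = 64,
                     noise_sigma: float = 0.08, blur_sigma: float = 1.0):
    """n phantoms deterministically split by sample into train/val/test.

    Split ratios are normalised; counts are floor(train), floor(val),
    remainder test (so 100 at 7:1:2 gives 70/10/20).
    """
    ratios = np.asarray(split, np.float64)
    ratios = ratios / ratios.sum()
    n_train = int(np.floor(n * ratios[0]))
    n_val = int(np.floor(n * ratios[1]))
    n_test = n - n_train - n_val
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(f"n={n} too small for a non-empty {split} split")
    rng = np.random.default_rng(seed)
    sample_seeds = rng.integers(0, 2 ** 31 - 1, size=n)
    samples = [generate_phantom(int(s), size, noise_sigma, blur_sigma)
               for s in sample_seeds]
    order = rng.permutation(n)
    splits = {"train": [samples[i] for i in order[:n_train]],
              "val": [samples[i] for i in order[n_train:n_train + n_val]],
              "test": [samples[i] for i in order[n_train + n_val:]]}
    ids = {k: [int(sample_seeds[i]) for i in idx] for k, idx in
           zip(splits, (order[:n_train], order[n_train:n_train + n_val],
                        order[n_train + n_val:]))}
    return splits, ids


def generate_volume(seed: int, depth: int = 10, size: int = 64,
                    noise_sigma: float = 0.08, blur_sigma: float = 1.0):
    """Stack phantoms with smoothly varying radii into an (H, W, depth) volume
    (apex-to-base emulation for NIfTI slicing)."""
    rng = np.random.default_rng(seed)
    base = generate_phantom(int(rng.integers(0, 2 ** 31 - 1)), size, 0.0, 0.0)
    imgs, labs = [], []
    for k in range(depth):
        # taper toward the apex: erode the tissue union slice by slice
        it = int(round(3 * k / max(depth - 1, 1)))
        lab = base.labels.copy()
        if it:
            tissue = ndimage.binary_erosion(lab > 0, iterations=it)
            lab[~tissue] = BG
        img = np.full((size, size), _INTENS[BG])
        for c in (RV, MYO, LV):
            img[lab == c] = _INTENS[c]
        if blur_sigma > 0:
            img = ndimage.gaussian_filter(img, blur_sigma)
        if noise_sigma > 0:
            img = img + rng.normal(0, noise_sigma, img.shape)
        imgs.append(np.clip(img, 0.0, 1.0))
        labs.append(lab)
    return np.stack(imgs, axis=-1), np.stack(labs, axis=-1).astype(np.int64)


# ---------------------------------------------------------------------------
# planted-importance tasks
# ---------------------------------------------------------------------------

@dataclass
class PlantedTask:
    X: np.ndarray                     # (n, N, D) token inputs
    y: np.ndarray                     # (n,) binary labels
    config: SearchSpaceConfig
    kind: str                         # 'mhsa' | 'mlp' | 'patch'
    signal_sites: List[Tuple]         # (layer, head, index) / (layer, index)
    seed: int


class PlantedClassifier:
    """Minimal masked model for planted tasks: one masked block, mean-pool,
    linear head.  No residual path, so the label signal must flow through the
    masked activations — zeroing a signal dimension provably hurts CE while
    zeroing a noise dimension cannot help it.
    """

    def __init__(self, config: SearchSpaceConfig, kind: str, seed: int):
        if config.L != 1:
            raise ValueError("planted tasks use a single masked block (L=1)")
        self.config = config
        self.kind = kind
        rng = np.random.default_rng(seed)
        D = config.D
        if kind == "mhsa":
            eye = np.eye(D, dtype=nn.DTYPE)
            body = {"Wq": 0.01 * nn.glorot(rng, D, D, (D, D)),
                    "bq": np.zeros(D, nn.DTYPE),
                    "Wk": 0.01 * nn.glorot(rng, D, D, (D, D)),
                    "bk": np.zeros(D, nn.DTYPE),
                    "Wv": eye.copy(), "bv": np.zeros(D, nn.DTYPE),
                    "Wo": eye.copy(), "bo": np.zeros(D, nn.DTYPE)}
            head_in = D
        elif kind == "mlp":
            if config.M != D:
                raise ValueError("identity routing needs M == D")
            body = {"f1": {"W": np.eye(D, dtype=nn.DTYPE),
                           "b": np.zeros(D, nn.DTYPE)},
                    "f2": {"W": np.eye(D, dtype=nn.DTYPE),
                           "b": np.zeros(D, nn.DTYPE)}}
            head_in = D
        elif kind == "patch":
            body = {}
            head_in = D
        else:
            raise ValueError(f"unknown planted kind {kind!r}")
        # zero head: the CE gradient on the masks vanishes at step one, so the
        # L1 penalty acts immediately while the head learns which dims matter
        head = {"W": np.zeros((head_in, 2), nn.DTYPE), "b": np.zeros(2, nn.DTYPE)}
        self.params = {"body": body, "head": head,
                       "masks": MaskSet.ones(config).to_params()}

    def forward(self, params, x):
        cfg, m = self.config, params["masks"]
        if self.kind == "mhsa":
            z = anp.reshape(m["z_mhsa"][0], (cfg.H, cfg.d))
            t = masked_mhsa_forward(params["body"], x, z, cfg.d)
        elif self.kind == "mlp":
            t = nn.linear(params["body"]["f2"],
                          nn.linear(params["body"]["f1"], x) * m["z_mlp"][0])
        else:  # patch
            t = masked_patch_forward(x, m["z_patch"][0])
        pooled = anp.mean(t, axis=1)
        return nn.linear(params["head"], pooled)

    def loss_ce(self, params, xb, yb):
        return nn.cross_entropy(self.forward(params, xb), yb)


def generate_planted_task(seed: int, config: SearchSpaceConfig, k_signal: int,
                          kind: str = "mhsa", n_samples: int = 512,
                          amplitude: float = 2.0) -> PlantedTask:
    """Build inputs whose labels flow only through ``k_signal`` chosen sites.

    For 'mhsa' the identity v/o routing of PlantedClassifier maps input
    feature channel h*d+j onto head-dim (h, j), so planting the label mean in
    channel c makes exactly dim (0, h, j) informative; noise channels are
    independent N(0, 1).  'mlp' plants channels through the identity f1;
    'patch' plants whole tokens.
    """
    total = {"mhsa": config.H * config.d, "mlp": config.M,
             "patch": config.N}[kind]
    if k_signal > total:
        raise ValueError(f"k_signal={k_signal} exceeds {total} searchable sites")
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(total, size=k_signal, replace=False).tolist()) \
        if k_signal else []
    y = rng.integers(0, 2, size=n_samples)
    sgn = (2 * y - 1).astype(np.float64)
    X = rng.standard_normal((n_samples, config.N, config.D))
    if kind in ("mhsa", "mlp"):
        for c in chosen:
            X[:, :, c] += sgn[:, None] * amplitude
        if kind == "mhsa":
            sites = [(0, c // config.d, c % config.d) for c in chosen]
        else:
            sites = [(0, c) for c in chosen]
    else:  # patch: planted tokens carry the label in every channel's mean
        for j in chosen:
            X[:, j, :] += sgn[:, None] * amplitude
        sites = [(0, j) for j in chosen]
    return PlantedTask(X.astype(nn.DTYPE), y, config, kind, sites, seed)


def signal_sites_in_bottom(ranking, task: PlantedTask, n_bottom: int) -> int:
    """How many planted signal sites fall in the lowest n_bottom ranks of
    their kind (0 = perfect recovery)."""
    kind = {"mhsa": "mhsa-dim", "mlp": "mlp-dim", "patch": "patch"}[task.kind]
    items = [r for r in ranking if r.kind == kind]
    bottom = items[:n_bottom]
    if task.kind == "mhsa":
        sigs = set(task.signal_sites)
        return sum((r.layer, r.head, r.index) in sigs for r in bottom)
    sigs = {(l, i) for l, i in task.signal_sites}
    return sum((r.layer, r.index) in sigs for r in bottom)
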