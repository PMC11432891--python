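"""Single-round sparsity search: CE + L1 co-training of weights and masks.

The objective is ``L_CE(f(z * T(W, x)), y) + ||z||_1`` with per-group penalty
weights — the L1 term pulls mask magnitudes toward zero while the CE term
defends the dimensions the task actually needs, so after training the mask
magnitude of a site is its global importance score.  One search yields a
ranking from which any budget's subnet can be read off with no further
training.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import autograd.numpy as anp
import numpy as np

from . import nn
from .config import OptimizerSettings, SearchSpaceConfig
from .masked_transformer import MaskSet

KINDS = ("mhsa-dim", "mlp-dim", "patch")


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def l1_penalty(mask_params, cfg: SearchSpaceConfig):
    """Weighted L1 of the mask groups; patches are penalised through tanh."""
    pen = 0.0
    if cfg.search_mhsa and cfg.w_mhsa > 0:
        pen = pen + cfg.w_mhsa * anp.sum(anp.abs(mask_params["z_mhsa"]))
    if cfg.search_mlp and cfg.w_mlp > 0:
        pen = pen + cfg.w_mlp * anp.sum(anp.abs(mask_params["z_mlp"]))
    if cfg.search_patch and cfg.w_patch > 0:
        pen = pen + cfg.w_patch * anp.sum(anp.abs(anp.tanh(mask_params["z_patch"])))
    return pen


def search_loss(logits, targets, masks, config: SearchSpaceConfig,
                return_parts: bool = False):
    """Cross-entropy plus the weighted L1 mask penalty (added once per step)."""
    targets = np.asarray(targets)
    lshape = np.asarray(logits).shape if not hasattr(logits, "shape") else logits.shape
    if len(lshape) == 4 and (lshape[0] != targets.shape[0]
                             or tuple(lshape[2:]) != targets.shape[1:]):
        raise ValueError(f"logits {lshape} / targets {targets.shape} misaligned")
    mask_params = masks.to_params() if isinstance(masks, MaskSet) else masks
    ce = nn.cross_entropy(logits, targets)
    pen = l1_penalty(mask_params, config)
    if return_parts:
        return ce + pen, ce, pen
    return ce + pen


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class SearchResult:
    masks: MaskSet
    ce_trace: List[float]
    l1_trace: List[float]
    epochs: int
    optimizer: OptimizerSettings
    seed: int

    def __post_init__(self):
        if len(self.ce_trace) != self.epochs or len(self.l1_trace) != self.epochs:
            raise ValueError("loss trace length must equal epochs run")
        if not (np.all(np.isfinite(self.ce_trace)) and np.all(np.isfinite(self.l1_trace))):
            raise ValueError("non-finite loss in trace")


@dataclass
class RankedDimension:
    kind: str           # 'mhsa-dim' | 'mlp-dim' | 'patch'
    layer: int
    head: Optional[int]  # mhsa only
    index: int
    score: float         # |z|, or |tanh(z)| for patches

    def site(self):
        return (self.layer, self.head, self.index)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def run_search(model, data, epochs: int = 50, seed: int = 0,
               optimizer: OptimizerSettings | None = None) -> SearchResult:
    """Jointly train weights and masks of ``model`` by AdamW on ``data``.

    ``model`` exposes ``.config`` (SearchSpaceConfig), ``.params`` (pytree with
    a ``masks`` namespace) and ``.loss_ce(params, xb, yb) -> scalar``; ``data``
    is an ``(X, y)`` pair of arrays indexed along axis 0.  Deterministic under
    fixed seed and data order; updates ``model.params`` in place.
    """
    opt_cfg = optimizer or OptimizerSettings()
    X, y = data
    n = len(X)
    if n == 0:
        raise ValueError("empty training set")
    cfg = model.config
    get_masks = getattr(model, "mask_params", None) or (lambda p: p["masks"])

    def current_masks():
        md = get_masks(model.params)
        return MaskSet(np.asarray(md["z_mhsa"]), np.asarray(md["z_mlp"]),
                       np.asarray(md["z_patch"]))

    if epochs == 0:
        return SearchResult(current_masks(), [], [], 0, opt_cfg, seed)

    def total_loss(params, xb, yb):
        return model.loss_ce(params, xb, yb) + l1_penalty(get_masks(params), cfg)

    vg = nn.loss_and_grad(total_loss)
    opt = nn.AdamW(model.params, lr=opt_cfg.lr, weight_decay=opt_cfg.weight_decay,
                   no_decay_paths=("masks", "gamma", "beta"))
    rng = np.random.default_rng(seed)
    bs = min(opt_cfg.batch_size, n)
    ce_trace, l1_trace = [], []
    for epoch in range(epochs):
        order = rng.permutation(n)
        ce_sum, steps = 0.0, 0
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            params = opt.params
            loss, grads = vg(params, X[idx], y[idx])
            if not np.isfinite(loss):
                ce = float(model.loss_ce(params, X[idx], y[idx]))
                term = "cross-entropy" if not np.isfinite(ce) else "L1 penalty"
                raise FloatingPointError(
                    f"non-finite {term} at epoch {epoch + 1}")
            pen = float(l1_penalty(get_masks(params), cfg))
            ce_sum += float(loss) - pen
            steps += 1
            opt.step(grads)
        model.params = opt.params
        ce_trace.append(ce_sum / steps)
        l1_trace.append(float(l1_penalty(get_masks(model.params), cfg)))
    return SearchResult(current_masks(), ce_trace, l1_trace,
                        epochs, opt_cfg, seed)


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

def rank_dimensions(masks: MaskSet) -> List[RankedDimension]:
    """Rank every searchable site ascending by importance score, per kind.

    Score is |z| for MHSA/MLP dims and |tanh(z)| for patches — the penalty
    drives magnitudes toward zero and a large-magnitude negative mask still
    transmits signal, so elimination targets low influence, not low signed
    value.  Ties break by (layer, head, index); the order is stable and total.
    """
    out: List[RankedDimension] = []
    z_a, z_m, z_p = (np.asarray(masks.z_mhsa), np.asarray(masks.z_mlp),
                     np.asarray(masks.z_patch))
    L, H, d = z_a.shape
    items = [RankedDimension("mhsa-dim", l, h, i, float(abs(z_a[l, h, i])))
             for l in range(L) for h in range(H) for i in range(d)]
    out.extend(sorted(items, key=lambda r: (r.score, r.layer, r.head, r.index)))
    L, M = z_m.shape
    items = [RankedDimension("mlp-dim", l, None, i, float(abs(z_m[l, i])))
             for l in range(L) for i in range(M)]
    out.extend(sorted(items, key=lambda r: (r.score, r.layer, r.index)))
    L, N = z_p.shape
    items = [RankedDimension("patch", l, None, j, float(abs(np.tanh(z_p[l, j]))))
             for l in range(L) for j in range(N)]
    out.extend(sorted(items, key=lambda r: (r.score, r.layer, r.index)))
    return out
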