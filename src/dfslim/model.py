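"""Full segmentation model (stem + transformer encoder + decoder + DF module),
the retraining stage, and Dice evaluation.

Layout: a two-stage convolutional stem supplies skip features at full and
half resolution; its output is patchified into tokens for the masked (or
sliced) transformer encoder; an upsampling decoder with the two skip
connections recovers a 64-channel full-resolution feature map.  From it a
1x1 classifier produces the initial class scores FN; when the DF module is
enabled a 1x1 field head predicts the direction field, FN is rectified along
it into FN', and a fusion classifier over [FN, FN'] gives the final scores.
The fusion weights start as the identity on the FN block, so an untrained DF
branch changes nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import autograd.numpy as anp
import numpy as np
from autograd.tracer import getval

from . import nn
from .config import OptimizerSettings, SegModelConfig
from .direction_field import (df_head, df_head_init, field_loss, fuse_and_classify,
                              fuse_init, gt_direction_field, rectify)
from .masked_transformer import MaskedModel, build_supernet
from .subnet import CompactModel, SubnetSpec, count_flops, count_params, slice_supernet


# ---------------------------------------------------------------------------
# Dice
# ---------------------------------------------------------------------------

def dsc(mt, mp) -> float:
    """Dice similarity 2|mt ∩ mp| / (|mt| + |mp|) of two binary masks.

    Both-empty is defined as 1 (a correct prediction of absence is perfect).
    """
    mt = np.asarray(mt).astype(bool)
    mp = np.asarray(mp).astype(bool)
    if mt.shape != mp.shape:
        raise ValueError(f"shape mismatch {mt.shape} vs {mp.shape}")
    denom = int(mt.sum()) + int(mp.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((mt & mp).sum()) / denom


def multiclass_dsc(labels_t, labels_p, n_classes: int):
    """Per-tissue-class one-vs-rest DSC (classes 1..C-1) and unweighted mean."""
    per = {c: dsc(labels_t == c, labels_p == c) for c in range(1, n_classes)}
    return per, float(np.mean(list(per.values())))


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class SegModel:
    """Segmentation network around a masked supernet or a sliced subnet.

    ``params`` is one pytree: stem/embed/pos/decoder/clf(/df/fuse) plus the
    encoder's own tree under ``'enc'``.  ``search_mode=True`` runs the
    continuous-mask forward (patch tanh active) for the sparsity search;
    otherwise a MaskedModel encoder runs with all masks at 1 and the patch
    tanh bypassed, i.e. the plain unmasked network.
    """

    def __init__(self, seg_config: SegModelConfig, encoder, params: dict,
                 search_mode: bool = False):
        self.seg_config = seg_config
        self.config = seg_config.search          # for the search objective
        self.encoder = encoder
        self.params = params
        self.search_mode = search_mode
        self.training_log: List[dict] = []
        self._field_cache: dict = {}

    # -- plumbing -----------------------------------------------------------
    def mask_params(self, params):
        return params["enc"]["masks"]

    @property
    def spec(self) -> Optional[SubnetSpec]:
        return self.encoder.spec if isinstance(self.encoder, CompactModel) else None

    def count_parameters(self) -> int:
        return nn.tree_size(self.params)

    # -- forward ------------------------------------------------------------
    def _tokens(self, p, x):
        cfg = self.seg_config
        if x.ndim == 3:
            x = x[:, None]
        s1 = nn.relu(nn.conv2d(p["stem1"], x))
        s2 = nn.relu(nn.conv2d(p["stem2"], s1, stride=2))
        B = x.shape[0]
        g = cfg.grid
        down = (cfg.image_size // 2) // g
        c2 = cfg.stem_channels[1]
        t = anp.reshape(s2, (B, c2, g, down, g, down))
        t = anp.transpose(t, (0, 2, 4, 1, 3, 5))
        t = anp.reshape(t, (B, g * g, c2 * down * down))
        t = nn.linear(p["embed"], t) + p["pos"]
        return t, s1, s2

    def _decode(self, p, t, s1, s2):
        cfg = self.seg_config
        B = t.shape[0]
        g = cfg.grid
        f = anp.transpose(anp.reshape(t, (B, g, g, cfg.search.D)), (0, 3, 1, 2))
        cur = g
        while cur < cfg.image_size // 4:
            f = nn.upsample2(f)
            cur *= 2
        u = nn.relu(nn.conv2d(p["dec1"], f))
        u = nn.upsample2(u)
        u = nn.relu(nn.conv2d(p["dec2"], anp.concatenate([u, s2], axis=1)))
        u = nn.upsample2(u)
        feat = nn.relu(nn.conv2d(p["dec3"], anp.concatenate([u, s1], axis=1)))
        return feat

    def forward(self, params, x, return_aux: bool = False):
        p = params
        t, s1, s2 = self._tokens(p, x)
        if isinstance(self.encoder, CompactModel):
            t = self.encoder.forward(t, params=p["enc"])
        else:
            t = self.encoder.forward(t, params=p["enc"],
                                     patch_bypass=not self.search_mode)
        feat = self._decode(p, t, s1, s2)
        FN = nn.conv1x1(p["clf"], feat)
        aux = {"FN": FN, "field": None}
        if self.seg_config.df_enabled:
            # the field head reads the trunk features through a stop-gradient:
            # its supervision trains the 1x1 head only, so the auxiliary task
            # cannot degrade the segmentation features it hangs off
            D = df_head(p["df"], getval(feat))
            FNp = rectify(FN, D, self.seg_config.df_iters)
            out = fuse_and_classify(p["fuse"], FN, FNp)
            aux["field"] = D
        else:
            out = FN
        return (out, aux) if return_aux else out

    def predict(self, x) -> np.ndarray:
        logits = self.forward(self.params, np.asarray(x, nn.DTYPE))
        return np.argmax(np.asarray(logits), axis=1)

    # -- losses -------------------------------------------------------------
    def _field_targets(self, yb: np.ndarray) -> np.ndarray:
        outs = []
        for lab in yb:
            key = lab.tobytes()
            if key not in self._field_cache:
                self._field_cache[key] = gt_direction_field(lab).astype(nn.DTYPE)
            outs.append(self._field_cache[key])
        return np.stack(outs)

    def loss_ce(self, params, xb, yb):
        """Segmentation loss: pixel CE, plus the field MSE when DF is on."""
        logits, aux = self.forward(params, xb, return_aux=True)
        loss = nn.cross_entropy(logits, yb)
        if self.seg_config.df_enabled and self.seg_config.field_loss_weight > 0:
            gt = self._field_targets(np.asarray(yb))
            loss = loss + self.seg_config.field_loss_weight * \
                field_loss(aux["field"], gt, np.asarray(yb) > 0)
        return loss


def assemble_model(config: SegModelConfig, spec: Optional[SubnetSpec] = None,
                   seed: int = 0, search_mode: bool = False) -> SegModel:
    """Build a SegModel around a fresh supernet (spec=None) or around the
    slice of a fresh supernet described by ``spec``."""
    rng = np.random.default_rng(seed)
    scfg = config.search
    c1, c2 = config.stem_channels
    dc1, dc2 = config.decoder_channels
    down = (config.image_size // 2) // config.grid
    p = {
        "stem1": nn.conv_init(rng, 1, c1),
        "stem2": nn.conv_init(rng, c1, c2),
        "embed": nn.linear_init(rng, c2 * down * down, scfg.D),
        "pos": (0.02 * rng.standard_normal((scfg.N, scfg.D))).astype(nn.DTYPE),
        "dec1": nn.conv_init(rng, scfg.D, dc1),
        "dec2": nn.conv_init(rng, dc1 + c2, dc2),
        "dec3": nn.conv_init(rng, dc2 + c1, config.feature_channels),
        "clf": {"W": nn.glorot(rng, config.feature_channels, config.n_classes,
                               (config.feature_channels, config.n_classes)),
                "b": np.zeros(config.n_classes, nn.DTYPE)},
    }
    if config.df_enabled:
        p["df"] = df_head_init(rng, config.feature_channels)
        p["fuse"] = fuse_init(rng, config.n_classes)
    supernet = build_supernet(scfg, seed=int(rng.integers(0, 2 ** 31 - 1)))
    if spec is None:
        p["enc"] = supernet.params
        return SegModel(config, supernet, p, search_mode=search_mode)
    compact = slice_supernet(supernet, spec)
    p["enc"] = compact.params
    return SegModel(config, compact, p, search_mode=False)


def extract_compact(model: SegModel, spec: SubnetSpec,
                    df_enabled: Optional[bool] = None) -> SegModel:
    """Slice a searched SegModel's encoder, keeping every other trained
    weight; optionally flip the DF module on/off for the retraining stage."""
    if not isinstance(model.encoder, MaskedModel):
        raise ValueError("extract_compact needs a supernet-backed model")
    compact = slice_supernet(model.encoder, spec)
    cfg = model.seg_config
    if df_enabled is not None and df_enabled != cfg.df_enabled:
        from dataclasses import replace
        cfg = replace(cfg, df_enabled=df_enabled)
    p = {k: nn.tree_map(np.array, v) for k, v in model.params.items()
         if k != "enc"}
    if cfg.df_enabled and "df" not in p:
        rng = np.random.default_rng(0)
        p["df"] = df_head_init(rng, cfg.feature_channels)
        p["fuse"] = fuse_init(rng, cfg.n_classes)
    if not cfg.df_enabled:
        p.pop("df", None)
        p.pop("fuse", None)
    p["enc"] = compact.params
    return SegModel(cfg, compact, p, search_mode=False)


# ---------------------------------------------------------------------------
# retraining
# ---------------------------------------------------------------------------

def retrain(model: SegModel, data, epochs: int = 50, seed: int = 0,
            optimizer: OptimizerSettings | None = None) -> SegModel:
    """Retrain a (sliced) model with the search optimiser settings but no
    sparsity penalty; deterministic under the seed.  The per-epoch loss trace
    is appended to ``model.training_log``."""
    opt_cfg = optimizer or OptimizerSettings()
    X, y = data
    n = len(X)
    if n == 0:
        raise ValueError("empty training set")
    if epochs == 0:
        return model
    vg = nn.loss_and_grad(model.loss_ce)
    opt = nn.AdamW(model.params, lr=opt_cfg.lr, weight_decay=opt_cfg.weight_decay,
                   no_decay_paths=("masks", "gamma", "beta"))
    rng = np.random.default_rng(seed)
    bs = min(opt_cfg.batch_size, n)
    for epoch in range(epochs):
        order = rng.permutation(n)
        tot, steps = 0.0, 0
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            loss, grads = vg(opt.params, X[idx], y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at retrain epoch {epoch + 1}")
            tot += float(loss)
            steps += 1
            opt.step(grads)
        model.params = opt.params
        model.training_log.append({"epoch": epoch + 1, "loss": tot / steps})
    return model


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    per_class: dict               # class id -> mean DSC over images
    mean_dsc: float               # unweighted mean over tissue classes
    mean_dsc_per_image: float     # mean over images of per-image mean DSC
    per_image: List[dict]         # per-image per-class DSC
    params: int
    flops: int
    flop_convention: str = "1 MAC = 1 FLOP; encoder matmul MACs only"

    def as_dict(self):
        return {"per_class": {str(k): v for k, v in self.per_class.items()},
                "mean_dsc": self.mean_dsc,
                "mean_dsc_per_image": self.mean_dsc_per_image,
                "per_image": self.per_image, "params": self.params,
                "flops": self.flops, "flop_convention": self.flop_convention}


def evaluate(model: SegModel, data) -> EvalReport:
    """Per-class and mean DSC over a test set, with parameter/FLOP counts.

    ``data`` is an (X, y) pair.  Mean DSC is reported both class-first
    (mean over images per class, then over classes) and image-first.
    """
    X, y = data
    if len(X) == 0:
        raise ValueError("empty test set")
    C = model.seg_config.n_classes
    per_image = []
    for i in range(0, len(X), 16):
        pred = model.predict(X[i:i + 16])
        for p_lab, t_lab in zip(pred, y[i:i + 16]):
            per, mean = multiclass_dsc(t_lab, p_lab, C)
            per_image.append({**{str(c): v for c, v in per.items()}, "mean": mean})
    per_class = {c: float(np.mean([im[str(c)] for im in per_image]))
                 for c in range(1, C)}
    spec = model.spec or SubnetSpec.full(model.config)
    return EvalReport(
        per_class=per_class,
        mean_dsc=float(np.mean(list(per_class.values()))),
        mean_dsc_per_image=float(np.mean([im["mean"] for im in per_image])),
        per_image=per_image,
        params=model.count_parameters(),
        flops=count_flops(spec, model.config),
    )
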