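"""ViT-style encoder with learnable multiplicative sparsity masks.

Every searchable linear layer stores one super-weight matrix at its maximum
width; candidate sub-layers are column/row slices of it.  Importance masks
``z`` multiply *activations*, not weights:

* MHSA, head (l, h):  ``A_i = softmax((q_i z)(k_i z)^T / sqrt(d))``,
  ``O_i = A_i (v_i z)``, output = projection of ``[O_1 ... O_H]``.  The same
  per-head mask multiplies q, k and v; the softmax temperature always uses the
  full ``d``.
* MLP, layer l:  ``t_e = f1(t_m) * z_m``, output ``f2(t_e)``.
* Patch j, layer l: token row scaled by ``tanh(z_patch[l, j])`` at the entry
  of the block — tanh bounds the scale so patch masks cannot explode.

Masks start at 1 everywhere, so a fresh supernet computes exactly the
unmasked forward (with patch tanh bypassed).

A second, *binarized* forward realises the end state of the search: masks are
0/1, the patch tanh is bypassed, and dead tokens are excluded from attention
(their keys are masked out of the softmax and their rows zeroed).  This is the
semantics under which slicing the supernet is exactly equivalent to masking
it — a token multiplied by a continuous mask of 0 would still expose its
projection biases to the softmax, so the binarized mode, not the continuous
zero limit, defines what "removed" means.
"""

from __future__ import annotations

from dataclasses import dataclass

import autograd.numpy as anp
import numpy as np

from . import nn
from .config import SearchSpaceConfig

NEG_INF = -1e9


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

@dataclass
class MaskSet:
    """Learnable importance scores for every searchable site.

    z_mhsa: (L, H, d) — per-head feature-dimension masks
    z_mlp:  (L, M)    — per-layer MLP hidden-dimension masks
    z_patch:(L, N)    — per-layer pre-tanh patch scores
    """

    z_mhsa: np.ndarray
    z_mlp: np.ndarray
    z_patch: np.ndarray

    @classmethod
    def ones(cls, cfg: SearchSpaceConfig) -> "MaskSet":
        return cls(
            z_mhsa=np.ones((cfg.L, cfg.H, cfg.d), nn.DTYPE),
            z_mlp=np.ones((cfg.L, cfg.M), nn.DTYPE),
            z_patch=np.ones((cfg.L, cfg.N), nn.DTYPE),
        )

    @classmethod
    def from_params(cls, params: dict) -> "MaskSet":
        m = params["masks"]
        return cls(np.asarray(m["z_mhsa"]), np.asarray(m["z_mlp"]),
                   np.asarray(m["z_patch"]))

    def to_params(self) -> dict:
        return {"z_mhsa": np.asarray(self.z_mhsa, nn.DTYPE),
                "z_mlp": np.asarray(self.z_mlp, nn.DTYPE),
                "z_patch": np.asarray(self.z_patch, nn.DTYPE)}

    def validate(self, cfg: SearchSpaceConfig) -> None:
        exp = {(cfg.L, cfg.H, cfg.d): self.z_mhsa, (cfg.L, cfg.M): self.z_mlp,
               (cfg.L, cfg.N): self.z_patch}
        for shape, arr in exp.items():
            if np.asarray(arr).shape != shape:
                raise ValueError(f"mask shape {np.asarray(arr).shape} != {shape}")


def _check_finite(x, what: str):
    # only enforceable on concrete arrays, not on autograd tracer boxes
    if isinstance(x, np.ndarray) and not np.all(np.isfinite(x)):
        raise FloatingPointError(f"non-finite activations in {what}")


# ---------------------------------------------------------------------------
# masked block forwards (Eqs. of the search formulation)
# ---------------------------------------------------------------------------

def masked_mhsa_forward(p, t, z, d_full: int, key_keep=None):
    """Masked multi-head attention on tokens t (B, N, D) or (N, D).

    p: {'Wq','bq','Wk','bk','Wv','bv','Wo','bo'} with Wq/Wk/Wv (D, H*d).
    z: (H, d) mask, multiplies q, k, v per head.
    key_keep: optional boolean (N,) — keys outside it are excluded from every
    softmax (binarized dead-token semantics).
    """
    squeeze = t.ndim == 2
    if squeeze:
        t = t[None]
    B, N, D = t.shape
    H, d = z.shape

    def heads(W, b):
        y = anp.matmul(t, W) + b
        return anp.reshape(y, (B, N, H, d))

    q = heads(p["Wq"], p["bq"]) * z
    k = heads(p["Wk"], p["bk"]) * z
    v = heads(p["Wv"], p["bv"]) * z
    scores = anp.einsum("bnhd,bmhd->bhnm", q, k) / np.sqrt(d_full)
    if key_keep is not None:
        bias = np.where(np.asarray(key_keep, bool), 0.0, NEG_INF).astype(nn.DTYPE)
        scores = scores + bias[None, None, None, :]
    A = nn.softmax(scores, axis=-1)
    O = anp.einsum("bhnm,bmhd->bnhd", A, v)
    out = anp.matmul(anp.reshape(O, (B, N, H * d)), p["Wo"]) + p["bo"]
    _check_finite(out, "masked_mhsa_forward")
    return out[0] if squeeze else out


def masked_mlp_forward(p, t, z):
    """t_e = f1(t) * z; out = f2(t_e).  p: {'f1','f2'} linear params."""
    t_e = nn.linear(p["f1"], t) * z
    out = nn.linear(p["f2"], t_e)
    _check_finite(out, "masked_mlp_forward")
    return out


def masked_patch_forward(t, z_patch_layer, bypass: bool = False, binary=None):
    """Scale token rows by tanh(z) (search phase) or a 0/1 keep vector."""
    if binary is not None:
        scale = np.asarray(binary, nn.DTYPE)
    elif bypass:
        return t
    else:
        scale = anp.tanh(z_patch_layer)
    return t * scale[..., :, None]


# ---------------------------------------------------------------------------
# the supernet
# ---------------------------------------------------------------------------

def init_encoder_params(cfg: SearchSpaceConfig, rng: np.random.Generator) -> dict:
    blocks = []
    for _ in range(cfg.L):
        blocks.append({
            "ln1": nn.layernorm_init(cfg.D),
            "attn": {
                "Wq": nn.glorot(rng, cfg.D, cfg.D, (cfg.D, cfg.H * cfg.d)),
                "bq": np.zeros(cfg.H * cfg.d, nn.DTYPE),
                "Wk": nn.glorot(rng, cfg.D, cfg.D, (cfg.D, cfg.H * cfg.d)),
                "bk": np.zeros(cfg.H * cfg.d, nn.DTYPE),
                "Wv": nn.glorot(rng, cfg.D, cfg.D, (cfg.D, cfg.H * cfg.d)),
                "bv": np.zeros(cfg.H * cfg.d, nn.DTYPE),
                "Wo": nn.glorot(rng, cfg.D, cfg.D, (cfg.H * cfg.d, cfg.D)),
                "bo": np.zeros(cfg.D, nn.DTYPE),
            },
            "ln2": nn.layernorm_init(cfg.D),
            "mlp": {"f1": nn.linear_init(rng, cfg.D, cfg.M),
                    "f2": nn.linear_init(rng, cfg.M, cfg.D)},
        })
    return {str(i): b for i, b in enumerate(blocks)}


def encoder_forward(params, t, cfg: SearchSpaceConfig, patch_bypass: bool = False,
                    keep=None):
    """Run the L-block masked encoder on tokens t.

    keep: None for the continuous search phase; otherwise a dict
    {'mhsa': (L,H,d) bool, 'mlp': (L,M) bool, 'patch': (L,N) bool} switching
    to binarized semantics (0/1 masks, patch tanh bypass, dead-key exclusion).
    """
    masks = params["masks"]
    enc = params["encoder"]
    for l in range(cfg.L):
        blk = enc[str(l)]
        if keep is not None:
            pk = np.asarray(keep["patch"][l], bool)
            t = masked_patch_forward(t, None, binary=pk)
            z_a = np.asarray(keep["mhsa"][l], nn.DTYPE)
            z_m = np.asarray(keep["mlp"][l], nn.DTYPE)
            key_keep = pk
        else:
            t = masked_patch_forward(t, masks["z_patch"][l], bypass=patch_bypass)
            z_a = masks["z_mhsa"][l]
            z_m = masks["z_mlp"][l]
            key_keep = None
        a = t + masked_mhsa_forward(blk["attn"], nn.layernorm(blk["ln1"], t),
                                    z_a, cfg.d, key_keep=key_keep)
        t = a + masked_mlp_forward(blk["mlp"], nn.layernorm(blk["ln2"], a), z_m)
        if keep is not None:
            # residual paths revive dead rows; re-kill them so they stay inert
            t = t * np.asarray(keep["patch"][l], nn.DTYPE)[:, None]
    return t


class MaskedModel:
    """A masked supernet encoder: config + parameter pytree.

    ``params['encoder']`` holds the super-weights, ``params['masks']`` the
    MaskSet arrays under their own namespace (also the checkpoint layout).
    """

    def __init__(self, config: SearchSpaceConfig, params: dict):
        self.config = config
        self.params = params

    def forward(self, t, params=None, patch_bypass: bool = False, keep=None):
        p = self.params if params is None else params
        return encoder_forward(p, t, self.config, patch_bypass=patch_bypass,
                               keep=keep)

    @property
    def masks(self) -> MaskSet:
        return MaskSet.from_params(self.params)

    def set_masks(self, masks: MaskSet) -> None:
        masks.validate(self.config)
        self.params["masks"] = masks.to_params()


def build_supernet(config: SearchSpaceConfig, seed: int) -> MaskedModel:
    """Deterministically initialise a supernet with all-ones masks."""
    rng = np.random.default_rng(seed)
    params = {"encoder": init_encoder_params(config, rng),
              "masks": MaskSet.ones(config).to_params()}
    return MaskedModel(config, params)
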