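"""Budget-based subnet extraction: ranking -> kept-index sets -> sliced model.

The budget is global per kind: the top ``ceil(fraction * total)`` scoring
sites network-wide are kept, so per-layer (and per-head) kept counts may
differ — that freedom to give different heads different widths is the point
of a continuous search space.  Patch kept-sets are then made monotone down
the depth (a patch dead at layer l stays dead at every later layer), after
which slicing the super-weights is exactly equivalent to running the supernet
with binarized masks.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Dict, List

import autograd.numpy as anp
import numpy as np

from . import nn
from .config import BudgetSpec, SearchSpaceConfig
from .masked_transformer import MaskedModel
from .sparsity_search import KINDS, RankedDimension


@dataclass
class SubnetSpec:
    """Kept 0-based indices per site after budget selection.

    mhsa[l][h]: kept feature dims of head (l, h); mlp[l]: kept hidden dims of
    layer l; patch[l]: kept patch indices at the entry of layer l.
    """

    mhsa: List[List[List[int]]]
    mlp: List[List[int]]
    patch: List[List[int]]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mhsa = [[sorted(int(i) for i in hd) for hd in layer] for layer in self.mhsa]
        self.mlp = [sorted(int(i) for i in layer) for layer in self.mlp]
        self.patch = [sorted(int(i) for i in layer) for layer in self.patch]

    # -- serialization ------------------------------------------------------
    def to_json(self, path=None) -> str:
        doc = {"index_convention": "0-based, row-major patch order",
               "mhsa": self.mhsa, "mlp": self.mlp, "patch": self.patch,
               "provenance": self.provenance}
        s = json.dumps(doc, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, source) -> "SubnetSpec":
        if hasattr(source, "read"):
            doc = json.load(source)
        elif isinstance(source, str) and source.lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        return cls(doc["mhsa"], doc["mlp"], doc["patch"], doc.get("provenance", {}))

    @classmethod
    def full(cls, cfg: SearchSpaceConfig) -> "SubnetSpec":
        return cls(
            mhsa=[[list(range(cfg.d)) for _ in range(cfg.H)] for _ in range(cfg.L)],
            mlp=[list(range(cfg.M)) for _ in range(cfg.L)],
            patch=[list(range(cfg.N)) for _ in range(cfg.L)],
            provenance={"budget": {"mhsa": 1.0, "mlp": 1.0, "patch": 1.0}},
        )

    def is_patch_monotone(self) -> bool:
        return all(set(self.patch[l + 1]) <= set(self.patch[l])
                   for l in range(len(self.patch) - 1))


def _ranking_checksum(ranking: List[RankedDimension]) -> str:
    h = hashlib.sha1()
    for r in ranking:
        h.update(f"{r.kind}:{r.layer}:{r.head}:{r.index}:{r.score:.8e};".encode())
    return h.hexdigest()[:16]


def select_budget(ranking: List[RankedDimension], budget: BudgetSpec) -> SubnetSpec:
    """Keep the globally top-scoring ``ceil(fraction * total)`` sites per kind.

    The ranking must be complete (every site of every kind exactly once);
    geometry (L, H, d, M, N) is read off the ranking itself.
    """
    by_kind = {k: [r for r in ranking if r.kind == k] for k in KINDS}
    for k, items in by_kind.items():
        if not items:
            raise ValueError(f"ranking has no '{k}' entries")
    L = 1 + max(r.layer for r in ranking)
    H = 1 + max(r.head for r in by_kind["mhsa-dim"])
    d = 1 + max(r.index for r in by_kind["mhsa-dim"])
    M = 1 + max(r.index for r in by_kind["mlp-dim"])
    N = 1 + max(r.index for r in by_kind["patch"])

    fracs = {"mhsa-dim": budget.mhsa, "mlp-dim": budget.mlp, "patch": budget.patch}
    kept: Dict[str, set] = {}
    for k, items in by_kind.items():
        total = len(items)
        n_keep = int(np.ceil(fracs[k] * total))
        # ranking is ascending by score: survivors are the tail
        kept[k] = {(r.layer, r.head, r.index) for r in
                   sorted(items, key=lambda r: (r.score, r.layer,
                                                r.head if r.head is not None else -1,
                                                r.index))[total - n_keep:]}
    spec = SubnetSpec(
        mhsa=[[[i for i in range(d) if (l, h, i) in kept["mhsa-dim"]]
               for h in range(H)] for l in range(L)],
        mlp=[[i for i in range(M) if (l, None, i) in kept["mlp-dim"]]
             for l in range(L)],
        patch=[[j for j in range(N) if (l, None, j) in kept["patch"]]
               for l in range(L)],
        provenance={"budget": {"mhsa": budget.mhsa, "mlp": budget.mlp,
                               "patch": budget.patch},
                    "ranking_checksum": _ranking_checksum(ranking)},
    )
    return spec


def enforce_patch_monotonicity(spec: SubnetSpec) -> SubnetSpec:
    """Propagate patch eliminations downward: kept(l+1) := kept(l+1) ∩ kept(l).

    Only removals, never additions; idempotent.
    """
    patch, running = [], None
    for layer in spec.patch:
        s = set(layer) if running is None else set(layer) & running
        running = s
        patch.append(sorted(s))
    return SubnetSpec(spec.mhsa, spec.mlp, patch, dict(spec.provenance))


# ---------------------------------------------------------------------------
# slicing
# ---------------------------------------------------------------------------

class CompactModel:
    """A physically sliced subnet: per-head widths vary, dead tokens are gone.

    The forward contract matches the supernet's: tokens enter at the full
    grid size N and leave at the full grid size with zero rows at dead patch
    positions, so the surrounding segmentation model never needs to know the
    token sequence shrank.  The softmax temperature stays sqrt(d_full) of the
    parent supernet.
    """

    def __init__(self, config: SearchSpaceConfig, spec: SubnetSpec, params: dict):
        self.config = config
        self.spec = spec
        self.params = params

    def forward(self, t, params=None):
        p = self.params if params is None else params
        cfg, spec = self.config, self.spec
        squeeze = t.ndim == 2
        if squeeze:
            t = t[None]
        active = list(range(cfg.N))
        for l in range(cfg.L):
            new_active = spec.patch[l]
            if not new_active:
                raise ValueError(f"layer {l} has no surviving patches")
            pos = np.searchsorted(active, new_active)
            t = t[:, pos, :]
            active = new_active
            blk = p["encoder"][str(l)]
            a = t + self._attn(blk, nn.layernorm(blk["ln1"], t), l)
            h = nn.linear(blk["mlp"]["f1"], nn.layernorm(blk["ln2"], a))
            t = a + nn.linear(blk["mlp"]["f2"], h)
        out = _scatter_rows(t, active, self.config.N)
        return out[0] if squeeze else out

    def _attn(self, blk, t, l):
        cfg, spec = self.config, self.spec
        at = blk["attn"]
        outs = []
        for h in range(cfg.H):
            if not spec.mhsa[l][h]:
                continue  # whole head removed
            q = anp.matmul(t, at[f"Wq{h}"]) + at[f"bq{h}"]
            k = anp.matmul(t, at[f"Wk{h}"]) + at[f"bk{h}"]
            v = anp.matmul(t, at[f"Wv{h}"]) + at[f"bv{h}"]
            A = nn.softmax(anp.einsum("bnd,bmd->bnm", q, k) / np.sqrt(cfg.d))
            outs.append(anp.einsum("bnm,bmd->bnd", A, v))
        O = anp.concatenate(outs, axis=-1)
        return anp.matmul(O, at["Wo"]) + at["bo"]


def _scatter_rows(t, indices, n_total):
    B, _, D = t.shape
    rows = []
    lookup = {j: i for i, j in enumerate(indices)}
    zero = anp.zeros((B, D), dtype=nn.DTYPE)
    for j in range(n_total):
        rows.append(t[:, lookup[j], :] if j in lookup else zero)
    return anp.stack(rows, axis=1)


def slice_supernet(model: MaskedModel, spec: SubnetSpec) -> CompactModel:
    """Extract the kept rows/columns of every super-weight into a CompactModel.

    Requires a patch-monotone spec (run enforce_patch_monotonicity first);
    the compact forward then equals the binarized-mask supernet forward.
    """
    cfg = model.config
    if not spec.is_patch_monotone():
        raise ValueError("spec is not patch-monotone; enforce monotonicity first")
    enc_in = model.params["encoder"]
    enc_out = {}
    for l in range(cfg.L):
        src = enc_in[str(l)]
        at = src["attn"]
        new_at = {"bo": np.array(at["bo"])}
        kept_rows = []  # rows of Wo, in head-major order
        for h in range(cfg.H):
            idx = [h * cfg.d + i for i in spec.mhsa[l][h]]
            if not idx:
                continue
            for name in ("q", "k", "v"):
                new_at[f"W{name}{h}"] = np.array(at[f"W{name}"][:, idx])
                new_at[f"b{name}{h}"] = np.array(at[f"b{name}"][idx])
            kept_rows.extend(idx)
        if not kept_rows:
            raise ValueError(f"layer {l}: every attention head was eliminated")
        new_at["Wo"] = np.array(at["Wo"][kept_rows, :])
        mlp_idx = spec.mlp[l]
        enc_out[str(l)] = {
            "ln1": {k: np.array(v) for k, v in src["ln1"].items()},
            "ln2": {k: np.array(v) for k, v in src["ln2"].items()},
            "attn": new_at,
            "mlp": {"f1": {"W": np.array(src["mlp"]["f1"]["W"][:, mlp_idx]),
                           "b": np.array(src["mlp"]["f1"]["b"][mlp_idx])},
                    "f2": {"W": np.array(src["mlp"]["f2"]["W"][mlp_idx, :]),
                           "b": np.array(src["mlp"]["f2"]["b"])}},
        }
    return CompactModel(cfg, spec, {"encoder": enc_out})


def keep_arrays(spec: SubnetSpec, cfg: SearchSpaceConfig) -> dict:
    """Boolean (L,H,d)/(L,M)/(L,N) keep masks for the binarized forward."""
    ka = np.zeros((cfg.L, cfg.H, cfg.d), bool)
    km = np.zeros((cfg.L, cfg.M), bool)
    kp = np.zeros((cfg.L, cfg.N), bool)
    for l in range(cfg.L):
        for h in range(cfg.H):
            ka[l, h, spec.mhsa[l][h]] = True
        km[l, spec.mlp[l]] = True
        kp[l, spec.patch[l]] = True
    return {"mhsa": ka, "mlp": km, "patch": kp}


# ---------------------------------------------------------------------------
# accounting
# ---------------------------------------------------------------------------

def count_params(spec: SubnetSpec, config: SearchSpaceConfig) -> int:
    """Searchable parameter count of the sliced encoder (closed form).

    Each kept MHSA dim owns a q, k and v weight column plus bias entry,
    3*(D+1), and one projection row, D.  Each kept MLP dim owns an f1 column
    plus bias, (D+1), and an f2 row, D.  Per-layer constants (projection and
    f2 biases, layer norms) are not searchable; see count_params_fixed.
    """
    D = config.D
    n_mhsa = sum(len(hd) for layer in spec.mhsa for hd in layer)
    n_mlp = sum(len(layer) for layer in spec.mlp)
    return n_mhsa * (3 * (D + 1) + D) + n_mlp * ((D + 1) + D)


def count_params_fixed(config: SearchSpaceConfig) -> int:
    """Non-searchable encoder parameters: bo, f2 bias, two layer norms/layer."""
    return config.L * (config.D + config.D + 2 * (2 * config.D))


def count_flops(spec: SubnetSpec, config: SearchSpaceConfig) -> int:
    """Encoder multiply–accumulate count (1 MAC = 1 reported FLOP).

    Token-wise linear layers scale with the layer's active patch count N_l;
    the attention score and apply terms scale with N_l**2.  Layer norms and
    softmax are not counted (no matmul MACs).
    """
    D = config.D
    total = 0
    for l in range(config.L):
        N_l = len(spec.patch[l])
        d_tot = sum(len(hd) for hd in spec.mhsa[l])
        M_l = len(spec.mlp[l])
        total += 3 * N_l * D * d_tot          # q, k, v projections
        total += 2 * N_l * N_l * d_tot        # scores + apply
        total += N_l * d_tot * D              # output projection
        total += 2 * N_l * D * M_l            # f1 + f2
    return int(total)


def enumerate_params(model) -> int:
    """Exhaustive tensor-size enumeration over a model's encoder weights."""
    return nn.tree_size(model.params["encoder"])


def enumerate_searchable_params(model: CompactModel) -> int:
    """Enumeration restricted to searchable tensors (excludes the per-layer
    constants bo, f2 bias and layer norms)."""
    total = 0
    for l, blk in model.params["encoder"].items():
        for name, arr in blk["attn"].items():
            if name not in ("Wo", "bo"):
                total += arr.size
        total += blk["attn"]["Wo"].size
        total += blk["mlp"]["f1"]["W"].size + blk["mlp"]["f1"]["b"].size
        total += blk["mlp"]["f2"]["W"].size
    return int(total)
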