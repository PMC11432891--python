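"""Run configuration: search-space geometry, model layout, budgets, optimiser.

All configs are plain dataclasses that round-trip losslessly through YAML;
unknown keys are rejected so a typo in a config file fails loudly instead of
silently running defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


def _from_dict(cls, d: dict):
    names = {f.name for f in fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for f in fields(cls):
        if f.name not in d:
            continue
        v = d[f.name]
        if hasattr(f.type, "__dataclass_fields__") if isinstance(f.type, type) else False:
            v = _from_dict(f.type, v)
        kwargs[f.name] = v
    return cls(**kwargs)


@dataclass
class SearchSpaceConfig:
    """Geometry of the searchable transformer and the sparsity weights.

    L: encoder depth; H: heads per layer; d: max per-head dim; D: embed dim
    (must equal H*d); M: max MLP hidden dim; N: patch/token count.
    w_mhsa/w_mlp/w_patch are the L1 penalty weights on the corresponding
    mask groups (dimensionless).
    """

    L: int = 2
    H: int = 2
    d: int = 8
    D: int = 16
    M: int = 32
    N: int = 64
    search_mhsa: bool = True
    search_mlp: bool = True
    search_patch: bool = True
    w_mhsa: float = 2e-4
    w_mlp: float = 4e-4
    w_patch: float = 1e-4

    def __post_init__(self):
        for name in ("L", "H", "d", "D", "M", "N"):
            v = getattr(self, name)
            if not isinstance(v, int) or v <= 0:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.D != self.H * self.d:
            raise ValueError(
                f"inconsistent head geometry: D={self.D} != H*d={self.H * self.d}")
        for name in ("w_mhsa", "w_mlp", "w_patch"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    # Din/Dmax of a shared (super-weight) layer, per site kind
    @property
    def qkv_shape(self):
        return self.D, self.d  # per head

    def total_sites(self, kind: str) -> int:
        return {"mhsa-dim": self.L * self.H * self.d,
                "mlp-dim": self.L * self.M,
                "patch": self.L * self.N}[kind]


@dataclass
class OptimizerSettings:
    algorithm: str = "adamw"
    lr: float = 1e-3
    weight_decay: float = 1e-2
    batch_size: int = 16


@dataclass
class BudgetSpec:
    """Fraction of searchable sites kept per kind, each in (0, 1]."""

    mhsa: float = 1.0
    mlp: float = 1.0
    patch: float = 1.0

    def __post_init__(self):
        for name in ("mhsa", "mlp", "patch"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"budget fraction {name}={v} outside (0, 1]")


@dataclass
class SegModelConfig:
    """Layout of the full segmentation model (stem + encoder + decoder + DF)."""

    image_size: int = 64
    patch_size: int = 8
    n_classes: int = 4
    stem_channels: tuple = (8, 16)
    decoder_channels: tuple = (32, 16)
    feature_channels: int = 64   # pre-classifier feature width fed to the DF head
    df_enabled: bool = True
    df_iters: int = 5
    field_loss_weight: float = 1.0
    search: SearchSpaceConfig = field(default_factory=SearchSpaceConfig)

    def __post_init__(self):
        if isinstance(self.search, dict):
            self.search = _from_dict(SearchSpaceConfig, self.search)
        self.stem_channels = tuple(self.stem_channels)
        self.decoder_channels = tuple(self.decoder_channels)
        if self.image_size % self.patch_size:
            raise ValueError("image_size must be divisible by patch_size")
        grid = self.image_size // self.patch_size
        if self.search.N != grid * grid:
            raise ValueError(
                f"search.N={self.search.N} != (image_size/patch_size)^2={grid * grid}")

    @property
    def grid(self) -> int:
        return self.image_size // self.patch_size


@dataclass
class RunConfig:
    """Everything a full search -> extract -> retrain -> eval run needs."""

    model: SegModelConfig = field(default_factory=SegModelConfig)
    optimizer: OptimizerSettings = field(default_factory=OptimizerSettings)
    budget: BudgetSpec = field(default_factory=BudgetSpec)
    search_epochs: int = 50
    retrain_epochs: int = 50
    seed: int = 0
    n_phantoms: int = 200
    phantom_size: int = 64
    noise_sigma: float = 0.08
    blur_sigma: float = 1.0

    def __post_init__(self):
        if isinstance(self.model, dict):
            self.model = _from_dict(SegModelConfig, self.model)
        if isinstance(self.optimizer, dict):
            self.optimizer = _from_dict(OptimizerSettings, self.optimizer)
        if isinstance(self.budget, dict):
            self.budget = _from_dict(BudgetSpec, self.budget)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return _from_dict(cls, yaml.safe_load(Path(path).read_text()))
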