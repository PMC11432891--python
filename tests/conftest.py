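import numpy as np
import pytest

from dfslim.config import SearchSpaceConfig
from dfslim.masked_transformer import build_supernet
from dfslim.subnet import SubnetSpec, enforce_patch_monotonicity


@pytest.fixture
def toy_cfg():
    return SearchSpaceConfig(L=2, H=2, d=4, D=8, M=16, N=16)


@pytest.fixture
def toy_model(toy_cfg):
    return build_supernet(toy_cfg, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_monotone_spec(rng, cfg, min_patch=2):
    """A random SubnetSpec with >=1 dim per site kind and monotone,
    nowhere-empty patch sets (redrawn until the running intersection of the
    per-layer draws keeps at least one patch everywhere)."""
    mhsa = [[sorted(rng.choice(cfg.d, size=rng.integers(1, cfg.d + 1),
                               replace=False).tolist())
             for _ in range(cfg.H)] for _ in range(cfg.L)]
    mlp = [sorted(rng.choice(cfg.M, size=rng.integers(1, cfg.M + 1),
                             replace=False).tolist()) for _ in range(cfg.L)]
    while True:
        patch = [sorted(rng.choice(cfg.N, size=rng.integers(min_patch, cfg.N + 1),
                                   replace=False).tolist()) for _ in range(cfg.L)]
        spec = enforce_patch_monotonicity(SubnetSpec(mhsa, mlp, patch))
        if all(spec.patch):
            return spec
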