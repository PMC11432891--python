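"""Budget selection, patch monotonicity, slicing equivalence and accounting."""

import numpy as np
import pytest

from conftest import random_monotone_spec
from dfslim.config import BudgetSpec, SearchSpaceConfig
from dfslim.masked_transformer import MaskSet, build_supernet
from dfslim.sparsity_search import rank_dimensions
from dfslim.subnet import (SubnetSpec, count_flops, count_params,
                           enforce_patch_monotonicity, enumerate_searchable_params,
                           keep_arrays, select_budget, slice_supernet)


def ranking_for(cfg, rng):
    m = MaskSet(rng.uniform(0.01, 1, (cfg.L, cfg.H, cfg.d)),
                rng.uniform(0.01, 1, (cfg.L, cfg.M)),
                rng.uniform(0.01, 1, (cfg.L, cfg.N)))
    return rank_dimensions(m), m


class TestSelectBudget:
    def test_full_budget_keeps_everything(self, toy_cfg, rng):
        ranking, _ = ranking_for(toy_cfg, rng)
        spec = select_budget(ranking, BudgetSpec(1.0, 1.0, 1.0))
        assert spec.mhsa == SubnetSpec.full(toy_cfg).mhsa
        assert spec.mlp == SubnetSpec.full(toy_cfg).mlp
        assert spec.patch == SubnetSpec.full(toy_cfg).patch

    def test_ceiling_count_and_top_scores(self, rng):
        cfg = SearchSpaceConfig(L=1, H=1, d=2, D=2, M=10, N=2)
        ranking, m = ranking_for(cfg, rng)
        spec = select_budget(ranking, BudgetSpec(1.0, 0.6, 1.0))
        kept = spec.mlp[0]
        assert len(kept) == 6  # ceil(0.6 * 10)
        top6 = set(np.argsort(np.abs(m.z_mlp[0]))[-6:].tolist())
        assert set(kept) == top6

    def test_no_kept_score_below_any_dropped_score(self, toy_cfg, rng):
        for _ in range(10):
            ranking, m = ranking_for(toy_cfg, rng)
            spec = select_budget(ranking, BudgetSpec(0.3, 0.3, 0.3))
            scores = np.abs(m.z_mhsa)
            kept_mask = keep_arrays(spec, toy_cfg)["mhsa"]
            if kept_mask.any() and (~kept_mask).any():
                assert scores[kept_mask].min() >= scores[~kept_mask].max()

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            BudgetSpec(0.0, 0.5, 0.5)


class TestPatchMonotonicity:
    def test_already_monotone_unchanged(self, toy_cfg):
        spec = SubnetSpec.full(toy_cfg)
        spec.patch[0] = [0, 1, 2]
        spec.patch[1] = [0, 1, 2]
        out = enforce_patch_monotonicity(spec)
        assert out.patch == [[0, 1, 2], [0, 1, 2]]

    def test_revived_patch_is_removed_downstream(self, toy_cfg):
        spec = SubnetSpec.full(toy_cfg)
        spec.patch[0] = [0, 2]
        spec.patch[1] = [0, 1, 2]
        out = enforce_patch_monotonicity(spec)
        assert out.patch[1] == [0, 2]

    def test_matches_running_intersection_oracle(self, rng):
        cfg = SearchSpaceConfig(L=4, H=1, d=2, D=2, M=2, N=12)
        for _ in range(20):
            layers = [sorted(rng.choice(12, size=rng.integers(1, 13),
                                        replace=False).tolist())
                      for _ in range(4)]
            spec = SubnetSpec([[list(range(2))]] * 4, [[0, 1]] * 4, layers)
            got = enforce_patch_monotonicity(spec).patch
            acc, want = None, []
            for lay in layers:
                acc = set(lay) if acc is None else acc & set(lay)
                want.append(sorted(acc))
            assert got == want
            # only removals, never additions
            for g, orig in zip(got, layers):
                assert set(g) <= set(orig)


class TestSlicing:
    def test_full_budget_roundtrip(self, toy_cfg, toy_model, rng):
        full = SubnetSpec.full(toy_cfg)
        compact = slice_supernet(toy_model, full)
        t = rng.standard_normal((toy_cfg.N, toy_cfg.D)).astype(np.float32)
        np.testing.assert_allclose(
            np.asarray(toy_model.forward(t, patch_bypass=True)),
            np.asarray(compact.forward(t)), atol=1e-5)
        assert count_params(full, toy_cfg) == enumerate_searchable_params(compact)

    def test_random_specs_match_binarized_supernet(self, toy_cfg, toy_model, rng):
        for _ in range(10):
            spec = random_monotone_spec(rng, toy_cfg)
            keep = keep_arrays(spec, toy_cfg)
            compact = slice_supernet(toy_model, spec)
            for _ in range(2):
                t = rng.standard_normal((toy_cfg.N, toy_cfg.D)).astype(np.float32)
                np.testing.assert_allclose(
                    np.asarray(toy_model.forward(t, keep=keep)),
                    np.asarray(compact.forward(t)), atol=1e-4)

    def test_non_monotone_spec_rejected(self, toy_cfg, toy_model):
        spec = SubnetSpec.full(toy_cfg)
        spec.patch[0] = [0, 1]
        spec.patch[1] = [0, 1, 2]
        with pytest.raises(ValueError, match="monotone"):
            slice_supernet(toy_model, spec)

    def test_json_roundtrip(self, toy_cfg, rng, tmp_path):
        spec = random_monotone_spec(rng, toy_cfg)
        path = tmp_path / "spec.json"
        spec.to_json(path)
        back = SubnetSpec.from_json(path)
        assert back.mhsa == spec.mhsa and back.mlp == spec.mlp \
            and back.patch == spec.patch


class TestAccounting:
    def test_single_dim_costs(self, toy_cfg):
        # D=8: one mhsa dim costs 3*(8+1) + 8 = 35; one mlp dim costs 9 + 8 = 17
        full = SubnetSpec.full(toy_cfg)
        base = count_params(full, toy_cfg)
        drop_mhsa = SubnetSpec.full(toy_cfg)
        drop_mhsa.mhsa[0][0] = drop_mhsa.mhsa[0][0][:-1]
        assert base - count_params(drop_mhsa, toy_cfg) == 35
        drop_mlp = SubnetSpec.full(toy_cfg)
        drop_mlp.mlp[1] = drop_mlp.mlp[1][:-1]
        assert base - count_params(drop_mlp, toy_cfg) == 17

    def test_closed_form_equals_enumeration(self, toy_cfg, toy_model, rng):
        for _ in range(15):
            spec = random_monotone_spec(rng, toy_cfg)
            compact = slice_supernet(toy_model, spec)
            assert count_params(spec, toy_cfg) == enumerate_searchable_params(compact)

    def test_params_strictly_decrease_per_dropped_dim(self, toy_cfg):
        spec = SubnetSpec.full(toy_cfg)
        prev = count_params(spec, toy_cfg)
        while spec.mhsa[0][0]:
            spec.mhsa[0][0] = spec.mhsa[0][0][:-1]
            cur = count_params(spec, toy_cfg)
            assert cur < prev
            prev = cur

    def test_flops_scaling_with_patch_count(self):
        cfg = SearchSpaceConfig(L=1, H=2, d=4, D=8, M=16, N=16)
        full = SubnetSpec.full(cfg)
        half = SubnetSpec.full(cfg)
        half.patch[0] = list(range(8))
        N, Nh, D, dt, M = 16, 8, 8, 8, 16
        attn_full, attn_half = 2 * N * N * dt, 2 * Nh * Nh * dt
        lin_full = 3 * N * D * dt + N * dt * D + 2 * N * D * M
        lin_half = 3 * Nh * D * dt + Nh * dt * D + 2 * Nh * D * M
        assert count_flops(full, cfg) == attn_full + lin_full
        assert count_flops(half, cfg) == attn_half + lin_half
        assert attn_half * 4 == attn_full and lin_half * 2 == lin_full

    def test_flops_monotone_under_spec_inclusion(self, toy_cfg, rng):
        for _ in range(10):
            spec = random_monotone_spec(rng, toy_cfg)
            sub = SubnetSpec(
                [[hd[:max(1, len(hd) - 1)] for hd in layer] for layer in spec.mhsa],
                [m[:max(1, len(m) - 1)] for m in spec.mlp],
                spec.patch)
            assert count_flops(sub, toy_cfg) <= count_flops(spec, toy_cfg)
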