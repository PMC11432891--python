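"""Masked-forward contracts: shapes, determinism, identity and annihilation."""

import autograd
import autograd.numpy as anp
import numpy as np
import pytest

from dfslim import nn
from dfslim.config import SearchSpaceConfig
from dfslim.masked_transformer import (MaskSet, build_supernet, encoder_forward,
                                       masked_mhsa_forward, masked_mlp_forward,
                                       masked_patch_forward)
from dfslim.subnet import SubnetSpec, keep_arrays, slice_supernet


def reference_mhsa(p, t, keep_per_head, d_full):
    """Independently coded MHSA on physically sliced weights (plain numpy)."""
    N, D = t.shape
    outs = []
    rows = []
    H = len(keep_per_head)
    d = p["Wq"].shape[1] // H
    for h, idx in enumerate(keep_per_head):
        cols = [h * d + i for i in idx]
        q = t @ p["Wq"][:, cols] + p["bq"][cols]
        k = t @ p["Wk"][:, cols] + p["bk"][cols]
        v = t @ p["Wv"][:, cols] + p["bv"][cols]
        s = q @ k.T / np.sqrt(d_full)
        a = np.exp(s - s.max(axis=-1, keepdims=True))
        a /= a.sum(axis=-1, keepdims=True)
        outs.append(a @ v)
        rows.extend(cols)
    O = np.concatenate(outs, axis=-1) if outs else np.zeros((N, 0))
    return O @ p["Wo"][rows, :] + p["bo"]


class TestBuildSupernet:
    def test_shapes_follow_config(self):
        cfg = SearchSpaceConfig(L=2, H=2, d=4, D=8, M=16, N=9)
        model = build_supernet(cfg, seed=0)
        m = model.masks
        assert m.z_mhsa.shape == (2, 2, 4)
        assert m.z_mlp.shape == (2, 16)
        assert m.z_patch.shape == (2, 9)
        assert np.all(m.z_mhsa == 1) and np.all(m.z_mlp == 1) and np.all(m.z_patch == 1)

    def test_deterministic_under_seed(self):
        cfg = SearchSpaceConfig(L=2, H=2, d=4, D=8, M=16, N=9)
        a = build_supernet(cfg, seed=0)
        b = build_supernet(cfg, seed=0)
        for (pa, la), (pb, lb) in zip(nn.tree_leaves(a.params),
                                      nn.tree_leaves(b.params)):
            assert pa == pb and np.array_equal(la, lb)

    def test_inconsistent_head_geometry_rejected(self):
        with pytest.raises(ValueError, match="head geometry"):
            SearchSpaceConfig(L=1, H=2, d=4, D=7, M=8, N=4)


class TestMaskedMHSA:
    def test_binary_mask_matches_sliced_oracle(self, toy_cfg, toy_model, rng):
        t = rng.standard_normal((3, toy_cfg.D)).astype(np.float32)
        p = toy_model.params["encoder"]["0"]["attn"]
        for _ in range(10):
            keep = [sorted(rng.choice(toy_cfg.d, size=rng.integers(1, 5),
                                      replace=False).tolist())
                    for _ in range(toy_cfg.H)]
            z = np.zeros((toy_cfg.H, toy_cfg.d), np.float32)
            for h, idx in enumerate(keep):
                z[h, idx] = 1.0
            got = masked_mhsa_forward(p, t, z, toy_cfg.d)
            want = reference_mhsa(p, t, keep, toy_cfg.d)
            np.testing.assert_allclose(got, want, atol=1e-5)

    def test_allzero_head_annihilates(self, toy_cfg, toy_model, rng):
        t = rng.standard_normal((5, toy_cfg.D)).astype(np.float32)
        p = toy_model.params["encoder"]["0"]["attn"]
        z = np.ones((toy_cfg.H, toy_cfg.d), np.float32)
        z[1] = 0.0
        got = masked_mhsa_forward(p, t, z, toy_cfg.d)
        want = reference_mhsa(p, t, [list(range(toy_cfg.d)), []], toy_cfg.d)
        np.testing.assert_allclose(got, want, atol=1e-5)


class TestMaskedMLP:
    def test_ones_mask_is_plain_mlp(self, toy_cfg, toy_model, rng):
        t = rng.standard_normal((4, toy_cfg.D)).astype(np.float32)
        p = toy_model.params["encoder"]["1"]["mlp"]
        z = np.ones(toy_cfg.M, np.float32)
        got = masked_mlp_forward(p, t, z)
        want = (t @ p["f1"]["W"] + p["f1"]["b"]) @ p["f2"]["W"] + p["f2"]["b"]
        np.testing.assert_allclose(got, want, atol=1e-6)

    def test_zero_mask_leaves_f2_bias(self, toy_cfg, toy_model, rng):
        t = rng.standard_normal((4, toy_cfg.D)).astype(np.float32)
        p = toy_model.params["encoder"]["0"]["mlp"]
        got = masked_mlp_forward(p, t, np.zeros(toy_cfg.M, np.float32))
        np.testing.assert_allclose(got, np.broadcast_to(p["f2"]["b"], got.shape),
                                   atol=1e-7)

    def test_binary_mask_matches_sliced_oracle(self, toy_cfg, toy_model, rng):
        t = rng.standard_normal((3, toy_cfg.D)).astype(np.float32)
        p = toy_model.params["encoder"]["0"]["mlp"]
        idx = sorted(rng.choice(toy_cfg.M, size=7, replace=False).tolist())
        z = np.zeros(toy_cfg.M, np.float32)
        z[idx] = 1.0
        got = masked_mlp_forward(p, t, z)
        h = t @ p["f1"]["W"][:, idx] + p["f1"]["b"][idx]
        want = h @ p["f2"]["W"][idx, :] + p["f2"]["b"]
        np.testing.assert_allclose(got, want, atol=1e-5)


class TestPatchMask:
    def test_zero_score_kills_token(self, rng):
        t = rng.standard_normal((6, 8)).astype(np.float32)
        z = np.ones(6, np.float32)
        z[2] = 0.0
        out = np.asarray(masked_patch_forward(t, z))
        assert np.all(out[2] == 0)
        np.testing.assert_allclose(out[[0, 1, 3, 4, 5]],
                                   t[[0, 1, 3, 4, 5]] * np.tanh(1.0), rtol=1e-6)

    def test_tanh_bounded_and_value(self, rng):
        t = np.ones((3, 4), np.float32)
        out = np.asarray(masked_patch_forward(t, np.array([0.5, 50.0, -50.0],
                                                          np.float32)))
        assert out[0, 0] == pytest.approx(np.tanh(0.5), abs=1e-6)  # ~0.462117
        assert out[1, 0] == pytest.approx(1.0, abs=1e-6)
        assert out[2, 0] == pytest.approx(-1.0, abs=1e-6)
        assert np.all(np.abs(out) <= 1.0 + 1e-6)


class TestEncoderProperties:
    def test_identity_masks_match_unmasked_model(self, toy_cfg, toy_model, rng):
        """All-ones masks with the patch tanh bypassed reproduce the plain
        (sliced-at-full-budget) network on 20 random draws."""
        full = slice_supernet(toy_model, SubnetSpec.full(toy_cfg))
        for _ in range(20):
            t = rng.standard_normal((toy_cfg.N, toy_cfg.D)).astype(np.float32)
            a = np.asarray(toy_model.forward(t, patch_bypass=True))
            b = np.asarray(full.forward(t))
            np.testing.assert_allclose(a, b, atol=1e-5)

    def test_single_coordinate_annihilation(self, toy_cfg, toy_model, rng):
        """Zeroing any single MHSA/MLP mask coordinate equals physically
        removing that dimension from the network."""
        t = rng.standard_normal((toy_cfg.N, toy_cfg.D)).astype(np.float32)
        sites = [("mhsa", l, h, i) for l in range(toy_cfg.L)
                 for h in range(toy_cfg.H) for i in range(toy_cfg.d)] + \
                [("mlp", l, None, i) for l in range(toy_cfg.L)
                 for i in range(toy_cfg.M)]
        for kind, l, h, i in sites:
            spec = SubnetSpec.full(toy_cfg)
            keep = keep_arrays(spec, toy_cfg)
            if kind == "mhsa":
                spec.mhsa[l][h].remove(i)
                keep["mhsa"][l, h, i] = False
            else:
                spec.mlp[l].remove(i)
                keep["mlp"][l, i] = False
            masked = encoder_forward(
                {"encoder": toy_model.params["encoder"],
                 "masks": toy_model.params["masks"]},
                t, toy_cfg, keep=keep)
            sliced = slice_supernet(toy_model, spec).forward(t)
            np.testing.assert_allclose(np.asarray(masked), np.asarray(sliced),
                                       atol=1e-5)

    def test_masking_preserves_shapes_and_grads_finite(self, toy_cfg, toy_model, rng):
        t = rng.standard_normal((toy_cfg.N, toy_cfg.D)).astype(np.float32)

        def loss(masks):
            params = {"encoder": toy_model.params["encoder"], "masks": masks}
            return anp.sum(encoder_forward(params, t, toy_cfg) ** 2)

        g = autograd.grad(loss)(toy_model.params["masks"])
        for _, leaf in nn.tree_leaves(g):
            assert np.all(np.isfinite(leaf))
        out = toy_model.forward(t)
        assert out.shape == t.shape
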