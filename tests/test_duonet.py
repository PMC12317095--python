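"""Dual-branch transformer: gradients, invariances, sharing, dropout."""

import numpy as np
import pytest

from duetmil.duonet import (DuetTransformer, DuoNetConfig, branch_dropout_mask,
                            count_parameters)

TINY = DuoNetConfig(embed_dim_in=12, model_dim=8, n_layers=2, n_heads=2,
                    mlp_hidden=8, p_branch_dropout=0.0)


def _bags(n_he=4, n_ihc=3, d=12, seed=0):
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n_he, d)), rng.standard_normal((n_ihc, d))


class TestGradients:
    def test_backward_matches_finite_differences(self):
        """Analytic gradients of the BCE loss agree with central differences
        for every parameter tensor (spot-checked at the largest-gradient
        entry plus a random entry)."""
        model = DuetTransformer(TINY, seed=3)
        he, ihc = _bags()
        y, eps = 1.0, 1e-6
        rng = np.random.default_rng(0)
        trace = model.forward(he, ihc, mode="DUET", training=True, rng=rng)
        grads = model.backward(trace, y)

        def loss():
            return model.bce_loss(model.forward(he, ihc, mode="DUET").logit, y)

        check_rng = np.random.default_rng(1)
        for k, p in model.params.items():
            flat_idx = [int(np.argmax(np.abs(grads[k]))),
                        int(check_rng.integers(p.size))]
            for fi in flat_idx:
                idx = np.unravel_index(fi, p.shape)
                orig = p[idx]
                p[idx] = orig + eps
                lp = loss()
                p[idx] = orig - eps
                lm = loss()
                p[idx] = orig
                num = (lp - lm) / (2 * eps)
                ana = grads[k][idx]
                assert abs(num - ana) <= 1e-6 + 1e-4 * abs(num), f"grad mismatch in {k}"

    def test_gradient_reaches_both_branch_inputs(self):
        model = DuetTransformer(TINY, seed=1)
        he, ihc = _bags()
        trace = model.forward(he, ihc, mode="DUET", training=True,
                              rng=np.random.default_rng(0))
        assert trace.branch_kept == ("HE", "IHC")
        model.backward(trace, 1.0)
        assert np.abs(trace.d_inputs["HE"]).max() > 0
        assert np.abs(trace.d_inputs["IHC"]).max() > 0

    def test_dropped_branch_gets_zero_gradient(self):
        cfg = DuoNetConfig(embed_dim_in=12, model_dim=8, n_layers=2, n_heads=2,
                           mlp_hidden=8, p_branch_dropout=0.999)
        model = DuetTransformer(cfg, seed=1)
        he, ihc = _bags()
        trace = model.forward(he, ihc, mode="DUET", training=True,
                              rng=np.random.default_rng(0))
        assert len(trace.branch_kept) == 1
        model.backward(trace, 0.0)
        dropped = ({"HE", "IHC"} - set(trace.branch_kept)).pop()
        assert dropped not in trace.d_inputs  # no path, hence exactly zero gradient


class TestForwardContracts:
    def test_tile_permutation_invariance(self):
        model = DuetTransformer(TINY, seed=2)
        rng = np.random.default_rng(4)
        he, ihc = rng.standard_normal((20, 12)), rng.standard_normal((15, 12))
        base = model.forward(he, ihc, mode="DUET").probability
        for _ in range(25):
            p = model.forward(he[rng.permutation(20)], ihc[rng.permutation(15)],
                              mode="DUET").probability
            assert abs(p - base) < 1e-5

    def test_single_modality_ignores_other_bag(self):
        model = DuetTransformer(TINY, seed=2)
        he, ihc = _bags()
        a = model.forward(he, ihc, mode="HE_ONLY")
        b = model.forward(he, ihc * 100 + 5, mode="HE_ONLY")
        assert a.probability == b.probability and a.logit == b.logit

    def test_identical_tiles_share_attention_uniformly(self):
        """Identical tiles are indistinguishable to self-attention: the class
        token spreads its tile mass uniformly over them, and the prediction
        converges as multiplicity grows (exact invariance would require
        dropping the class token from the attention keys)."""
        model = DuetTransformer(TINY, seed=2)
        tile = np.random.default_rng(1).standard_normal((1, 12))
        trace = model.forward(np.repeat(tile, 7, axis=0), mode="HE_ONLY")
        for layer in trace.attention["HE"]:
            tile_w = layer[:, 0, 1:]
            assert np.allclose(tile_w, tile_w[:, :1])  # uniform over duplicates
        probs = {n: model.forward(np.repeat(tile, n, axis=0), mode="HE_ONLY").probability
                 for n in (16, 32, 256, 512)}
        assert abs(probs[512] - probs[256]) < abs(probs[32] - probs[16])
        assert abs(probs[512] - probs[256]) < 1e-3  # ~1/N tail from the class token

    def test_attention_rows_are_stochastic(self):
        model = DuetTransformer(TINY, seed=2)
        he, ihc = _bags()
        trace = model.forward(he, ihc, mode="DUET")
        for mats in trace.attention.values():
            for layer in mats:
                assert (layer >= 0).all()
                assert np.abs(layer.sum(axis=-1) - 1.0).max() < 1e-5

    def test_shared_trunk_branch_symmetry(self):
        """The same bag fed through either branch yields the same trunk output."""
        model = DuetTransformer(TINY, seed=2)
        bag, _ = _bags()
        fa = model.forward(bag, mode="HE_ONLY").branch_features["HE"]
        fb = model.forward(None, bag, mode="IHC_ONLY").branch_features["IHC"]
        assert np.allclose(fa, fb)

    def test_missing_required_bag_rejected(self):
        model = DuetTransformer(TINY, seed=0)
        he, _ = _bags()
        with pytest.raises(ValueError):
            model.forward(he, None, mode="DUET")
        with pytest.raises(ValueError):
            model.forward(None, None, mode="HE_ONLY")

    def test_allow_missing_zero_fills_branch(self):
        model = DuetTransformer(TINY, seed=0)
        he, _ = _bags()
        p = model.forward(he, None, mode="DUET", allow_missing=True)
        assert p.branch_kept == ("HE",)
        assert 0.0 < p.probability < 1.0

    def test_nan_embeddings_rejected(self):
        model = DuetTransformer(TINY, seed=0)
        he, ihc = _bags()
        he[0, 0] = np.nan
        with pytest.raises(ValueError):
            model.forward(he, ihc, mode="DUET")


class TestBranchDropout:
    def test_single_available_branch_always_kept(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            assert branch_dropout_mask(["HE"], 0.9, rng) == ("HE",)

    def test_empty_available_rejected(self):
        with pytest.raises(ValueError):
            branch_dropout_mask([], 0.3, np.random.default_rng(0))

    def test_p_zero_keeps_both(self):
        rng = np.random.default_rng(0)
        assert branch_dropout_mask(["HE", "IHC"], 0.0, rng) == ("HE", "IHC")


class TestParameterCounts:
    def test_trunk_shared_between_duet_and_single_use(self):
        cfg = DuoNetConfig(embed_dim_in=16, model_dim=8, n_heads=2, mlp_hidden=8)
        counts = count_parameters(DuetTransformer(cfg, seed=0))
        # the duet trunk IS the single-branch trunk: same tensors serve both
        assert counts["trunk"] == count_parameters(DuetTransformer(cfg, seed=1))["trunk"]
        assert counts["total"] == counts["trunk"] + counts["head"]

    def test_head_ingests_concatenated_branches(self):
        cfg = DuoNetConfig(embed_dim_in=16, model_dim=8, n_heads=2, mlp_hidden=8)
        model = DuetTransformer(cfg, seed=0)
        assert model.params["head_W1"].shape == (2 * cfg.model_dim, cfg.mlp_hidden)

    def test_trunk_grows_linearly_with_layers(self):
        def trunk(n_layers):
            cfg = DuoNetConfig(embed_dim_in=16, model_dim=8, n_heads=2,
                               mlp_hidden=8, n_layers=n_layers)
            return count_parameters(DuetTransformer(cfg, seed=0))["trunk"]

        d, f = 8, 8
        per_layer = 4 * (d * d + d) + 2 * 2 * d + (d * f + f) + (f * d + d)
        assert trunk(2) - trunk(1) == per_layer
        assert trunk(4) - trunk(2) == 2 * per_layer


class TestSerialization:
    def test_checkpoint_round_trip(self, tmp_path):
        model = DuetTransformer(TINY, seed=5)
        he, ihc = _bags()
        p_before = model.forward(he, ihc, mode="DUET").probability
        path = tmp_path / "model.npz"
        model.save(path)
        back = DuetTransformer.load(path)
        assert back.config == TINY
        assert back.forward(he, ihc, mode="DUET").probability == p_before

    def test_config_validation(self):
        with pytest.raises(ValueError):
            DuoNetConfig(model_dim=10, n_heads=3)
        with pytest.raises(ValueError):
            DuoNetConfig(p_branch_dropout=1.0)
        with pytest.raises(ValueError):
            DuoNetConfig(n_layers=0)
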