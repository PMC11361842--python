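import math

import numpy as np
import pytest

import slconnect as sl
from slconnect.autodiff import Tensor
from slconnect.connectivity_model import ConnectivityModel, normalized_adjacency


def small_cfg(**kw):
    return sl.ModelConfig.small(**kw)


def make_model(cfg, n_pop=5, n_cell=5, n_views=2):
    return ConnectivityModel(cfg, n_pop, n_cell, n_views)


class TestConfig:
    def test_head_divisibility_enforced(self):
        with pytest.raises(ValueError):
            sl.ModelConfig(embed_dim=10, n_attention_heads=4)

    def test_conservative_training_defaults(self):
        cfg = sl.ModelConfig()
        assert cfg.learning_rate == 5e-5
        assert cfg.dropout_encoder == 0.5 and cfg.dropout_predictor == 0.7
        assert cfg.max_epochs == 1000 and cfg.early_stop_patience_epochs == 200


class TestGeneEncoder:
    def test_output_shape(self, bench_strong_small):
        bundle, _ = bench_strong_small
        emb = sl.encode_genes(bundle, small_cfg())
        assert emb.matrix.shape == (len(bundle.genes), 16)
        assert emb.stage == "gene_encoded"

    def test_row_permutation_equivariance(self):
        cfg = small_cfg()
        model = make_model(cfg)
        rng = np.random.default_rng(0)
        xp, xc = rng.standard_normal((7, 5)), rng.standard_normal((7, 5))
        perm = rng.permutation(7)
        base = model.gene_stage(xp, xc, 7).data
        permuted = model.gene_stage(xp[perm], xc[perm], 7).data
        np.testing.assert_allclose(permuted, base[perm])

    def test_missing_scope_uses_constant_branch(self):
        cfg = small_cfg()
        model = ConnectivityModel(cfg, n_pop=0, n_cell=3, n_views=0)
        xc = np.random.default_rng(0).standard_normal((4, 3))
        out = model.gene_stage(None, xc, 4).data
        assert out.shape == (4, 16)

    def test_zero_features_give_identical_rows(self):
        cfg = small_cfg()
        model = make_model(cfg, n_views=0)
        out = model.gene_stage(np.zeros((5, 5)), np.zeros((5, 5)), 5).data
        assert np.allclose(out, out[0])


class TestGraphEncoder:
    def path_adjacency(self):
        view = sl.NetworkView("pathway", frozenset({("A", "B"), ("B", "C")}),
                              frozenset({"A", "B", "C"}))
        return normalized_adjacency(view, ("A", "B", "C"))

    def test_normalized_adjacency_hand_computed(self):
        """3-node path A-B-C: A+I degrees are (2,3,2); check entries."""
        ahat = self.path_adjacency()
        expected = np.array([
            [1 / 2, 1 / math.sqrt(6), 0],
            [1 / math.sqrt(6), 1 / 3, 1 / math.sqrt(6)],
            [0, 1 / math.sqrt(6), 1 / 2],
        ])
        np.testing.assert_allclose(ahat, expected)

    def test_message_passing_equals_dense_oracle(self):
        """One layer on the path graph reproduces relu(A_hat @ H @ W + b)."""
        cfg = small_cfg(n_graph_layers=1)
        model = ConnectivityModel(cfg, 5, 5, n_views=1)
        rng = np.random.default_rng(1)
        h = rng.standard_normal((3, 16))
        ahat = self.path_adjacency()
        out = model.graph_stage(Tensor(h), [ahat]).data
        W = model.params["gcn_0_0_W"].data
        b = model.params["gcn_0_0_b"].data
        hv = np.maximum(ahat @ h @ W + b, 0.0)
        oracle = hv @ model.params["view_W"].data + model.params["view_b"].data
        np.testing.assert_allclose(out, oracle, atol=1e-10)

    def test_edgeless_graph_depends_only_on_self(self):
        cfg = small_cfg(n_graph_layers=1)
        model = ConnectivityModel(cfg, 5, 5, n_views=1)
        empty = sl.NetworkView("pathway", frozenset(), frozenset({"A", "B"}))
        ahat = normalized_adjacency(empty, ("A", "B"))
        np.testing.assert_array_equal(ahat, np.eye(2))
        rng = np.random.default_rng(2)
        h1, h2 = rng.standard_normal((2, 2, 16))
        h1[1] = h2[1]  # same gene B, different gene A
        o1 = model.graph_stage(Tensor(h1), [ahat]).data
        o2 = model.graph_stage(Tensor(h2), [ahat]).data
        np.testing.assert_allclose(o1[1], o2[1])

    def test_isomorphic_graphs_give_permuted_outputs(self):
        cfg = small_cfg(n_graph_layers=2)
        model = ConnectivityModel(cfg, 5, 5, n_views=1)
        view = sl.NetworkView("pathway",
                              frozenset({("A", "B"), ("B", "C"), ("A", "D")}),
                              frozenset("ABCD"))
        genes = ("A", "B", "C", "D")
        rng = np.random.default_rng(3)
        h = rng.standard_normal((4, 16))
        perm = np.array([2, 0, 3, 1])
        ahat = normalized_adjacency(view, genes)
        out = model.graph_stage(Tensor(h), [ahat]).data
        out_p = model.graph_stage(Tensor(h[perm]),
                                  [ahat[np.ix_(perm, perm)]]).data
        np.testing.assert_allclose(out_p, out[perm], atol=1e-10)

    def test_no_views_passthrough_warns(self):
        model = make_model(small_cfg(), n_views=0)
        h = Tensor(np.ones((3, 16)))
        with pytest.warns(UserWarning):
            out = model.graph_stage(h, [])
        np.testing.assert_array_equal(out.data, h.data)


class TestTransformer:
    def test_attention_rows_are_distributions(self):
        model = make_model(small_cfg())
        h = np.random.default_rng(0).standard_normal((6, 16))
        model.transformer_stage(Tensor(h))
        for attn in model.last_attention:
            assert (attn >= 0).all()
            np.testing.assert_allclose(attn.sum(axis=-1), 1.0, atol=1e-6)

    def test_single_gene_attention_is_one(self):
        model = make_model(small_cfg())
        h = np.random.default_rng(1).standard_normal((1, 16))
        out = model.transformer_stage(Tensor(h))
        np.testing.assert_allclose(model.last_attention[0],
                                   np.ones((2, 1, 1)))
        assert out.data.shape == (1, 16)

    def test_attention_matches_direct_formula(self):
        """Single-layer single-head output context equals softmax(QK^T/sqrt(d))V
        computed independently from the same fixed weights."""
        cfg = small_cfg(n_attention_heads=1)
        model = make_model(cfg)
        rng = np.random.default_rng(2)
        h = rng.standard_normal((3, 16))
        p = model.params
        q = h @ p["attn_0_qW"].data + p["attn_0_qb"].data
        k = h @ p["attn_0_kW"].data + p["attn_0_kb"].data
        v = h @ p["attn_0_vW"].data + p["attn_0_vb"].data
        scores = q @ k.T / math.sqrt(16)
        e = np.exp(scores - scores.max(axis=1, keepdims=True))
        attn = e / e.sum(axis=1, keepdims=True)
        model.transformer_stage(Tensor(h))
        np.testing.assert_allclose(model.last_attention[0][0], attn, atol=1e-10)


class TestTrainingAndPrediction:
    def test_predictions_nonnegative_and_deterministic(self, bench_strong_small,
                                                       small_model_config):
        bundle, _ = bench_strong_small
        split = sl.split_nonoverlap(bundle, seed=0)
        trained = sl.train_connectivity_model(bundle, split, small_model_config)
        p1, p2 = trained.predict(), trained.predict()
        assert (p1 >= 0).all() and np.isfinite(p1).all()
        np.testing.assert_array_equal(p1, p2)  # eval mode is bit-stable

    def test_early_stopping_contract(self, bench_strong_small, small_model_config):
        bundle, _ = bench_strong_small
        split = sl.split_nonoverlap(bundle, seed=0)
        trained = sl.train_connectivity_model(bundle, split, small_model_config)
        val = [h["val_loss"] for h in trained.history]
        assert trained.best_epoch <= trained.history[-1]["epoch"]
        assert val[trained.best_epoch] == min(val)

    def test_seeded_determinism(self, bench_strong_small, small_model_config):
        bundle, _ = bench_strong_small
        split = sl.split_nonoverlap(bundle, seed=1)
        a = sl.train_connectivity_model(bundle, split, small_model_config)
        b = sl.train_connectivity_model(bundle, split, small_model_config)
        assert a.history == b.history
        for k in a.model.params:
            np.testing.assert_array_equal(a.model.params[k].data,
                                          b.model.params[k].data)

    def test_heldout_recovery_on_strong_signal(self, bench_strong_small):
        """Predicted vs true connectivity correlates on held-out genes."""
        bundle, _ = bench_strong_small
        split = sl.split_nonoverlap(bundle, seed=0)
        cfg = small_cfg(max_epochs=120, early_stop_patience_epochs=30)
        trained = sl.train_connectivity_model(bundle, split, cfg)
        genes = sorted(split.test_genes)
        truth = sl.compute_connectivity(bundle.screen, split.test_pairs)
        true_c = truth.as_dict()
        r = np.corrcoef(trained.predict(genes),
                        [true_c[g] for g in genes])[0, 1]
        assert r > 0.5

    def test_null_recovery_near_zero(self):
        """Pure-noise features and networks: median held-out correlation
        over 5 independent benchmarks stays within +/-0.15 of zero (a single
        30-gene test set has null sd ~0.19, so one draw is uninformative)."""
        rs = []
        for seed in range(5):
            cfg_sim = sl.SimConfig(n_genes=150, feature_signal=0.0,
                                   network_rewire_prob=1.0, seed=seed)
            bundle, _ = sl.make_benchmark(cfg_sim)
            split = sl.split_nonoverlap(bundle, seed=seed)
            cfg = small_cfg(seed=seed, max_epochs=80,
                            early_stop_patience_epochs=25)
            trained = sl.train_connectivity_model(bundle, split, cfg)
            genes = sorted(split.test_genes)
            true_c = sl.compute_connectivity(bundle.screen,
                                             split.test_pairs).as_dict()
            rs.append(np.corrcoef(trained.predict(genes),
                                  [true_c[g] for g in genes])[0, 1])
        assert abs(np.median(rs)) < 0.15

    def test_stage_wrappers_compose(self, bench_strong_small):
        bundle, _ = bench_strong_small
        cfg = small_cfg()
        emb = sl.encode_genes(bundle, cfg)
        emb = sl.graph_encode(emb, bundle.networks, cfg)
        assert emb.stage == "graph_encoded"
        emb = sl.transformer_encode(emb, cfg)
        assert emb.stage == "transformer_encoded"
        with pytest.raises(sl.StateError):
            sl.transformer_encode(emb, cfg)  # wrong stage ordering
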