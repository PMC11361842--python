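import numpy as np
import pytest
from hypothesis import given, strategies as st

import slconnect as sl


# ---------------------------------------------------------------------------
# Brute-force metric oracles (independent of the implementations under test)
# ---------------------------------------------------------------------------

def auc_pair_counting(labels, scores):
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def aupr_threshold_sweep(labels, scores):
    """Step-wise PR area: at each distinct score threshold (descending),
    precision times the recall increment, ties grouped."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = labels.sum()
    area, prev_recall = 0.0, 0.0
    for t in sorted(set(scores.tolist()), reverse=True):
        sel = scores >= t
        tp = labels[sel].sum()
        precision = tp / sel.sum()
        recall = tp / n_pos
        area += precision * (recall - prev_recall)
        prev_recall = recall
    return area


def precision_topm(labels, scores, k_percent):
    order = sorted(range(len(labels)), key=lambda i: (-scores[i], i))
    m = int(np.ceil(k_percent / 100 * len(labels)))
    return sum(labels[i] for i in order[:m]) / m


binary_instances = st.integers(2, 12).flatmap(
    lambda n: st.tuples(
        st.lists(st.integers(0, 1), min_size=n, max_size=n),
        st.lists(st.integers(0, 4), min_size=n, max_size=n),  # ties likely
    )
)


class TestMetrics:
    def test_auc_hand_example(self):
        # positives {0.9, 0.1} vs negatives {0.8, 0.05}: 3 of 4 pairs won
        labels, scores = [1, 0, 1, 0], [0.9, 0.8, 0.1, 0.05]
        assert sl.auc_roc(labels, scores) == 0.75
        assert sl.auc_roc(labels, scores) == auc_pair_counting(labels, scores)

    def test_auc_perfect_and_ties(self):
        assert sl.auc_roc([1, 1, 0], [3, 2, 1]) == 1.0
        assert sl.auc_roc([1, 0, 1, 0], [1, 1, 1, 1]) == 0.5

    def test_auc_single_class_errors(self):
        with pytest.raises(sl.MetricError):
            sl.auc_roc([1, 1], [0.1, 0.2])

    def test_aupr_hand_example_matches_sweep(self):
        labels, scores = [1, 0, 1, 0], [0.9, 0.8, 0.1, 0.05]
        assert sl.aupr(labels, scores) == pytest.approx(
            aupr_threshold_sweep(labels, scores), abs=1e-9
        )

    def test_aupr_perfect_and_constant(self):
        assert sl.aupr([1, 1, 0, 0], [4, 3, 2, 1]) == 1.0
        assert sl.aupr([1, 0, 0, 0], [1, 1, 1, 1]) == pytest.approx(0.25)

    @given(binary_instances)
    def test_auc_matches_pair_counting_oracle(self, case):
        labels, scores = case
        if len(set(labels)) < 2:
            return
        assert sl.auc_roc(labels, scores) == pytest.approx(
            auc_pair_counting(labels, scores), abs=1e-9
        )

    @given(binary_instances)
    def test_aupr_matches_threshold_sweep_oracle(self, case):
        labels, scores = case
        if sum(labels) == 0:
            return
        assert sl.aupr(labels, scores) == pytest.approx(
            aupr_threshold_sweep(labels, scores), abs=1e-9
        )

    @given(binary_instances)
    def test_precision_at_k_matches_oracle(self, case):
        labels, scores = case
        for k in (10, 25, 50, 100):
            assert sl.precision_at_k(labels, scores, k) == pytest.approx(
                precision_topm(labels, scores, k)
            )

    @given(binary_instances)
    def test_auc_invariant_under_monotone_transform(self, case):
        labels, scores = case
        if len(set(labels)) < 2:
            return
        transformed = [np.expm1(s) + 3 for s in scores]
        assert sl.auc_roc(labels, scores) == pytest.approx(
            sl.auc_roc(labels, transformed), abs=1e-12
        )

    def test_precision_at_100_is_prevalence(self):
        labels = [1, 0, 1, 0, 0]
        assert sl.precision_at_k(labels, [5, 4, 3, 2, 1], 100) == 0.4

    def test_precision_at_k_hand_examples(self):
        labels, scores = [1, 0, 1, 0], [0.9, 0.8, 0.1, 0.05]
        assert sl.precision_at_k(labels, scores, 50) == 0.5
        assert sl.precision_at_k(labels, scores, 25) == 1.0


class TestSplits:
    def complete_bundle(self, n=10, seed=0):
        bundle, _ = sl.make_benchmark(sl.SimConfig(n_genes=n, seed=seed))
        return bundle

    def test_nonoverlap_counting_on_complete_screen(self):
        bundle = self.complete_bundle(10)
        split = sl.split_nonoverlap(bundle, 0.2, 0.2, seed=0)
        assert len(split.test_genes) == 2
        assert len(split.test_pairs) == 1
        assert len(split.train_pairs) + len(split.val_pairs) == 28
        discarded = 45 - 1 - 28
        assert discarded == 16

    def test_nonoverlap_no_shared_genes_any_seed(self):
        bundle = self.complete_bundle(20)
        for seed in range(20):
            split = sl.split_nonoverlap(bundle, seed=seed)
            assert not (split.train_genes & split.test_genes)
            assert all(p[0] in split.test_genes and p[1] in split.test_genes
                       for p in split.test_pairs)

    def test_overlap_counts_and_conservation(self):
        bundle, _ = sl.make_benchmark(sl.SimConfig(n_genes=15, seed=1))
        n_pairs = len(bundle.screen.pair_set)
        split = sl.split_overlap(bundle, 0.2, 0.2, seed=0)
        n_test = round(0.2 * n_pairs)
        n_val = round(0.2 * (n_pairs - n_test))
        assert len(split.test_pairs) == n_test
        assert len(split.val_pairs) == n_val
        assert (len(split.train_pairs) + len(split.val_pairs)
                + len(split.test_pairs)) == n_pairs

    def test_split_determinism(self):
        bundle = self.complete_bundle(12)
        a = sl.split_nonoverlap(bundle, seed=5)
        b = sl.split_nonoverlap(bundle, seed=5)
        assert a == b


class TestRepeatedEvaluation:
    def test_single_run_flagged(self, bench_strong_small, small_model_config):
        bundle, _ = bench_strong_small
        report = sl.repeated_evaluation(bundle, small_model_config, n_runs=1)
        assert report.single_run and report.n_runs == 1
        assert all(v == 0.0 for v in report.sd.values())

    def test_mean_consistent_with_per_run(self, bench_strong_small,
                                          small_model_config):
        bundle, _ = bench_strong_small
        report = sl.repeated_evaluation(bundle, small_model_config, n_runs=3)
        for m, runs in report.per_run.items():
            assert report.mean[m] == pytest.approx(np.mean(runs))
            assert report.sd[m] == pytest.approx(np.std(runs, ddof=1))
            assert all(0.0 <= v <= 1.0 for v in runs)

    def test_report_reproducibility(self, bench_strong_small, small_model_config):
        bundle, _ = bench_strong_small
        a = sl.repeated_evaluation(bundle, small_model_config, n_runs=2)
        b = sl.repeated_evaluation(bundle, small_model_config, n_runs=2)
        assert a.per_run == b.per_run


class TestAblation:
    def test_transformer_toggle_isolated(self, bench_strong_small):
        """Disabling the transformer changes nothing upstream of it."""
        bundle, _ = bench_strong_small
        cfg = sl.ModelConfig.small()
        emb = sl.encode_genes(bundle, cfg)
        emb_g = sl.graph_encode(emb, bundle.networks, cfg)
        # the graph-stage output is identical whether or not a transformer
        # will be applied afterwards; the toggle only bypasses the next stage
        cfg_no = sl.ModelConfig.small()
        emb2 = sl.encode_genes(bundle, cfg_no)
        emb2_g = sl.graph_encode(emb2, bundle.networks, cfg_no)
        np.testing.assert_array_equal(emb_g.matrix, emb2_g.matrix)

    def test_single_feature_spec_shape(self, bench_strong_small):
        bundle, _ = bench_strong_small
        spec = sl.AblationSpec(single_feature="expression")
        ablated = sl.apply_ablation(bundle, spec, seed=0)
        kept = [t for t in ablated.features if t.modality == "expression"]
        randomized = [t for t in ablated.features if t.modality != "expression"]
        assert len(kept) == 1
        orig = {t.modality: t for t in bundle.features}
        for t in randomized:
            assert t.values.shape == (len(bundle.genes), len(t.feature_names))
        for v, ov in zip(ablated.networks, bundle.networks):
            assert len(v.edges) == len(ov.edges)
            assert v.edges != ov.edges

    def test_disabled_sources_are_randomized(self, bench_strong_small):
        bundle, _ = bench_strong_small
        spec = sl.AblationSpec(use_network_features=False,
                               use_population_omics=False,
                               use_cell_specific_omics=True)
        ablated = sl.apply_ablation(bundle, spec, seed=0)
        for t, ot in zip(ablated.features, bundle.features):
            if ot.scope == "cell_specific":
                np.testing.assert_array_equal(t.values, ot.values)
            else:
                assert not np.array_equal(t.values, ot.values)

    def test_all_random_control_near_chance(self):
        """Everything replaced by random features: AUC within 0.1 of 0.5."""
        bundle, _ = sl.make_benchmark(
            sl.SimConfig(n_genes=150, feature_signal=0.9,
                         network_rewire_prob=0.1, seed=0)
        )
        spec = sl.AblationSpec(use_network_features=False,
                               use_population_omics=False,
                               use_cell_specific_omics=False)
        cfg = sl.ModelConfig.small(max_epochs=60, early_stop_patience_epochs=20)
        report = sl.ablation_run(bundle, spec, cfg, n_runs=5)
        assert abs(report.mean["auc_roc"] - 0.5) < 0.1
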