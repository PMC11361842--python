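"""Splits, ranking metrics, repeated-run aggregation, and ablation harness.

The evaluation protocol of record is the *nonoverlap* split: genes — not
pairs — are partitioned into train and test sets, test pairs have both
endpoints among test genes, and pairs straddling the partition are
discarded.  This measures generalization to genes never seen in training,
the regime where pair-level models fail.  The conventional *overlap* split
(random pairs) is also provided.

Metrics are AUC-ROC, AUPR (step-wise precision-recall area with tie
grouping), and Precision@k% (ceil convention, deterministic tie-break).
Repeated evaluation runs the full two-step pipeline over seeded splits and
reports mean +/- sd.  The ablation harness swaps out feature sources for
shape-matched standard-normal random features (and network views for random
edge sets of equal size), or bypasses the transformer stage, leaving
everything else identical.
"""

from __future__ import annotations



from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .connectivity_model import ModelConfig, TrainedConnectivityModel, \
    train_connectivity_model
from .data_io import DatasetBundle, FeatureTable, NetworkView
from .pair_classifier import SLClassifier, fit_sl_classifier, predict_sl
from .synthetic_data import _rewire_edges  # random replacement shares machinery


class MetricError(ValueError):
    """Metric undefined for the given labels (e.g. single class)."""


class SplitError(ValueError):
    """A split produced an unusable partition."""


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    """A train/validation/test partition of genes and pairs."""

    mode: str
    train_genes: frozenset[str]
    test_genes: frozenset[str]
    train_pairs: frozenset[tuple[str, str]]
    val_pairs: frozenset[tuple[str, str]]
    test_pairs: frozenset[tuple[str, str]]
    seed: int

    def __post_init__(self):
        if self.mode == "nonoverlap":
            if self.train_genes & self.test_genes:
                raise SplitError("nonoverlap split has shared genes")
            bad = [p for p in self.test_pairs
                   if p[0] not in self.test_genes or p[1] not in self.test_genes]
            if bad:
                raise SplitError(f"test pairs outside test genes: {bad[:3]}")
        for a, b in [(self.train_pairs, self.val_pairs),
                     (self.train_pairs, self.test_pairs),
                     (self.val_pairs, self.test_pairs)]:
            if a & b:
                raise SplitError("train/val/test pair sets overlap")


def split_nonoverlap(
    bundle: DatasetBundle,
    test_gene_fraction: float = 0.2,
    val_pair_fraction: float = 0.2,
    seed: int = 0,
) -> SplitSpec:
    """Partition genes into train/test; keep only same-side pairs.

    Cross pairs (one endpoint per side) are discarded entirely — assigning
    them to training would let test genes influence the fit.
    """
    if not (0 < test_gene_fraction < 1 and 0 < val_pair_fraction < 1):
        raise ValueError("fractions must be in (0, 1)")
    rng = np.random.Generator(np.random.PCG64(seed))
    genes = np.array(bundle.genes)
    perm = rng.permutation(len(genes))
    n_test = max(1, int(round(test_gene_fraction * len(genes))))
    test_genes = frozenset(genes[perm[:n_test]].tolist())
    train_genes = frozenset(genes[perm[n_test:]].tolist())
    pairs = sorted(bundle.screen.pair_set)
    test_pairs, train_side = [], []
    for p in pairs:
        in_test = (p[0] in test_genes) + (p[1] in test_genes)
        if in_test == 2:
            test_pairs.append(p)
        elif in_test == 0:
            train_side.append(p)
    if not test_pairs:
        raise SplitError(
            "no test pairs with both endpoints in the test genes; "
            "try a larger test_gene_fraction"
        )
    vperm = rng.permutation(len(train_side))
    n_val = int(round(val_pair_fraction * len(train_side)))
    val_pairs = frozenset(train_side[i] for i in vperm[:n_val])
    train_pairs = frozenset(train_side[i] for i in vperm[n_val:])
    return SplitSpec("nonoverlap", train_genes, test_genes,
                     train_pairs, val_pairs, frozenset(test_pairs), seed)


def split_overlap(
    bundle: DatasetBundle,
    test_pair_fraction: float = 0.2,
    val_pair_fraction: float = 0.2,
    seed: int = 0,
) -> SplitSpec:
    """Random pair-level split; every pair lands in exactly one subset."""
    if not (0 < test_pair_fraction < 1 and 0 < val_pair_fraction < 1):
        raise ValueError("fractions must be in (0, 1)")
    rng = np.random.Generator(np.random.PCG64(seed))
    pairs = sorted(bundle.screen.pair_set)
    perm = rng.permutation(len(pairs))
    n_test = int(round(test_pair_fraction * len(pairs)))
    n_val = int(round(val_pair_fraction * (len(pairs) - n_test)))
    test_pairs = frozenset(pairs[i] for i in perm[:n_test])
    val_pairs = frozenset(pairs[i] for i in perm[n_test:n_test + n_val])
    train_pairs = frozenset(pairs[i] for i in perm[n_test + n_val:])
    if not test_pairs:
        raise SplitError("no test pairs; try a larger test_pair_fraction")
    genes = frozenset(bundle.genes)
    return SplitSpec("overlap", genes, genes,
                     train_pairs, val_pairs, test_pairs, seed)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise MetricError("empty label list")
    return labels


def auc_roc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Probability a positive outranks a negative (ties count half)."""
    y = _check_binary(labels)
    if len(set(y.tolist())) < 2:
        raise MetricError("AUC-ROC needs both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def aupr(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Step-wise precision-recall area with tie grouping (average precision).

    Degenerate all-tied scores give the prevalence.
    """
    y = _check_binary(labels)
    if y.sum() == 0:
        raise MetricError("AUPR needs at least one positive")
    return float(average_precision_score(y, np.asarray(scores, dtype=float)))


def precision_at_k(
    labels: Sequence[int],
    scores: Sequence[float],
    k_percent: float = 10.0,
    tie_key: Optional[Sequence] = None,
) -> float:
    """Precision among the top ceil(k% * N) scored items.

    Ties are broken by a stable sort on a deterministic secondary key
    (supplied tie_key, e.g. the gene pair, else the input index), so results
    are platform-independent.
    """
    if not (0 < k_percent <= 100):
        raise ValueError("k_percent must be in (0, 100]")
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    keys = list(tie_key) if tie_key is not None else list(range(len(y)))
    order = sorted(range(len(y)), key=lambda i: (-s[i], keys[i]))
    m = int(np.ceil(k_percent / 100.0 * len(y)))
    top = order[:m]
    return float(y[top].sum() / m)


# ---------------------------------------------------------------------------
# Two-step pipeline and repeated evaluation
# ---------------------------------------------------------------------------

@dataclass
class RunResult:
    """One split's trained models, test scores, and metric values."""

    split: SplitSpec
    trained: TrainedConnectivityModel
    classifier: SLClassifier
    test_pairs: tuple[tuple[str, str], ...]
    test_labels: np.ndarray
    test_scores: np.ndarray
    metrics: dict[str, float]


@dataclass(frozen=True)
class MetricsReport:
    """Per-run metric values with mean +/- sd (sd uses n-1 denominator)."""

    per_run: dict[str, tuple[float, ...]]
    mean: dict[str, float]
    sd: dict[str, float]
    n_runs: int
    single_run: bool = False
    conventions: dict = field(default_factory=lambda: {
        "aupr": "step-wise precision-recall area, ties grouped",
        "precision_at_k": "ceil(k% * N), stable lexicographic tie-break",
    })


def run_two_step(bundle: DatasetBundle, split: SplitSpec,
                 model_config: ModelConfig,
                 k_percent: float = 10.0) -> RunResult:
    """Train step 1 + step 2 on the training side and score the test pairs.

    Step 2 is fitted on *predicted* connectivities of training genes (the
    quantities available at prediction time), against the training pairs'
    labels; test-pair metrics use test labels only.
    """
    trained = train_connectivity_model(bundle, split, model_config)
    conn = trained.predictions_by_gene()
    train_pairs = sorted(split.train_pairs)
    train_labels = bundle.screen.labels_for(train_pairs)
    classifier = fit_sl_classifier(
        [(conn[a], conn[b]) for a, b in train_pairs], train_labels
    )
    test_pairs = tuple(sorted(split.test_pairs))
    test_labels = bundle.screen.labels_for(test_pairs)
    test_scores = predict_sl(classifier, test_pairs, conn)
    metrics = {
        "auc_roc": auc_roc(test_labels, test_scores),
        "aupr": aupr(test_labels, test_scores),
        f"precision_at_{int(k_percent)}": precision_at_k(
            test_labels, test_scores, k_percent, tie_key=test_pairs
        ),
    }
    return RunResult(split, trained, classifier, test_pairs,
                     test_labels, test_scores, metrics)


def _aggregate(per_run_metrics: list[dict[str, float]]) -> MetricsReport:
    names = list(per_run_metrics[0])
    per_run = {m: tuple(r[m] for r in per_run_metrics) for m in names}
    mean = {m: float(np.mean(v)) for m, v in per_run.items()}
    n = len(per_run_metrics)
    sd = {m: (float(np.std(v, ddof=1)) if n > 1 else 0.0)
          for m, v in per_run.items()}
    return MetricsReport(per_run, mean, sd, n_runs=n, single_run=(n == 1))


def repeated_evaluation(
    bundle: DatasetBundle,
    model_config: ModelConfig,
    n_runs: int = 10,
    mode: str = "nonoverlap",
    k_percent: float = 10.0,
    run_seeds: Optional[Sequence[int]] = None,
) -> MetricsReport:
    """Evaluate the two-step pipeline over repeated seeded splits.

    Run i uses split seed i (0..n_runs-1 unless run_seeds overrides) and a
    model seeded identically, then aggregates metrics as mean +/- sd.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    seeds = list(run_seeds) if run_seeds is not None else list(range(n_runs))
    if len(seeds) != n_runs:
        raise ValueError("run_seeds length must equal n_runs")
    splitter = split_nonoverlap if mode == "nonoverlap" else split_overlap
    results = []
    for s in seeds:
        split = splitter(bundle, seed=s)
        cfg = replace(model_config, seed=s)
        results.append(run_two_step(bundle, split, cfg, k_percent).metrics)
    return _aggregate(results)


# ---------------------------------------------------------------------------
# Ablation harness
# ---------------------------------------------------------------------------

SINGLE_FEATURE_SOURCES = (
    "ppi_physical", "ppi_genetic", "pathway",
    "expression", "essentiality", "cnv", "mutation",
)


@dataclass(frozen=True)
class AblationSpec:
    """Which input sources stay real; disabled ones become random controls."""

    use_network_features: bool = True
    use_population_omics: bool = True
    use_cell_specific_omics: bool = True
    use_transformer: bool = True
    single_feature: Optional[str] = None

    def __post_init__(self):
        if self.single_feature is not None:
            if self.single_feature not in SINGLE_FEATURE_SOURCES:
                raise ValueError(
                    f"unknown single_feature {self.single_feature!r}"
                )


def _random_feature_table(table: FeatureTable,
                          rng: np.random.Generator) -> FeatureTable:
    values = rng.standard_normal(table.values.shape)
    return replace(table, values=values, modality="other")


def _random_network(view: NetworkView, genes: tuple[str, ...],
                    rng: np.random.Generator) -> NetworkView:
    # same edge count, uniformly random topology
    edges = _rewire_edges(view.edges, genes, prob=1.0, rng=rng)
    return replace(view, edges=edges)


def apply_ablation(bundle: DatasetBundle, spec: AblationSpec,
                   seed: int = 0) -> DatasetBundle:
    """Return a bundle in which disabled sources are replaced by controls:
    standard-normal features of matching shape, or random same-size networks."""
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    if spec.single_feature is not None:
        keep_network = {n for n in ("ppi_physical", "ppi_genetic", "pathway")
                        if n == spec.single_feature}
        features = [
            t if t.modality == spec.single_feature
            else _random_feature_table(t, rng)
            for t in bundle.features
        ]
        networks = [
            v if v.name in keep_network else _random_network(v, bundle.genes, rng)
            for v in bundle.networks
        ]
        return DatasetBundle(bundle.screen, features, networks,
                             bundle.connectivity)
    if not (spec.use_network_features or spec.use_population_omics
            or spec.use_cell_specific_omics):
        pass  # all-random control: every source replaced below
    features = []
    for t in bundle.features:
        keep = (spec.use_population_omics if t.scope == "population"
                else spec.use_cell_specific_omics)
        features.append(t if keep else _random_feature_table(t, rng))
    networks = [
        v if spec.use_network_features else _random_network(v, bundle.genes, rng)
        for v in bundle.networks
    ]
    return DatasetBundle(bundle.screen, features, networks, bundle.connectivity)


def ablation_run(
    bundle: DatasetBundle,
    spec: AblationSpec,
    model_config: ModelConfig,
    n_runs: int = 10,
    mode: str = "nonoverlap",
) -> MetricsReport:
    """Repeated evaluation with the given sources ablated.

    use_transformer=False bypasses the transformer stage (graph-encoder-only
    pipeline); all other machinery is unchanged.
    """
    ablated = apply_ablation(bundle, spec, seed=0)
    cfg = replace(model_config, use_transformer=spec.use_transformer)
    return repeated_evaluation(ablated, cfg, n_runs=n_runs, mode=mode)
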