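"""Desk-scale synthetic benchmark generator.

Real SL networks are scale-free: a few hub genes carry many SL partners
while most genes carry few.  The generator reproduces that structure with a
Barabasi-Albert preferential-attachment graph, then builds everything the
two-step model consumes around it:

* a complete-pair GI screen whose scores place true SL pairs around -5 and
  non-SL pairs around 0 (so the -3 labeling threshold sits between classes,
  with flip probability governed by the Gaussian noise sd);
* omics-like feature tables whose columns mix a standardized log(1+degree)
  signal with independent Gaussian noise, at a configurable signal fraction;
* network views that are noisy copies of the true SL graph, produced by
  rewiring each edge to a random non-edge with a configurable probability.

Every simulator is a pure function of (config, seed): per-component
sub-streams are spawned deterministically from the master seed, so any
component can be regenerated independently and repeat calls are
byte-identical.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .data_io import (
    ConnectivityVector,
    DatasetBundle,
    FeatureTable,
    GenePairRecord,
    NetworkView,
    SLScreen,
    build_bundle,
    canonical_pair,
    compute_connectivity,
    label_pairs,
    write_feature_table,
    write_network,
    write_screen,
)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic benchmark.

    feature_signal is the fraction of each feature's standard deviation
    carried by the connectivity signal; the resulting population correlation
    with standardized log(1+degree) is s / sqrt(s^2 + (1-s)^2).
    """

    n_genes: int = 500
    attachment_m: int = 2
    feature_signal: float = 0.7
    n_features_per_block: int = 10
    network_rewire_prob: float = 0.2
    gi_noise_sd: float = 1.0
    sl_score_mean: float = -5.0
    non_sl_score_mean: float = 0.0
    include_mutation_block: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 1 <= self.attachment_m < self.n_genes:
            raise ConfigError(
                f"need 1 <= attachment_m < n_genes, got m={self.attachment_m}, "
                f"n={self.n_genes}"
            )
        if not (0.0 <= self.feature_signal <= 1.0):
            raise ConfigError("feature_signal must be in [0, 1]")
        if not (0.0 <= self.network_rewire_prob <= 1.0):
            raise ConfigError("network_rewire_prob must be in [0, 1]")
        if self.gi_noise_sd < 0:
            raise ConfigError("gi_noise_sd must be >= 0")
        if self.n_features_per_block < 1:
            raise ConfigError("n_features_per_block must be >= 1")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth behind one benchmark: SL pairs and per-gene connectivity."""

    true_sl_pairs: frozenset[tuple[str, str]]
    true_connectivity: ConnectivityVector
    config: SimConfig

    def __post_init__(self):
        total = int(self.true_connectivity.counts.sum())
        if total != 2 * len(self.true_sl_pairs):
            raise ConfigError(
                "connectivity inconsistent with SL pairs: "
                f"sum={total}, 2|pairs|={2 * len(self.true_sl_pairs)}"
            )

    @property
    def genes(self) -> tuple[str, ...]:
        return self.true_connectivity.genes


def _gene_names(n: int) -> tuple[str, ...]:
    width = max(4, len(str(n - 1)))
    return tuple(f"G{i:0{width}d}" for i in range(n))


def _substream(config: SimConfig, component: int) -> np.random.Generator:
    ss = np.random.SeedSequence(config.seed, spawn_key=(component,))
    return np.random.Generator(np.random.PCG64(ss))


def simulate_sl_graph(config: SimConfig) -> SimTruth:
    """Scale-free true SL graph via Barabasi-Albert preferential attachment.

    Starts from attachment_m connected seed nodes; each new node attaches to
    m existing nodes with probability proportional to current degree, giving
    m * (n - m) edges and a degree tail with power-law exponent ~3.
    """
    rng = _substream(config, 0)
    seed_int = int(rng.integers(0, 2**31 - 1))
    graph = nx.barabasi_albert_graph(config.n_genes, config.attachment_m, seed=seed_int)
    genes = _gene_names(config.n_genes)
    pairs = frozenset(canonical_pair(genes[u], genes[v]) for u, v in graph.edges())
    degree = np.zeros(config.n_genes, dtype=int)
    for u, v in graph.edges():
        degree[u] += 1
        degree[v] += 1
    return SimTruth(pairs, ConnectivityVector(genes, degree), config)


def simulate_gi_scores(truth: SimTruth, config: SimConfig) -> SLScreen:
    """GI scores for every unordered gene pair, labeled at the -3 threshold.

    True SL pairs draw from Normal(sl_score_mean, sd), non-SL pairs from
    Normal(non_sl_score_mean, sd); with the defaults (-5 vs 0) and sd=1 the
    per-pair flip probability at threshold -3 is Phi(-2) for each class.
    """
    rng = _substream(config, 1)
    genes = truth.genes
    pairs = list(itertools.combinations(genes, 2))
    is_sl = np.array([p in truth.true_sl_pairs for p in pairs])
    noise = rng.normal(0.0, config.gi_noise_sd, size=len(pairs))
    scores = np.where(is_sl, config.sl_score_mean, config.non_sl_score_mean) + noise
    records = tuple(
        GenePairRecord(a, b, float(s)) for (a, b), s in zip(pairs, scores)
    )
    screen = SLScreen(f"sim-seed{config.seed}", records, genes)
    return label_pairs(screen)


def _signal_vector(truth: SimTruth) -> np.ndarray:
    """Standardized log(1 + connectivity) — the latent driving all features."""
    z = np.log1p(truth.true_connectivity.counts.astype(float))
    sd = z.std()
    return (z - z.mean()) / (sd if sd > 0 else 1.0)


def simulate_features(truth: SimTruth, config: SimConfig) -> list[FeatureTable]:
    """Connectivity-coupled feature blocks.

    Each column is feature_signal * standardized log(1+connectivity) plus
    (1 - feature_signal) * independent N(0,1) noise.  Default blocks: one
    population-scope table (expression-like) and one cell-specific table;
    optionally a mutation block of sparse nonnegative counts obtained by
    Poisson-thinning the continuous latent.
    """
    rng = _substream(config, 2)
    z = _signal_vector(truth)
    s = config.feature_signal
    k = config.n_features_per_block

    def block() -> np.ndarray:
        noise = rng.normal(size=(len(z), k))
        return s * z[:, None] + (1.0 - s) * noise

    tables = [
        FeatureTable(truth.genes, tuple(f"expr_{j}" for j in range(k)),
                     block(), scope="population", modality="expression"),
        FeatureTable(truth.genes, tuple(f"ess_{j}" for j in range(k)),
                     block(), scope="cell_specific", modality="essentiality"),
    ]
    if config.include_mutation_block:
        latent = block()
        # Poisson thinning of the continuous latent: mean exp(-1) keeps
        # counts sparse and nonnegative
        counts = rng.poisson(np.exp(np.clip(latent, -10.0, 3.0) - 1.0))
        tables.append(
            FeatureTable(truth.genes, tuple(f"mut_{j}" for j in range(k)),
                         counts.astype(float), scope="cell_specific",
                         modality="mutation")
        )
    return tables


def _rewire_edges(
    edges: frozenset[tuple[str, str]],
    genes: tuple[str, ...],
    prob: float,
    rng: np.random.Generator,
) -> frozenset[tuple[str, str]]:
    """Replace each edge, independently with probability prob, by a uniform
    random non-edge.  Edge count is preserved exactly."""
    current = set(edges)
    n = len(genes)
    for edge in sorted(edges):
        if rng.random() >= prob:
            continue
        while True:
            i, j = rng.integers(0, n, size=2)
            if i == j:
                continue
            candidate = canonical_pair(genes[i], genes[j])
            if candidate not in current:
                break
        current.discard(edge)
        current.add(candidate)
    return frozenset(current)


def simulate_network_views(truth: SimTruth, config: SimConfig) -> list[NetworkView]:
    """Three network views, each an independently rewired copy of the SL graph."""
    rng = _substream(config, 3)
    genes = truth.genes
    views = []
    for name in ("ppi_physical", "ppi_genetic", "pathway"):
        edges = _rewire_edges(truth.true_sl_pairs, genes,
                              config.network_rewire_prob, rng)
        views.append(NetworkView(name, edges, frozenset(genes)))
    return views


def make_benchmark(config: SimConfig) -> tuple[DatasetBundle, SimTruth]:
    """Compose graph, screen, features and views into a ready-to-train bundle."""
    truth = simulate_sl_graph(config)
    screen = simulate_gi_scores(truth, config)
    features = simulate_features(truth, config)
    networks = simulate_network_views(truth, config)
    bundle = build_bundle(screen, features, networks)
    bundle.connectivity = compute_connectivity(screen)
    return bundle, truth


def write_benchmark(bundle: DatasetBundle, truth: SimTruth, out_dir) -> None:
    """Serialize a benchmark in the standard TSV dialects plus truth files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_screen(bundle.screen, out / "screen.tsv")
    for i, table in enumerate(bundle.features):
        write_feature_table(table, out / f"features_{i}_{table.scope}.tsv")
    for view in bundle.networks:
        write_network(view, out / f"network_{view.name}.tsv")
    with open(out / "truth_sl_pairs.tsv", "w", encoding="utf-8") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in sorted(truth.true_sl_pairs):
            fh.write(f"{a}\t{b}\n")
    with open(out / "truth_connectivity.tsv", "w", encoding="utf-8") as fh:
        fh.write("gene\tconnectivity\n")
        for g, c in zip(truth.genes, truth.true_connectivity.counts):
            fh.write(f"{g}\t{int(c)}\n")
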