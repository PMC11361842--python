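"""Screen, feature, network and pathway I/O plus label/connectivity derivation.

The supervision source is a CRISPR double-knockout (CDKO) screen: a table of
gene pairs with genetic-interaction (GI) scores for one cell line.  Strongly
negative GI scores indicate synthetic lethality (SL); pairs are labeled SL
when their score falls strictly below a threshold (default -3, the screen
convention this package follows).  A gene's *SL connectivity* is its number
of labeled SL partners — the scalable per-gene quantity the two-step model
regresses first.

All tabular formats are plain TSV with a header, UTF-8, case-sensitive gene
symbols.  Unordered gene pairs are canonicalized to (min, max) under
lexicographic order everywhere, so every downstream operation is invariant
to the order genes appear within a pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

SL_THRESHOLD_DEFAULT = -3.0

FEATURE_SCOPES = ("population", "cell_specific")
FEATURE_MODALITIES = ("expression", "essentiality", "cnv", "mutation", "other")
NETWORK_NAMES = ("ppi_physical", "ppi_genetic", "pathway", "other")


class FormatError(ValueError):
    """A file does not conform to the expected TSV dialect."""


class IntegrityError(ValueError):
    """Contents violate a data invariant (e.g. conflicting duplicate pairs)."""


class StateError(RuntimeError):
    """An operation was called before its prerequisite state exists."""


def canonical_pair(gene_a: str, gene_b: str) -> tuple[str, str]:
    """Return the unordered pair as (min, max); reject self-pairs."""
    if gene_a == gene_b:
        raise IntegrityError(f"self-pair not allowed: {gene_a!r}")
    return (gene_a, gene_b) if gene_a < gene_b else (gene_b, gene_a)


@dataclass(frozen=True)
class GenePairRecord:
    """One screened gene pair: GI score plus (optional) SL label."""

    gene_a: str
    gene_b: str
    gi_score: float
    sl_label: Optional[int] = None

    def __post_init__(self):
        a, b = canonical_pair(self.gene_a, self.gene_b)
        object.__setattr__(self, "gene_a", a)
        object.__setattr__(self, "gene_b", b)
        if self.sl_label is not None and self.sl_label not in (0, 1):
            raise IntegrityError(f"sl_label must be 0/1, got {self.sl_label!r}")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


@dataclass(frozen=True)
class SLScreen:
    """A labeled or unlabeled CDKO screen for one cell line."""

    cell_line: str
    records: tuple[GenePairRecord, ...]
    gene_universe: tuple[str, ...]

    def __post_init__(self):
        universe = set(self.gene_universe)
        pairs = set()
        for r in self.records:
            if r.gene_a not in universe or r.gene_b not in universe:
                raise IntegrityError(
                    f"record genes {r.pair} not all in gene_universe"
                )
            if r.pair in pairs:
                raise IntegrityError(f"duplicate unordered pair {r.pair}")
            pairs.add(r.pair)

    @property
    def is_labeled(self) -> bool:
        return all(r.sl_label is not None for r in self.records)

    @property
    def pair_set(self) -> frozenset[tuple[str, str]]:
        return frozenset(r.pair for r in self.records)

    @property
    def sl_pairs(self) -> frozenset[tuple[str, str]]:
        return frozenset(r.pair for r in self.records if r.sl_label == 1)

    @property
    def prevalence(self) -> float:
        if not self.records:
            return 0.0
        return sum(r.sl_label == 1 for r in self.records) / len(self.records)

    def labels_for(self, pairs: Sequence[tuple[str, str]]) -> np.ndarray:
        by_pair = {r.pair: r.sl_label for r in self.records}
        return np.array([by_pair[canonical_pair(*p)] for p in pairs], dtype=int)


@dataclass(frozen=True)
class FeatureTable:
    """Genes x features real matrix with a scope and modality tag.

    scope: "population" (profiles across cell lines) or "cell_specific".
    Mutation-modality tables hold nonnegative integer mutation counts.
    """

    genes: tuple[str, ...]
    feature_names: tuple[str, ...]
    values: np.ndarray
    scope: str
    modality: str = "other"

    def __post_init__(self):
        if self.scope not in FEATURE_SCOPES:
            raise IntegrityError(f"unknown scope {self.scope!r}")
        if self.modality not in FEATURE_MODALITIES:
            raise IntegrityError(f"unknown modality {self.modality!r}")
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(self.genes), len(self.feature_names)):
            raise IntegrityError(
                f"values shape {vals.shape} != "
                f"({len(self.genes)}, {len(self.feature_names)})"
            )
        object.__setattr__(self, "values", vals)
        if self.modality == "mutation":
            observed = vals[~np.isnan(vals)]
            if observed.size and (
                (observed < 0).any() or (observed != np.round(observed)).any()
            ):
                raise IntegrityError(
                    "mutation modality requires nonnegative integer counts"
                )


@dataclass(frozen=True)
class NetworkView:
    """An undirected biological network: unordered edges over gene symbols."""

    name: str
    edges: frozenset[tuple[str, str]]
    node_set: frozenset[str]

    def __post_init__(self):
        if self.name not in NETWORK_NAMES:
            raise IntegrityError(f"unknown network name {self.name!r}")
        edges = frozenset(canonical_pair(*e) for e in self.edges)
        object.__setattr__(self, "edges", edges)
        endpoints = {g for e in edges for g in e}
        if not endpoints <= self.node_set:
            raise IntegrityError("node_set must contain all edge endpoints")

    def degree(self, gene: str) -> int:
        return sum(gene in e for e in self.edges)


@dataclass(frozen=True)
class ConnectivityVector:
    """Per-gene count of SL partners (the step-1 regression target)."""

    genes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.genes),):
            raise IntegrityError("counts length must match genes")
        if (counts < 0).any():
            raise IntegrityError("connectivity counts must be nonnegative")
        object.__setattr__(self, "counts", counts.astype(int))

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.genes, self.counts.tolist()))


@dataclass
class DatasetBundle:
    """Aligned gene universe + features + networks + screen.

    Everything is re-indexed to the screen's ordered gene universe: feature
    tables gain NaN rows for missing genes (imputed at standardization time),
    network views keep only edges among universe genes, and genes absent from
    a view become isolated nodes.
    """

    screen: SLScreen
    features: list[FeatureTable]
    networks: list[NetworkView]
    connectivity: Optional[ConnectivityVector] = None

    @property
    def genes(self) -> tuple[str, ...]:
        return self.screen.gene_universe


# ---------------------------------------------------------------------------
# Screen I/O and derivations
# ---------------------------------------------------------------------------

def _read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    df.columns = [c.strip() for c in df.columns]
    return df


def load_screen(path, cell_line: str) -> SLScreen:
    """Read a GI-score table (TSV/CSV: gene_a, gene_b, gi_score[, sl_label]).

    Duplicate unordered pairs with identical scores collapse to one record;
    conflicting duplicate scores are an integrity error.
    """
    df = _read_table(path)
    required = {"gene_a", "gene_b", "gi_score"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"missing required columns: {sorted(missing)}")
    has_label = "sl_label" in df.columns
    seen: dict[tuple[str, str], GenePairRecord] = {}
    for row in df.itertuples(index=False):
        score = float(getattr(row, "gi_score"))
        label = None
        if has_label:
            raw = getattr(row, "sl_label")
            label = None if (raw is None or raw != raw) else int(float(raw))
        pair = canonical_pair(str(row.gene_a), str(row.gene_b))
        rec = GenePairRecord(pair[0], pair[1], score, label)
        prev = seen.get(pair)
        if prev is not None:
            if prev.gi_score != rec.gi_score or prev.sl_label != rec.sl_label:
                raise IntegrityError(
                    f"conflicting duplicate records for pair {pair}: "
                    f"gi_score {prev.gi_score} vs {rec.gi_score}"
                )
            continue
        seen[pair] = rec
    universe = tuple(sorted({g for p in seen for g in p}))
    return SLScreen(cell_line, tuple(seen.values()), universe)


def write_screen(screen: SLScreen, path) -> None:
    """Write a screen back out in the canonical TSV dialect (sorted pairs)."""
    rows = sorted(screen.records, key=lambda r: r.pair)
    labeled = screen.is_labeled and screen.records
    with open(path, "w", encoding="utf-8") as fh:
        cols = ["gene_a", "gene_b", "gi_score"] + (["sl_label"] if labeled else [])
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            out = [r.gene_a, r.gene_b, repr(float(r.gi_score))]
            if labeled:
                out.append(str(r.sl_label))
            fh.write("\t".join(out) + "\n")


def label_pairs(screen: SLScreen, threshold: float = SL_THRESHOLD_DEFAULT) -> SLScreen:
    """Label records SL (1) iff gi_score < threshold, strictly; else 0.

    A score exactly at the threshold is non-SL.  Idempotent, and lowering the
    threshold can only remove SL labels.
    """
    records = tuple(
        replace(r, sl_label=int(r.gi_score < threshold)) for r in screen.records
    )
    return replace(screen, records=records)


def compute_connectivity(
    screen: SLScreen,
    restrict_to_pairs: Optional[Iterable[tuple[str, str]]] = None,
) -> ConnectivityVector:
    """Count each gene's SL partners; genes with none get 0.

    Conservation: sum of counts == 2 x (number of SL pairs counted).
    """
    if not screen.is_labeled:
        raise StateError("screen must be labeled before computing connectivity")
    allowed = None
    if restrict_to_pairs is not None:
        allowed = {canonical_pair(*p) for p in restrict_to_pairs}
    counts = dict.fromkeys(screen.gene_universe, 0)
    for r in screen.records:
        if r.sl_label != 1:
            continue
        if allowed is not None and r.pair not in allowed:
            continue
        counts[r.gene_a] += 1
        counts[r.gene_b] += 1
    genes = screen.gene_universe
    return ConnectivityVector(genes, np.array([counts[g] for g in genes]))


# ---------------------------------------------------------------------------
# Network operations
# ---------------------------------------------------------------------------

def filter_network_to_cell(network: NetworkView, expressed_genes: Iterable[str]) -> NetworkView:
    """Drop nodes not expressed in the cell line, and edges touching them."""
    expressed = set(expressed_genes)
    if not expressed:
        raise ValueError("expressed_genes must be nonempty")
    nodes = frozenset(network.node_set & expressed)
    edges = frozenset(e for e in network.edges if e[0] in nodes and e[1] in nodes)
    if not nodes:
        warnings.warn(
            f"network {network.name!r} is empty after cell-line filtering",
            stacklevel=2,
        )
    return NetworkView(network.name, edges, nodes)


def remove_leakage_edges(network: NetworkView, screen: SLScreen) -> NetworkView:
    """Remove every screened pair from the network (idempotent).

    Applied to genetic-interaction views so the encoder never sees the very
    pairs the screen will be used to supervise or evaluate.
    """
    screened = screen.pair_set
    edges = frozenset(e for e in network.edges if e not in screened)
    return replace(network, edges=edges)


def load_network(path, name: str) -> NetworkView:
    """Read an undirected TSV edge list with columns gene_a, gene_b."""
    df = _read_table(path)
    missing = {"gene_a", "gene_b"} - set(df.columns)
    if missing:
        raise FormatError(f"missing required columns: {sorted(missing)}")
    edges = frozenset(
        canonical_pair(str(a), str(b)) for a, b in zip(df["gene_a"], df["gene_b"])
    )
    nodes = frozenset(g for e in edges for g in e)
    return NetworkView(name, edges, nodes)


def write_network(network: NetworkView, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in sorted(network.edges):
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# Feature tables and pathway maps
# ---------------------------------------------------------------------------

def load_feature_table(path, scope: str, modality: str = "other") -> FeatureTable:
    """Read a TSV feature matrix: first column `gene`, rest named features."""
    df = _read_table(path)
    if "gene" not in df.columns:
        raise FormatError("feature table must have a leading `gene` column")
    genes = tuple(df["gene"].astype(str))
    feats = tuple(c for c in df.columns if c != "gene")
    values = df[list(feats)].astype(float).to_numpy()
    return FeatureTable(genes, feats, values, scope=scope, modality=modality)


def write_feature_table(table: FeatureTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\t" + "\t".join(table.feature_names) + "\n")
        for g, row in zip(table.genes, table.values):
            fh.write(g + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def load_pathway_map(path) -> dict[str, str]:
    """Read a TSV `gene  pathway` map; first mapping wins for multi-membership."""
    df = _read_table(path)
    missing = {"gene", "pathway"} - set(df.columns)
    if missing:
        raise FormatError(f"missing required columns: {sorted(missing)}")
    mapping: dict[str, str] = {}
    dupes = set()
    for g, p in zip(df["gene"].astype(str), df["pathway"].astype(str)):
        if g in mapping:
            if mapping[g] != p:
                dupes.add(g)
            continue
        mapping[g] = p
    if dupes:
        warnings.warn(
            f"genes with multiple pathway annotations (first mapping kept): "
            f"{sorted(dupes)}",
            stacklevel=2,
        )
    return mapping


# ---------------------------------------------------------------------------
# Bundle assembly and feature standardization
# ---------------------------------------------------------------------------

def _reindex_features(table: FeatureTable, genes: tuple[str, ...]) -> FeatureTable:
    idx = {g: i for i, g in enumerate(table.genes)}
    values = np.full((len(genes), len(table.feature_names)), np.nan)
    for j, g in enumerate(genes):
        if g in idx:
            values[j] = table.values[idx[g]]
    return replace(table, genes=genes, values=values)


def _reindex_network(view: NetworkView, genes: tuple[str, ...]) -> NetworkView:
    universe = frozenset(genes)
    edges = frozenset(
        e for e in view.edges if e[0] in universe and e[1] in universe
    )
    return NetworkView(view.name, edges, universe)


def build_bundle(
    screen: SLScreen,
    features: Sequence[FeatureTable],
    networks: Sequence[NetworkView],
) -> DatasetBundle:
    """Re-index all components onto the screen's ordered gene universe."""
    genes = screen.gene_universe
    return DatasetBundle(
        screen=screen,
        features=[_reindex_features(t, genes) for t in features],
        networks=[_reindex_network(v, genes) for v in networks],
    )


def standardize_features(
    table: FeatureTable, train_genes: Iterable[str]
) -> FeatureTable:
    """Median-impute then z-score each feature using training-gene statistics.

    Statistics come from the training genes only, so held-out genes never
    influence the scaling (split-leakage control).  Constant features map
    to zero.
    """
    train = set(train_genes)
    mask = np.array([g in train for g in table.genes])
    if not mask.any():
        raise StateError("no training genes present in feature table")
    values = table.values.copy()
    tr = values[mask]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        med = np.nanmedian(tr, axis=0)
    med = np.where(np.isnan(med), 0.0, med)
    nan_rows = np.isnan(values)
    values[nan_rows] = np.broadcast_to(med, values.shape)[nan_rows]
    mu = values[mask].mean(axis=0)
    sd = values[mask].std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return replace(table, values=(values - mu) / sd, modality="other")
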