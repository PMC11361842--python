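"""CDKO screen analytics: SL rates, screen comparison, stratified reports,
hub genes, and predicted-vs-validated connectivity correlation.

These are the validation-side computations for a model-guided screen: how
often selected pairs validate as SL, whether a guided screen is enriched
over an unguided one (2x2 chi-square), how prediction quality breaks down by
pathway-pair stratum, and whether the predicted SL network's hub genes and
connectivities agree with the validated network's.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .data_io import ConnectivityVector, SLScreen
from .evaluation import MetricError, aupr, auc_roc, precision_at_k


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows = screens/conditions, columns = (SL, non-SL) counts."""

    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (2, 2):
            raise ValueError(f"need a 2x2 table, got shape {counts.shape}")
        if (counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if counts.sum() == 0:
            raise ValueError("grand total must be positive")
        object.__setattr__(self, "counts", counts)


@dataclass(frozen=True)
class StratifiedRow:
    """One pathway-pair stratum of a validation screen report."""

    pathway_pair: tuple[str, str]
    predicted_sl: int
    predicted_non_sl: int
    validated_sl: int
    validated_non_sl: int
    precision: Optional[float]
    recall: Optional[float]
    auc_roc: Optional[float]
    aupr: Optional[float]
    precision_at_10: Optional[float]
    sl_ratio: Optional[float]


@dataclass(frozen=True)
class HubReport:
    """Top-connectivity genes, ties broken alphabetically."""

    ranked_genes: tuple[str, ...]
    top_n: int

    @property
    def top_genes(self) -> frozenset[str]:
        return frozenset(self.ranked_genes[: self.top_n])


def sl_rate(validated_sl: int, validated_non_sl: int) -> float:
    """Fraction of validated pairs that are SL."""
    total = validated_sl + validated_non_sl
    if total <= 0:
        raise ValueError("total pair count must be positive")
    if validated_sl < 0 or validated_non_sl < 0:
        raise ValueError("counts must be nonnegative")
    return validated_sl / total


def compare_screens_chi2(
    table: ContingencyTable2x2, yates_correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-square (1 df) comparing SL rates between two screens.

    No continuity correction by default — the motivating comparisons involve
    hundreds of pairs per cell.
    """
    counts = table.counts
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: a row or column total is zero")
    stat, p, dof, _ = stats.chi2_contingency(counts, correction=yates_correction)
    assert dof == 1
    return float(stat), float(p)


def _stratum_metrics(labels: np.ndarray, probs: np.ndarray,
                     pairs: Sequence[tuple[str, str]]) -> dict:
    out: dict[str, Optional[float]] = {}
    for name, fn in (("auc_roc", auc_roc), ("aupr", aupr)):
        try:
            out[name] = fn(labels, probs)
        except MetricError:
            out[name] = None
    try:
        out["precision_at_10"] = precision_at_k(labels, probs, 10.0, tie_key=pairs)
    except (MetricError, ValueError):
        out["precision_at_10"] = None
    return out


def stratified_report(
    screen: SLScreen,
    probabilities: Mapping[tuple[str, str], float],
    pathway_map: Mapping[str, str],
    calls: Optional[Mapping[tuple[str, str], int]] = None,
    call_threshold: float = 0.5,
) -> list[StratifiedRow]:
    """Per pathway-pair stratum: prediction counts, validation counts,
    precision/recall from binary calls, ranking metrics from probabilities.

    A pair's stratum is the unordered pair of its genes' pathways.  Binary
    calls default to probability >= call_threshold.  Undefined metrics
    (single-class or empty strata) are reported as None; the Total row
    aggregates everything.
    """
    if not screen.is_labeled:
        raise ValueError("screen must carry validated SL labels")
    unmapped = sorted(
        {g for r in screen.records for g in r.pair if g not in pathway_map}
    )
    if unmapped:
        raise KeyError(f"genes missing from pathway map: {unmapped}")

    strata: dict[tuple[str, str], list] = {}
    for r in screen.records:
        pair = r.pair
        prob = probabilities[pair]
        call = (calls[pair] if calls is not None
                else int(prob >= call_threshold))
        pa, pb = sorted((pathway_map[pair[0]], pathway_map[pair[1]]))
        strata.setdefault((pa, pb), []).append((pair, r.sl_label, prob, call))

    def make_row(key, items) -> StratifiedRow:
        pairs = [it[0] for it in items]
        labels = np.array([it[1] for it in items], dtype=int)
        probs = np.array([it[2] for it in items], dtype=float)
        call_arr = np.array([it[3] for it in items], dtype=int)
        pred_sl = int(call_arr.sum())
        pred_non = len(items) - pred_sl
        val_sl = int(labels.sum())
        val_non = len(items) - val_sl
        tp = int(((call_arr == 1) & (labels == 1)).sum())
        precision = tp / pred_sl if pred_sl > 0 else None
        recall = tp / val_sl if val_sl > 0 else None
        ratio = val_sl / (val_sl + val_non) if (val_sl + val_non) > 0 else None
        m = _stratum_metrics(labels, probs, pairs)
        return StratifiedRow(key, pred_sl, pred_non, val_sl, val_non,
                             precision, recall, m["auc_roc"], m["aupr"],
                             m["precision_at_10"], ratio)

    rows = [make_row(k, v) for k, v in sorted(strata.items())]
    everything = [it for v in strata.values() for it in v]
    rows.append(make_row(("Total", "Total"), everything))
    return rows


def hub_genes(connectivity: ConnectivityVector, top_n: int = 10) -> HubReport:
    """Rank genes by connectivity descending, ties alphabetical; keep top_n."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if (connectivity.counts == 0).all():
        warnings.warn("all connectivities are zero; ranking is alphabetical",
                      stacklevel=2)
    order = sorted(
        range(len(connectivity.genes)),
        key=lambda i: (-int(connectivity.counts[i]), connectivity.genes[i]),
    )
    ranked = tuple(connectivity.genes[i] for i in order)
    return HubReport(ranked, top_n=min(top_n, len(ranked)))


def hub_overlap(a: HubReport, b: HubReport) -> int:
    """Size of the intersection of two hub reports' top gene sets."""
    return len(a.top_genes & b.top_genes)


def connectivity_correlation(
    predicted: ConnectivityVector,
    validated: ConnectivityVector,
    gene_subset: Optional[Sequence[str]] = None,
) -> tuple[float, float]:
    """Pearson r (two-sided t-test p) between predicted and validated
    connectivity over the shared gene subset."""
    pred = predicted.as_dict()
    val = validated.as_dict()
    subset = sorted(gene_subset) if gene_subset is not None \
        else sorted(set(pred) & set(val))
    missing = [g for g in subset if g not in pred or g not in val]
    if missing:
        raise KeyError(f"genes missing from a connectivity vector: {missing}")
    if len(subset) < 3:
        raise ValueError("need at least 3 genes for a correlation")
    x = np.array([pred[g] for g in subset], dtype=float)
    y = np.array([val[g] for g in subset], dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined: zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
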