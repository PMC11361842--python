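"""Step 2: logistic regression from pair connectivities to SL probability.

A gene pair's chance of being synthetic lethal rises with how SL-connected
its two genes are.  Each pair is summarized order-invariantly by the sorted
pair of (predicted) connectivities and their product — (c_min, c_max,
c_min*c_max) by default, with sum and |difference| available — standardized
with training-set statistics and fed to an L2-regularized logistic
regression.  Class weighting defaults to balanced because SL prevalence in
real screens is around 0.5-1.5%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression

from .data_io import canonical_pair

PAIR_FEATURES_DEFAULT = ("min", "max", "product")
_FEATURE_FUNCS = {
    "min": lambda lo, hi: lo,
    "max": lambda lo, hi: hi,
    "product": lambda lo, hi: lo * hi,
    "sum": lambda lo, hi: lo + hi,
    "absdiff": lambda lo, hi: hi - lo,
}


class FitError(ValueError):
    """Classifier cannot be fitted (e.g. a class is absent)."""


@dataclass(frozen=True)
class PairFeatureVector:
    """Order-invariant summary of one pair's connectivities."""

    c_min: float
    c_max: float
    c_product: float

    def __post_init__(self):
        if self.c_min > self.c_max:
            raise ValueError("c_min must not exceed c_max")


def pair_features(c_a: float, c_b: float) -> PairFeatureVector:
    """Symmetrize two connectivities into (min, max, product)."""
    if c_a < 0 or c_b < 0:
        raise ValueError(f"connectivities must be >= 0, got ({c_a}, {c_b})")
    lo, hi = (c_a, c_b) if c_a <= c_b else (c_b, c_a)
    return PairFeatureVector(lo, hi, lo * hi)


def _design_matrix(
    conn_pairs: Sequence[tuple[float, float]],
    feature_set: Sequence[str],
) -> np.ndarray:
    rows = np.empty((len(conn_pairs), len(feature_set)))
    for i, (a, b) in enumerate(conn_pairs):
        if a < 0 or b < 0:
            raise ValueError(f"connectivities must be >= 0, got ({a}, {b})")
        lo, hi = (a, b) if a <= b else (b, a)
        for j, name in enumerate(feature_set):
            rows[i, j] = _FEATURE_FUNCS[name](lo, hi)
    return rows


@dataclass
class SLClassifier:
    """Fitted logistic model over standardized pair features."""

    coefficients: np.ndarray
    intercept: float
    feature_set: tuple[str, ...]
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    class_weighting: str

    def decision_function(self, conn_pairs: Sequence[tuple[float, float]]) -> np.ndarray:
        X = _design_matrix(conn_pairs, self.feature_set)
        X = (X - self.feature_mean) / self.feature_scale
        return X @ self.coefficients + self.intercept

    def predict_proba(self, conn_pairs: Sequence[tuple[float, float]]) -> np.ndarray:
        z = self.decision_function(conn_pairs)
        return 1.0 / (1.0 + np.exp(-z))


def fit_sl_classifier(
    conn_pairs: Sequence[tuple[float, float]],
    labels: Sequence[int],
    weighting: str = "balanced",
    feature_set: Sequence[str] = PAIR_FEATURES_DEFAULT,
    l2_penalty: float = 1e-4,
) -> SLClassifier:
    """Fit the logistic pair classifier on (connectivity_a, connectivity_b)
    tuples and binary SL labels.  Deterministic given inputs.

    l2_penalty is the per-sample ridge strength alpha in the objective
    mean(log-loss) + 0.5 * alpha * ||w||^2, so the fit is invariant to
    duplicating the training data.
    """
    if weighting not in ("balanced", "none"):
        raise ValueError(f"unknown weighting {weighting!r}")
    unknown = set(feature_set) - set(_FEATURE_FUNCS)
    if unknown:
        raise ValueError(f"unknown pair features: {sorted(unknown)}")
    y = np.asarray(labels, dtype=int)
    present = set(np.unique(y).tolist())
    missing = {0, 1} - present
    if missing:
        raise FitError(
            f"labels contain a single class; missing class {sorted(missing)}"
        )
    X = _design_matrix(conn_pairs, feature_set)
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale == 0, 1.0, scale)
    Xs = (X - mean) / scale
    # sklearn minimizes 0.5||w||^2 + C * sum(loss); C = 1/(alpha*n) keeps the
    # per-sample penalty fixed under duplication
    lr = LogisticRegression(
        C=1.0 / (l2_penalty * len(y)),
        class_weight="balanced" if weighting == "balanced" else None,
        solver="lbfgs",
        max_iter=5000,
        tol=1e-10,
    )
    lr.fit(Xs, y)
    return SLClassifier(
        coefficients=lr.coef_[0].copy(),
        intercept=float(lr.intercept_[0]),
        feature_set=tuple(feature_set),
        feature_mean=mean,
        feature_scale=scale,
        class_weighting=weighting,
    )


def predict_sl(
    classifier: SLClassifier,
    pairs: Sequence[tuple[str, str]],
    connectivity_pred: Mapping[str, float],
) -> np.ndarray:
    """SL probability per pair; invariant under endpoint swap."""
    missing = sorted(
        {g for p in pairs for g in p if g not in connectivity_pred}
    )
    if missing:
        raise KeyError(f"genes without connectivity predictions: {missing}")
    conn = [
        (connectivity_pred[a], connectivity_pred[b])
        for a, b in (canonical_pair(*p) for p in pairs)
    ]
    return classifier.predict_proba(conn)
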