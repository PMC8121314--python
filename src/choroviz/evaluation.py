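"""Cross-validated evaluation and paired model comparison.

Stratified 10-fold cross-validation with a shared fold assignment across
models, the metric suite (ROC AUC, accuracy, recall, precision, Cohen's
kappa; asymmetry is the positive class), and a paired two-sided Wilcoxon
signed-rank test on per-fold metrics (exact sign-pattern enumeration up
to n = 15, normal approximation with continuity correction above; zero
differences dropped, ties midranked).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np
from scipy.stats import norm, rankdata
from sklearn.model_selection import KFold, StratifiedKFold

from .models import encode_labels

logger = logging.getLogger(__name__)

METRICS = ("auc", "accuracy", "recall", "precision", "kappa")


@dataclass(frozen=True)
class FoldResult:
    fold_id: int
    test_indices: tuple[int, ...]
    auc: float
    accuracy: float
    recall: float
    precision: float
    kappa: float

    def metric(self, name: str) -> float:
        return getattr(self, name)


@dataclass
class CVSummary:
    folds: dict[str, list[FoldResult]]  # model name -> per-fold results
    pairwise_p: dict[tuple[str, str], dict[str, float]]  # (a, b) -> metric -> p

    def mean_sd(self, model: str, metric: str) -> tuple[float, float]:
        vals = np.array([f.metric(metric) for f in self.folds[model]])
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        return float(vals.mean()), sd

    def summary_table(self) -> "pd.DataFrame":  # noqa: F821
        import pandas as pd

        rows = []
        for model in self.folds:
            row = {"model": model}
            for m in METRICS:
                mean, sd = self.mean_sd(model, m)
                row[m] = mean
                row[f"{m}_sd"] = sd
            rows.append(row)
        return pd.DataFrame(rows)


def stratified_kfold(
    y: Sequence[str] | np.ndarray, k: int = 10, seed: int = 0
) -> list[np.ndarray]:
    """Deterministic stratified fold assignment; returns test-index arrays."""
    yb = y if isinstance(y, np.ndarray) and y.dtype.kind == "i" else encode_labels(y)
    if len(yb) < k:
        raise ValueError(f"n={len(yb)} < k={k}")
    if np.bincount(yb).min() < k:
        logger.warning(
            "a class has fewer than k members; falling back to unstratified folds"
        )
        kf = KFold(n_splits=k, shuffle=True, random_state=seed)
        return [test for _, test in kf.split(np.zeros(len(yb)))]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(len(yb)), yb)]


def roc_auc(scores_asym: np.ndarray, labels: Sequence[str] | np.ndarray) -> float:
    """Trapezoidal/Mann-Whitney AUC with asymmetry positive; ties averaged."""
    yb = (
        labels
        if isinstance(labels, np.ndarray) and labels.dtype.kind == "i"
        else encode_labels(labels)
    )
    pos = np.asarray(scores_asym, float)[yb == 0]  # asymmetric
    neg = np.asarray(scores_asym, float)[yb == 1]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes required for AUC")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def classification_metrics(
    pred: Sequence[str], labels: Sequence[str]
) -> dict[str, float]:
    """Accuracy, recall, precision (positive = asymmetric) and Cohen's kappa."""
    pred = np.asarray(pred)
    labels = np.asarray(labels)
    if pred.shape != labels.shape:
        raise ValueError("pred and labels must have equal length")
    tp = int(np.sum((pred == "asymmetric") & (labels == "asymmetric")))
    tn = int(np.sum((pred == "symmetric") & (labels == "symmetric")))
    fp = int(np.sum((pred == "asymmetric") & (labels == "symmetric")))
    fn = int(np.sum((pred == "symmetric") & (labels == "asymmetric")))
    n = tp + tn + fp + fn
    accuracy = (tp + tn) / n
    recall = tp / (tp + fn) if tp + fn else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    if not tp + fn or not tp + fp:
        logger.warning("zero-denominator recall/precision reported as 0")
    po = accuracy
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / (n * n)
    kappa = (po - pe) / (1.0 - pe) if pe < 1.0 else 1.0
    return {"accuracy": accuracy, "recall": recall, "precision": precision, "kappa": kappa}


def wilcoxon_signed_rank(
    a: Sequence[float], b: Sequence[float]
) -> tuple[float, float]:
    """Paired two-sided Wilcoxon signed-rank test; returns (W, p).

    W is the smaller of the positive/negative rank sums.  Zero
    differences are dropped; tied |differences| get midranks.  The
    two-sided p-value is exact (all 2^n sign patterns) for n <= 15 and
    uses the normal approximation with continuity correction beyond.
    """
    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        logger.warning("all paired differences are zero; p = 1")
        return 0.0, 1.0
    if n < 3:
        logger.warning("fewer than 3 nonzero differences; test has no power")
    ranks = rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    w = min(w_pos, w_neg)
    if n <= 15:
        count = 0
        total = 2**n
        for signs in itertools.product((0, 1), repeat=n):
            wp = sum(r for s, r in zip(signs, ranks) if s)
            if min(wp, ranks.sum() - wp) <= w + 1e-9:
                count += 1
        return w, count / total
    mean = n * (n + 1) / 4.0
    # tie-corrected variance
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    z = (w - mean + 0.5) / math.sqrt(var)
    return w, float(min(1.0, 2.0 * norm.cdf(z)))


class ModelSpec(Protocol):
    """Anything trainable per fold on (features, images, labels)."""

    name: str

    def fit_fold(
        self,
        X: np.ndarray,
        images: Sequence[np.ndarray] | None,
        y: np.ndarray,
        train_idx: np.ndarray,
        seed: int,
    ) -> "FittedFold": ...


class FittedFold(Protocol):
    def score_cs(self, X: np.ndarray, images, idx: np.ndarray) -> np.ndarray: ...


def evaluate_fold(
    cs_test: np.ndarray, labels_test: np.ndarray, fold_id: int, test_idx: np.ndarray
) -> FoldResult:
    """Metrics of one fold from symmetric-confidence scores."""
    scores_asym = 1.0 - cs_test
    pred = np.where(cs_test < 0.5, "asymmetric", "symmetric")
    m = classification_metrics(pred, labels_test)
    auc = roc_auc(scores_asym, labels_test)
    return FoldResult(
        fold_id, tuple(int(i) for i in test_idx), auc,
        m["accuracy"], m["recall"], m["precision"], m["kappa"],
    )


def run_model_comparison(
    X: np.ndarray,
    labels: Sequence[str],
    model_specs: Sequence,
    images: Sequence[np.ndarray] | None = None,
    k: int = 10,
    seed: int = 0,
) -> CVSummary:
    """Shared-fold cross-validated comparison of >= 1 model specs.

    Every model sees the identical fold assignment (required for the
    paired Wilcoxon tests on per-fold AUC and accuracy).
    """
    labels = np.asarray(labels)
    folds = stratified_kfold(labels, k=k, seed=seed)
    all_idx = np.arange(len(labels))
    results: dict[str, list[FoldResult]] = {s.name: [] for s in model_specs}
    for fold_id, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        for spec in model_specs:
            fitted = spec.fit_fold(X, images, labels, train_idx, seed + fold_id)
            cs = fitted.score_cs(X, images, test_idx)
            results[spec.name].append(
                evaluate_fold(cs, labels[test_idx], fold_id, test_idx)
            )
    pairwise: dict[tuple[str, str], dict[str, float]] = {}
    names = [s.name for s in model_specs]
    for a, b in itertools.combinations(names, 2):
        pvals = {}
        for metric in ("auc", "accuracy"):
            va = [f.metric(metric) for f in results[a]]
            vb = [f.metric(metric) for f in results[b]]
            _, p = wilcoxon_signed_rank(va, vb)
            pvals[metric] = p
        pairwise[(a, b)] = pvals
    return CVSummary(results, pairwise)
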