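"""Prediction-rate statistics, ROC/AUC, and the three validation protocols.

Two equivalent parameterizations of binary-classification quality are
provided.  In terms of class totals T+ (secretory) and T- (non-secretory)
with misclassification counts FN (secretory predicted non-secretory) and
FP (the converse):

    Upsilon+ = 1 - FN / T+          (true prediction rate, secretory)
    Upsilon- = 1 - FP / T-          (true prediction rate, non-secretory)
    Upsilon  = 1 - (FN + FP) / (T+ + T-)

and in confusion-matrix terms the familiar Sn, Sp, Acc and Matthews
correlation coefficient.  Acc and Upsilon are the same quantity; the two
MCC parameterizations agree exactly (both identities are asserted by the
test suite over random confusion tables).

Validation protocols: self-consistency (train and test on the full set),
stratified 10-fold cross-validation (the overall accuracy is the average
of the fold outcomes), and the jackknife (leave-one-out, retraining for
every held-out example).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .classifier import NON_SECRETORY, SECRETORY, MLPConfig, MLPModel, predict, train


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN with the positive class = secretory."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP, self.TN + other.TN, self.FP + other.FP, self.FN + other.FN
        )

    @property
    def total_positives(self) -> int:
        return self.TP + self.FN

    @property
    def total_negatives(self) -> int:
        return self.TN + self.FP


@dataclass(frozen=True)
class MetricReport:
    """Sn/Sp/Acc/MCC plus the Upsilon prediction rates (NaN = undefined)."""

    Sn: float
    Sp: float
    Acc: float
    MCC: float
    Upsilon_plus: float
    Upsilon_minus: float
    Upsilon: float

    def rounded(self, ndigits: int = 2) -> "MetricReport":
        """Display rounding (reports print 2 decimals)."""
        return MetricReport(**{k: round(v, ndigits) for k, v in self.__dict__.items()})


def metrics(counts: ConfusionCounts) -> MetricReport:
    """All statistics from one confusion table.

    Sn and Sp require a non-empty positive / negative class respectively;
    MCC requires all four marginals to be non-zero.  Undefined quantities
    are reported as NaN sentinels, everything else is still computed.
    """
    TP, TN, FP, FN = counts.TP, counts.TN, counts.FP, counts.FN
    t_pos = TP + FN
    t_neg = TN + FP
    nan = float("nan")

    sn = TP / t_pos if t_pos > 0 else nan
    sp = TN / t_neg if t_neg > 0 else nan
    total = TP + TN + FP + FN
    acc = (TP + TN) / total if total > 0 else nan

    marginals = [(TP + FP), (FN + TN), (FP + TN), (TP + FN)]
    if all(m > 0 for m in marginals):
        mcc = (TP * TN - FP * FN) / math.sqrt(math.prod(marginals))
    else:
        mcc = nan

    ups_plus = 1.0 - FN / t_pos if t_pos > 0 else nan
    ups_minus = 1.0 - FP / t_neg if t_neg > 0 else nan
    ups = 1.0 - (FN + FP) / total if total > 0 else nan
    return MetricReport(
        Sn=sn, Sp=sp, Acc=acc, MCC=mcc,
        Upsilon_plus=ups_plus, Upsilon_minus=ups_minus, Upsilon=ups,
    )


def mcc_rate_form(counts: ConfusionCounts) -> float:
    """MCC via the prediction-rate parameterization (class totals and errors).

    Algebraically identical to the confusion-matrix form; kept as a
    separate code path so the identity can be machine-checked.
    """
    t_pos = counts.total_positives
    t_neg = counts.total_negatives
    FN, FP = counts.FN, counts.FP
    if t_pos == 0 or t_neg == 0:
        return float("nan")
    numer = 1.0 - (FN / t_pos + FP / t_neg)
    inner = (1.0 + (FP - FN) / t_pos) * (1.0 + (FN - FP) / t_neg)
    if inner <= 0:
        return float("nan")
    return numer / math.sqrt(inner)


def roc(scores: Sequence[float], labels: Sequence[str]) -> Tuple[np.ndarray, float]:
    """ROC curve by threshold sweep and its trapezoidal AUC.

    Returns (curve, auc) where curve is an (m, 2) array of (FPR, TPR)
    points starting at (0, 0) and ending at (1, 1).
    """
    y = np.array([1 if lab == SECRETORY else 0 for lab in labels])
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes")

    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(1 - y_sorted)
    # keep the last index of each distinct threshold
    distinct = np.r_[np.where(np.diff(s_sorted))[0], len(s_sorted) - 1]
    tpr = tps[distinct] / n_pos
    fpr = fps[distinct] / n_neg
    curve = np.column_stack([np.r_[0.0, fpr], np.r_[0.0, tpr]])
    if curve[-1, 0] != 1.0 or curve[-1, 1] != 1.0:
        curve = np.vstack([curve, [1.0, 1.0]])
    auc = float(np.trapezoid(curve[:, 1], curve[:, 0]))
    return curve, auc


@dataclass
class ProtocolResult:
    """Per-fold confusion tables plus pooled and averaged summaries."""

    protocol: str
    fold_counts: List[ConfusionCounts]
    pooled: ConfusionCounts = field(init=False)
    report: MetricReport = field(init=False)
    fold_accuracies: List[float] = field(init=False)
    mean_accuracy: float = field(init=False)

    def __post_init__(self):
        pooled = ConfusionCounts(0, 0, 0, 0)
        for c in self.fold_counts:
            pooled = pooled + c
        self.pooled = pooled
        self.report = metrics(pooled)
        self.fold_accuracies = [metrics(c).Acc for c in self.fold_counts]
        self.mean_accuracy = float(np.mean(self.fold_accuracies))


def _confusion_from_predictions(pred_labels: Sequence[str], true_labels: Sequence[str]) -> ConfusionCounts:
    tp = tn = fp = fn = 0
    for pred, true in zip(pred_labels, true_labels):
        if true == SECRETORY:
            if pred == SECRETORY:
                tp += 1
            else:
                fn += 1
        else:
            if pred == NON_SECRETORY:
                tn += 1
            else:
                fp += 1
    return ConfusionCounts(tp, tn, fp, fn)


def stratified_folds(labels: Sequence[str], k: int, seed: int) -> List[np.ndarray]:
    """Disjoint covering test folds, stratified by class, seeded shuffle."""
    n = len(labels)
    if k > n:
        raise ValueError(f"k={k} exceeds dataset size {n}")
    rng = np.random.default_rng(seed)
    folds: List[List[int]] = [[] for _ in range(k)]
    cursor = 0  # continue round-robin across classes so fold sizes stay even
    for cls in (SECRETORY, NON_SECRETORY):
        idx = [i for i, lab in enumerate(labels) if lab == cls]
        rng.shuffle(idx)
        for i in idx:
            folds[cursor % k].append(i)
            cursor += 1
    return [np.array(sorted(f), dtype=int) for f in folds]


def run_protocol(
    features: np.ndarray,
    labels: Sequence[str],
    protocol: str,
    config: Optional[MLPConfig] = None,
    seed: int = 0,
    k: int = 10,
    fast_approx: bool = False,
) -> ProtocolResult:
    """Run self_consistency, kfold (stratified) or jackknife validation.

    Every fold retrains the classifier from the same seeded config on the
    training portion and evaluates on the held-out portion.  The jackknife
    is leave-one-out; ``fast_approx`` evaluates a single full-data model
    on each left-out item instead of retraining (never used for
    reference numbers, provided for exploration only).
    """
    X = np.asarray(features, dtype=float)
    labels = list(labels)
    if config is None:
        config = MLPConfig(seed=seed)

    if protocol == "self_consistency":
        model = train(X, labels, config)
        preds = [lab for lab, _ in predict(model, X)]
        return ProtocolResult(protocol, [_confusion_from_predictions(preds, labels)])

    if protocol == "kfold":
        folds = stratified_folds(labels, k, seed)
    elif protocol == "jackknife":
        folds = [np.array([i]) for i in range(len(labels))]
        if fast_approx:
            model = train(X, labels, config)
            preds = [lab for lab, _ in predict(model, X)]
            counts = [
                _confusion_from_predictions([preds[i]], [labels[i]]) for i in range(len(labels))
            ]
            return ProtocolResult("jackknife(fast_approx)", counts)
    else:
        raise ValueError(f"unknown protocol: {protocol!r}")

    all_idx = np.arange(len(labels))
    fold_counts = []
    # every fold retrains from the same seeded init, so the partition alone
    # determines the outcome (and kfold with k=n coincides with the jackknife)
    for test_idx in folds:
        train_idx = np.setdiff1d(all_idx, test_idx)
        train_labels = [labels[i] for i in train_idx]
        model = train(X[train_idx], train_labels, config)
        preds = [lab for lab, _ in predict(model, X[test_idx])]
        fold_counts.append(
            _confusion_from_predictions(preds, [labels[i] for i in test_idx])
        )
    return ProtocolResult(protocol, fold_counts)
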