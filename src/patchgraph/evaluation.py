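"""Classification metrics and the stratified cross-validation harness.

Multi-class performance is reported one-vs-rest per class: precision,
recall (sensitivity), specificity, plus overall accuracy, and ROC / PR curves
with their areas.  ROC AUC uses trapezoidal integration (equivalent to the
rank statistic with midpoint tie handling); PR AUC uses the conservative
step interpolation.  Cross-validation is stratified by slide label with
reproducible fold assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import auc, average_precision_score, precision_recall_curve, roc_curve
from sklearn.model_selection import StratifiedKFold

__all__ = ["EvalReport", "confusion_metrics", "roc_pr_curves", "evaluate_model",
           "cross_validate", "aggregate_reports"]


@dataclass
class EvalReport:
    accuracy: float
    precision: dict[int, float]
    recall: dict[int, float]
    specificity: dict[int, float]
    auc_roc: dict[int, float] = field(default_factory=dict)
    auc_pr: dict[int, float] = field(default_factory=dict)
    roc_points: dict[int, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    pr_points: dict[int, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def summary(self) -> dict:
        out = {"accuracy": self.accuracy}
        for c in self.precision:
            out[f"precision_{c}"] = self.precision[c]
            out[f"recall_{c}"] = self.recall[c]
            out[f"specificity_{c}"] = self.specificity[c]
        for c, v in self.auc_roc.items():
            out[f"auc_roc_{c}"] = v
        for c, v in self.auc_pr.items():
            out[f"auc_pr_{c}"] = v
        return out


def confusion_metrics(y_true, y_pred, n_classes: int) -> EvalReport:
    """One-vs-rest precision/recall/specificity per class plus accuracy.

    Degenerate denominators (e.g. no predicted positives) yield 0 with a
    warning rather than an error.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size and (y_true.min() < 0 or max(y_true.max(), y_pred.max()) >= n_classes):
        raise ValueError("labels out of range")
    precision, recall, specificity = {}, {}, {}
    for c in range(n_classes):
        tp = int(np.sum((y_pred == c) & (y_true == c)))
        fp = int(np.sum((y_pred == c) & (y_true != c)))
        fn = int(np.sum((y_pred != c) & (y_true == c)))
        tn = int(np.sum((y_pred != c) & (y_true != c)))

        def rate(num, den, name):
            if den == 0:
                warnings.warn(f"{name} undefined for class {c}: 0/0 -> 0", stacklevel=3)
                return 0.0
            return num / den

        precision[c] = rate(tp, tp + fp, "precision")
        recall[c] = rate(tp, tp + fn, "recall")
        specificity[c] = rate(tn, tn + fp, "specificity")
    accuracy = float(np.mean(y_true == y_pred)) if y_true.size else 0.0
    return EvalReport(accuracy=accuracy, precision=precision, recall=recall,
                      specificity=specificity)


def roc_pr_curves(y_true, scores) -> dict:
    """One-vs-rest ROC and PR curves with AUCs from per-class probabilities.

    Returns ``{class: {"roc": (fpr, tpr), "auc_roc": ..., "pr":
    (recall, precision), "auc_pr": ...}}``; classes absent from ``y_true``
    are skipped with a warning.
    """
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[0] != y_true.shape[0]:
        raise ValueError("scores must be (n_samples, n_classes)")
    out = {}
    for c in range(scores.shape[1]):
        pos = y_true == c
        if not pos.any() or pos.all():
            warnings.warn(f"class {c} absent from one side of y_true; curves skipped",
                          stacklevel=2)
            continue
        fpr, tpr, _ = roc_curve(pos.astype(int), scores[:, c])
        rec_prec = precision_recall_curve(pos.astype(int), scores[:, c])
        precision_c, recall_c = rec_prec[0], rec_prec[1]
        out[c] = {
            "roc": (fpr, tpr),
            "auc_roc": float(auc(fpr, tpr)),
            "pr": (recall_c, precision_c),
            "auc_pr": float(average_precision_score(pos.astype(int), scores[:, c])),
        }
    return out


def evaluate_model(model, graphs, labels) -> EvalReport:
    """Forward every graph, then metrics + curves in one report."""
    labels = np.asarray(labels, dtype=int)
    probs = np.stack([model.predict_proba(g) for g in graphs])
    preds = probs.argmax(axis=1)
    report = confusion_metrics(labels, preds, model.config.n_classes)
    curves = roc_pr_curves(labels, probs)
    for c, d in curves.items():
        report.auc_roc[c] = d["auc_roc"]
        report.auc_pr[c] = d["auc_pr"]
        report.roc_points[c] = d["roc"]
        report.pr_points[c] = d["pr"]
    return report


def cross_validate(graphs, labels, config, n_folds: int = 5, seed: int = 0,
                   train_fn=None) -> tuple[list[EvalReport], dict]:
    """Stratified k-fold train/evaluate; returns per-fold reports + aggregate.

    ``train_fn(graphs, labels, config)`` may be injected (defaults to
    :func:`patchgraph.gtp_model.train`); it must return an object with a
    ``model`` attribute.
    """
    from dataclasses import replace

    from .gtp_model import train as _train

    labels = np.asarray(labels, dtype=int)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    counts = np.bincount(labels)
    if (counts[counts > 0] < n_folds).any():
        raise ValueError(
            f"some class has fewer than {n_folds} members; reduce n_folds"
        )
    train_fn = train_fn or (lambda g, y, c: _train(g, y, c))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    reports = []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        cfg = replace(config, seed=config.seed + fold) if hasattr(config, "seed") else config
        result = train_fn([graphs[i] for i in tr], labels[tr], cfg)
        reports.append(evaluate_model(result.model, [graphs[i] for i in te], labels[te]))
    return reports, aggregate_reports(reports)


def aggregate_reports(reports: list[EvalReport]) -> dict:
    """Mean ± SD of every scalar metric across folds."""
    keys = set()
    for r in reports:
        keys.update(r.summary().keys())
    agg = {}
    for k in sorted(keys):
        vals = [r.summary()[k] for r in reports if k in r.summary()]
        agg[k] = {"mean": float(np.mean(vals)), "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0}
    return agg
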