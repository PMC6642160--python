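"""Decision-DAG SVM multiclass classification and its metric panel.

An N-class problem is decomposed into N(N-1)/2 linear soft-margin binary
SVMs, one per unordered class pair, trained only on the samples of those
two classes.  Prediction walks a directed acyclic elimination path: keep a
candidate list (the ordered classes), repeatedly evaluate the classifier
for the (first, last) pair and drop the losing class — exactly N-1
evaluations, returning the sole survivor.  This decomposition lets each
node focus on one pairwise discrimination and is robust to class imbalance.

The metric panel mirrors standard multiclass reporting: accuracy, per-class
and macro precision/recall, Cohen's kappa, micro/macro one-vs-rest AUC and
the confusion matrix.  AUC here is the rank-based (Mann-Whitney)
formulation with ties counted half; kappa and AUC are implemented directly
so they can be verified against brute-force pair counting.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import rankdata
from sklearn.svm import SVC

__all__ = ["DagSvmModel", "MetricPanel", "train_dagsvm", "predict_dag",
           "decision_scores", "cohens_kappa", "roc_auc", "multiclass_auc",
           "confusion_matrix", "metric_panel"]


@dataclass
class DagSvmModel:
    """Ordered classes plus one linear classifier per unordered pair.

    For pair ``(i, j)`` with ``i < j`` in class order, ``w . x + b > 0``
    votes for class ``classes[i]``.
    """

    classes: list
    weights: dict[tuple[int, int], np.ndarray]
    biases: dict[tuple[int, int], float]
    dim: int

    @property
    def n_classifiers(self) -> int:
        return len(self.weights)

    def margin(self, i: int, j: int, x: np.ndarray) -> float:
        return float(self.weights[(i, j)] @ x + self.biases[(i, j)])

    # -- persistence -----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        doc = {
            "classes": [c.item() if hasattr(c, "item") else c
                        for c in self.classes],
            "dim": self.dim,
            "pairs": [
                {"i": i, "j": j, "w": self.weights[(i, j)].tolist(),
                 "b": self.biases[(i, j)]}
                for (i, j) in sorted(self.weights)
            ],
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path: str | Path) -> "DagSvmModel":
        doc = json.loads(Path(path).read_text())
        weights = {(p["i"], p["j"]): np.asarray(p["w"]) for p in doc["pairs"]}
        biases = {(p["i"], p["j"]): float(p["b"]) for p in doc["pairs"]}
        return cls(doc["classes"], weights, biases, doc["dim"])


def train_dagsvm(X: np.ndarray, y, C: float = 1.0,
                 class_order: list | None = None) -> DagSvmModel:
    """Fit one linear soft-margin SVM per class pair on the embeddings.

    ``class_order`` fixes the DAG node ordering (default: sorted labels).
    Each pairwise classifier is fit only on the samples of its two classes.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes = class_order if class_order is not None else sorted(set(y))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    for c in classes:
        if int(np.sum(y == c)) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
    weights, biases = {}, {}
    for i in range(len(classes)):
        for j in range(i + 1, len(classes)):
            sel = (y == classes[i]) | (y == classes[j])
            svc = SVC(kernel="linear", C=C).fit(X[sel], y[sel])
            w = svc.coef_[0].copy()
            b = float(svc.intercept_[0])
            # libsvm's decision_function > 0 favors svc.classes_[1];
            # flip so that > 0 always votes for classes[i]
            if svc.classes_[1] != classes[i]:
                w, b = -w, -b
            weights[(i, j)] = w
            biases[(i, j)] = b
    return DagSvmModel(list(classes), weights, biases, X.shape[1])


def predict_dag(model: DagSvmModel, x: np.ndarray,
                return_trace: bool = False):
    """Classify one embedding by DAG elimination.

    Exactly N-1 pairwise evaluations; a zero margin (tie) eliminates the
    higher-indexed class.  With ``return_trace=True`` also returns the list
    of (class_i, class_j) pairs consulted, in order.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    if x.shape[0] != model.dim:
        raise ValueError(f"embedding dim {x.shape[0]} != model dim {model.dim}")
    candidates = list(range(len(model.classes)))
    trace = []
    n_evals = 0
    while len(candidates) > 1:
        i, j = candidates[0], candidates[-1]
        m = model.margin(i, j, x)
        n_evals += 1
        trace.append((model.classes[i], model.classes[j]))
        if m < 0:
            candidates.pop(0)      # i loses
        else:
            candidates.pop()       # j loses; ties eliminate the higher index
    assert n_evals == len(model.classes) - 1
    label = model.classes[candidates[0]]
    return (label, trace) if return_trace else label


def predict_dag_batch(model: DagSvmModel, X: np.ndarray) -> np.ndarray:
    return np.asarray([predict_dag(model, x) for x in np.asarray(X)])


def decision_scores(model: DagSvmModel, X: np.ndarray) -> np.ndarray:
    """Per-class scores by one-vs-one signed-margin voting.

    A DAG emits only a label; for threshold metrics (AUC) each class is
    scored by the sum of its signed pairwise margins.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    scores = np.zeros((X.shape[0], len(model.classes)))
    for (i, j), w in model.weights.items():
        m = X @ w + model.biases[(i, j)]
        scores[:, i] += m
        scores[:, j] -= m
    return scores


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def confusion_matrix(y_true, y_pred, classes: list | None = None) -> np.ndarray:
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if classes is None:
        classes = sorted(set(y_true) | set(y_pred))
    index = {c: k for k, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        cm[index[t], index[p]] += 1
    return cm


def cohens_kappa(confusion: np.ndarray) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    ``p_o`` is the observed agreement (trace / n); ``p_e`` the agreement
    expected from the row/column marginals.  Returns NaN when ``p_e == 1``
    (degenerate single-cell matrix).
    """
    cm = np.asarray(confusion, dtype=np.float64)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    n = cm.sum()
    if n <= 0 or (cm < 0).any():
        raise ValueError("confusion matrix must be nonnegative with sum > 0")
    p_o = np.trace(cm) / n
    p_e = float(cm.sum(axis=1) @ cm.sum(axis=0)) / n**2
    if abs(1.0 - p_e) < 1e-12:
        return float("nan")
    return float((p_o - p_e) / (1.0 - p_e))


def roc_auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC with ties counted half."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


def multiclass_auc(scores: np.ndarray, y_true, classes: list) -> dict[str, float]:
    """Micro and macro one-vs-rest AUC from a per-class score matrix."""
    scores = np.asarray(scores, dtype=np.float64)
    y_true = np.asarray(y_true)
    per_class, pooled_s, pooled_l = {}, [], []
    for k, c in enumerate(classes):
        pos = y_true == c
        pooled_s.append(scores[:, k])
        pooled_l.append(pos)
        if pos.all() or not pos.any():
            warnings.warn(f"class {c!r} absent or exhaustive; skipped in macro AUC")
            per_class[c] = float("nan")
        else:
            per_class[c] = roc_auc(scores[:, k], pos)
    micro = roc_auc(np.concatenate(pooled_s), np.concatenate(pooled_l))
    finite = [v for v in per_class.values() if np.isfinite(v)]
    macro = float(np.mean(finite)) if finite else float("nan")
    return {"micro": micro, "macro": macro, "per_class": per_class}


@dataclass
class MetricPanel:
    classes: list
    confusion: np.ndarray
    accuracy: float
    precision: dict
    recall: dict
    macro_precision: float
    macro_recall: float
    kappa: float
    micro_auc: float = float("nan")
    macro_auc: float = float("nan")

    def as_dict(self) -> dict:
        return {
            "classes": [str(c) for c in self.classes],
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "precision": {str(k): v for k, v in self.precision.items()},
            "recall": {str(k): v for k, v in self.recall.items()},
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "kappa": self.kappa,
            "micro_auc": self.micro_auc,
            "macro_auc": self.macro_auc,
        }


def metric_panel(y_true, y_pred, scores: np.ndarray | None = None,
                 classes: list | None = None) -> MetricPanel:
    """Full multiclass report; AUCs included when a score matrix is given."""
    y_true = np.asarray(y_true)
    if classes is None:
        classes = sorted(set(y_true) | set(np.asarray(y_pred)))
    cm = confusion_matrix(y_true, y_pred, classes)
    n = cm.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        prec_v = np.diag(cm) / cm.sum(axis=0)
        rec_v = np.diag(cm) / cm.sum(axis=1)
    precision = {c: float(prec_v[k]) for k, c in enumerate(classes)}
    recall = {c: float(rec_v[k]) for k, c in enumerate(classes)}
    aucs = {"micro": float("nan"), "macro": float("nan")}
    if scores is not None:
        aucs = multiclass_auc(scores, y_true, classes)
    return MetricPanel(
        classes=list(classes), confusion=cm,
        accuracy=float(np.trace(cm) / n),
        precision=precision, recall=recall,
        macro_precision=float(np.nanmean(prec_v)),
        macro_recall=float(np.nanmean(rec_v)),
        kappa=cohens_kappa(cm),
        micro_auc=aucs["micro"], macro_auc=aucs["macro"],
    )
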