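"""Phenotype prediction engines and jackknife (leave-one-out) validation.

Three engines share one sample-to-sample distance, the cosine distance

    d(e1, e2) = 1 - (e1 . e2) / (||e1|| ||e2||)

computed on the selected feature vectors:

``nn1``
    label of the nearest training sample,
``vote5``
    most frequent label among the five nearest training samples,
``centroid``
    label of the nearest class mean.

Jackknife validation predicts each sample from the remaining n-1: the
held-out sample is excluded from the neighbor pool and from centroid
computation, so nothing about it leaks into its own prediction.
Accuracy is the fraction of correct predictions,
(TP+TN)/(TP+TN+FP+FN) in confusion-count form.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import Counter
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ENGINES = ("vote5", "nn1", "centroid")


class DegenerateVectorError(ValueError):
    """Raised when a zero-norm vector makes the cosine distance undefined."""


class EmptyEvaluationError(ValueError):
    """Raised when an accuracy is requested over zero scored samples."""


@dataclasses.dataclass
class ConfusionCounts:
    """Binary confusion counts for a designated positive class."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "TN", "FP", "FN"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a nonnegative integer")
            setattr(self, name, int(v))

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def accuracy(counts: ConfusionCounts) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    if counts.total == 0:
        raise EmptyEvaluationError("no scored samples")
    return (counts.TP + counts.TN) / counts.total


def confusion_counts(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    positive_class: str,
) -> ConfusionCounts:
    """Binarize multiclass predictions one-vs-rest for ``positive_class``."""
    t = np.asarray(true_labels, dtype=object)
    p = np.asarray(predicted_labels, dtype=object)
    if t.shape != p.shape:
        raise ValueError("true and predicted labels must align")
    tp = int(np.sum((t == positive_class) & (p == positive_class)))
    tn = int(np.sum((t != positive_class) & (p != positive_class)))
    fp = int(np.sum((t != positive_class) & (p == positive_class)))
    fn = int(np.sum((t == positive_class) & (p != positive_class)))
    return ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)


# ---------------------------------------------------------------------------
# Distance
# ---------------------------------------------------------------------------

def sample_distance(e1: Sequence[float], e2: Sequence[float]) -> float:
    """Cosine distance between two feature vectors; range [0, 2].

    Symmetric and invariant to positive rescaling of either vector.
    Zero-norm vectors have no direction and raise
    :class:`DegenerateVectorError`.
    """
    a = np.asarray(e1, dtype=float).ravel()
    b = np.asarray(e2, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    if a.size == 0:
        raise ValueError("vectors must have length >= 1")
    na = float(np.linalg.norm(a))
    nb = float(np.linalg.norm(b))
    if na == 0.0 or nb == 0.0:
        raise DegenerateVectorError("zero-norm vector has no direction")
    d = 1.0 - float(a @ b) / (na * nb)
    return min(max(d, 0.0), 2.0)


def _distance_matrix(V: np.ndarray) -> np.ndarray:
    """All-pairs cosine distances for rows of a samples x features matrix."""
    norms = np.linalg.norm(V, axis=1)
    if np.any(norms == 0.0):
        raise DegenerateVectorError("zero-norm sample vector")
    Vn = V / norms[:, None]
    D = 1.0 - Vn @ Vn.T
    np.clip(D, 0.0, 2.0, out=D)
    np.fill_diagonal(D, 0.0)
    return D


def _distances_to(V: np.ndarray, query: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(V, axis=1)
    nq = float(np.linalg.norm(query))
    if np.any(norms == 0.0) or nq == 0.0:
        raise DegenerateVectorError("zero-norm vector")
    d = 1.0 - (V @ query) / (norms * nq)
    return np.clip(d, 0.0, 2.0)


# ---------------------------------------------------------------------------
# Prediction engines
# ---------------------------------------------------------------------------

def predict_nn1(
    train_vectors: np.ndarray,
    train_labels: Sequence[str],
    query: Sequence[float],
) -> str:
    """Label of the nearest training sample (ties: smallest train index)."""
    V = np.asarray(train_vectors, dtype=float)
    labels = np.asarray(train_labels, dtype=object)
    if V.shape[0] == 0:
        raise ValueError("no reference samples")
    d = _distances_to(V, np.asarray(query, dtype=float).ravel())
    return str(labels[int(np.argmin(d))])


def predict_vote5(
    train_vectors: np.ndarray,
    train_labels: Sequence[str],
    query: Sequence[float],
    k: int = 5,
) -> str:
    """Majority label among the ``k`` nearest training samples.

    Vote ties are resolved in favor of the tied label whose nearest
    representative is closest to the query; neighbor-distance ties break
    by smallest training index (stable sort).  If fewer than ``k``
    training samples exist, k is truncated with a logged notice.
    """
    V = np.asarray(train_vectors, dtype=float)
    labels = np.asarray(train_labels, dtype=object)
    if V.shape[0] == 0:
        raise ValueError("no reference samples")
    if V.shape[0] < k:
        logger.info("vote engine: only %d training samples, truncating k=%d",
                    V.shape[0], k)
        k = V.shape[0]
    d = _distances_to(V, np.asarray(query, dtype=float).ravel())
    order = np.argsort(d, kind="stable")[:k]
    top_labels = [str(labels[i]) for i in order]
    counts = Counter(top_labels)
    best = max(counts.values())
    for lab in top_labels:  # nearest-first scan resolves vote ties
        if counts[lab] == best:
            return lab
    raise AssertionError("unreachable")


def predict_centroid(
    train_vectors: np.ndarray,
    train_labels: Sequence[str],
    query: Sequence[float],
    class_order: Sequence[str],
) -> str:
    """Label of the class centroid nearest to the query.

    Centroids are arithmetic means of each class's training vectors;
    distance ties go to the earlier class in ``class_order``.
    """
    V = np.asarray(train_vectors, dtype=float)
    labels = np.asarray(train_labels, dtype=object)
    if V.shape[0] == 0:
        raise ValueError("no reference samples")
    q = np.asarray(query, dtype=float).ravel()
    best_label: str | None = None
    best_d = np.inf
    for cls in class_order:
        mask = labels == cls
        if not mask.any():
            continue
        centroid = V[mask].mean(axis=0)
        d = sample_distance(centroid, q)
        if d < best_d:  # strict: ties keep the earlier class
            best_d = d
            best_label = cls
    if best_label is None:
        raise ValueError("no training class present")
    return best_label


# ---------------------------------------------------------------------------
# Jackknife validation
# ---------------------------------------------------------------------------

def jackknife_predictions(
    matrix,
    feature_subset: Sequence[str],
    engines: Iterable[str] = ENGINES,
) -> pd.DataFrame:
    """Leave-one-out predictions for every requested engine.

    Returns one row per sample with columns ``sample_id``, ``true``,
    one predicted-label column per engine, and matching
    ``correct_<engine>`` indicator columns.  All engines share the
    pairwise distance matrix; centroids are recomputed inside each fold
    without the held-out sample.
    """
    engines = list(engines)
    unknown = [e for e in engines if e not in ENGINES]
    if unknown:
        raise ValueError(f"unknown engines: {unknown}")
    feature_subset = list(feature_subset)
    if not feature_subset:
        raise ValueError("feature_subset must be nonempty")
    if matrix.n_samples < 2:
        raise ValueError("jackknife needs at least 2 samples")

    V = matrix.subset_values(feature_subset)  # samples x features
    labels = matrix.labels
    class_order = matrix.class_order
    n = V.shape[0]
    out: dict[str, list] = {e: [] for e in engines}

    need_nn = any(e in ("nn1", "vote5") for e in engines)
    if need_nn:
        D = _distance_matrix(V)
        Dm = D.copy()
        np.fill_diagonal(Dm, np.inf)

    if "nn1" in engines:
        nn_idx = np.argmin(Dm, axis=1)  # ties -> smallest original index
        out["nn1"] = [str(labels[j]) for j in nn_idx]

    if "vote5" in engines:
        k = min(5, n - 1)
        if k < 5:
            logger.info("vote engine: only %d neighbors per fold", k)
        preds = []
        for i in range(n):
            order = np.argsort(Dm[i], kind="stable")[:k]
            top = [str(labels[j]) for j in order]
            counts = Counter(top)
            best = max(counts.values())
            preds.append(next(l for l in top if counts[l] == best))
        out["vote5"] = preds

    if "centroid" in engines:
        sums: dict[str, np.ndarray] = {}
        cnts: dict[str, int] = {}
        for cls in class_order:
            mask = labels == cls
            if mask.any():
                sums[cls] = V[mask].sum(axis=0)
                cnts[cls] = int(mask.sum())
        warned: set[str] = set()
        preds = []
        for i in range(n):
            best_label, best_d = None, np.inf
            for cls in class_order:
                if cls not in sums:
                    continue
                m = cnts[cls] - (1 if labels[i] == cls else 0)
                if m == 0:
                    if cls not in warned:
                        logger.warning(
                            "centroid engine: class %r emptied by leave-one-out;"
                            " omitting its centroid for that fold", cls)
                        warned.add(cls)
                    continue
                s = sums[cls] - (V[i] if labels[i] == cls else 0.0)
                d = sample_distance(s / m, V[i])
                if d < best_d:
                    best_d, best_label = d, cls
            if best_label is None:
                raise ValueError("no class centroid available in a fold")
            preds.append(best_label)
        out["centroid"] = preds

    frame = pd.DataFrame({"sample_id": matrix.sample_ids,
                          "true": [str(l) for l in labels]})
    for e in engines:
        frame[e] = out[e]
        frame[f"correct_{e}"] = (frame[e] == frame["true"]).astype(int)
    return frame


def jackknife(
    matrix,
    feature_subset: Sequence[str],
    engine: str,
) -> tuple[pd.DataFrame, float]:
    """Leave-one-out validation with one engine.

    Returns the per-sample prediction records and the overall accuracy
    (fraction of correct predictions across all held-out samples).
    """
    frame = jackknife_predictions(matrix, feature_subset, engines=[engine])
    records = frame.rename(columns={engine: "predicted",
                                    f"correct_{engine}": "correct"})
    acc = float(records["correct"].mean())
    return records, acc


def pairwise_accuracy(
    results: pd.DataFrame,
    class_a: str,
    class_b: str,
    predicted_col: str = "predicted",
) -> float:
    """Accuracy restricted to samples whose TRUE label is in {a, b}.

    A restricted prediction counts as correct iff it equals the true
    label; predictions on other classes are excluded from both numerator
    and denominator.
    """
    mask = results["true"].isin([class_a, class_b])
    if not mask.any():
        raise EmptyEvaluationError(
            f"no samples with true label in {{{class_a}, {class_b}}}")
    sub = results.loc[mask]
    return float((sub[predicted_col] == sub["true"]).mean())
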