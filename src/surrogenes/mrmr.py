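"""Maximum-relevance minimum-redundancy (mRMR) feature ranking.

Relevance and redundancy are both measured with the Gaussian
mutual-information estimator

    I(x, y) = -1/2 * ln(1 - rho(x, y)^2)      [nats]

where ``rho`` is a Pearson (default) or Spearman correlation.  The
categorical phenotype is encoded ordinally by its position in
``class_order`` (e.g. NT=0, PT=1, MT=2 for disease-progression phases),
so a monotone expression trend across phases yields high relevance.

Features are ranked greedily: the first pick maximizes relevance, every
later pick maximizes

    q = I(x_j, y) - (1/|S|) * sum_{x_k in S} I(x_j, x_k)

over the not-yet-selected candidates, where S is the selected set.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: rho^2 is clamped at this value so perfectly correlated pairs yield a
#: large finite MI (~13.8 nats) instead of infinity; keeps the greedy
#: argmax well-defined when exact duplicate probes are present.
RHO_SQ_CLAMP = 1.0 - 1e-12

#: Largest MI value the estimator can return under the clamp.
MAX_MI = -0.5 * float(np.log1p(-RHO_SQ_CLAMP))

CORRELATION_METHODS = ("pearson", "spearman")


class DegenerateTargetError(ValueError):
    """Raised when the phenotype vector carries no class contrast."""


@dataclasses.dataclass
class LabeledExpressionMatrix:
    """Expression values (probes x samples) with per-sample phenotype labels.

    Parameters
    ----------
    values
        2-D float array, one row per probe, one column per sample.
    probe_ids, sample_ids
        Identifier lists matching the two axes.
    labels
        One phenotype label per sample; every label must occur in
        ``class_order``.
    class_order
        Ordered class labels; the position in this tuple is the ordinal
        encoding used for correlation with the phenotype.
    """

    values: np.ndarray
    probe_ids: list[str]
    sample_ids: list[str]
    labels: np.ndarray
    class_order: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.labels = np.asarray(self.labels, dtype=object)
        self.class_order = tuple(str(c) for c in self.class_order)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D probes x samples array")
        n_probes, n_samples = self.values.shape
        if len(self.probe_ids) != n_probes:
            raise ValueError(
                f"probe_ids length {len(self.probe_ids)} != {n_probes} rows"
            )
        if len(self.sample_ids) != n_samples:
            raise ValueError(
                f"sample_ids length {len(self.sample_ids)} != {n_samples} columns"
            )
        if self.labels.shape != (n_samples,):
            raise ValueError("labels must have one entry per sample")
        if len(set(self.probe_ids)) != n_probes:
            raise ValueError("duplicate probe identifiers")
        unknown = sorted(set(self.labels) - set(self.class_order))
        if unknown:
            raise ValueError(f"labels not in class_order: {unknown}")
        if np.isnan(self.values).any():
            raise ValueError("expression values contain missing entries")
        self._probe_index = {p: i for i, p in enumerate(self.probe_ids)}

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def ordinal_labels(self) -> np.ndarray:
        """Labels encoded as their 0-based position in ``class_order``."""
        pos = {c: i for i, c in enumerate(self.class_order)}
        return np.array([pos[l] for l in self.labels], dtype=float)

    def class_counts(self) -> dict[str, int]:
        return {c: int(np.sum(self.labels == c)) for c in self.class_order}

    def probe_index(self, probe_id: str) -> int:
        try:
            return self._probe_index[probe_id]
        except KeyError:
            raise KeyError(f"unknown probe id: {probe_id!r}") from None

    def probe_values(self, probe_id: str) -> np.ndarray:
        return self.values[self.probe_index(probe_id)]

    def subset_values(self, probe_subset: Sequence[str]) -> np.ndarray:
        """Samples x features matrix for the given probes, in given order."""
        idx = [self.probe_index(p) for p in probe_subset]
        return self.values[idx].T.copy()


@dataclasses.dataclass
class FeatureRanking:
    """Greedy mRMR selection order with per-step score decomposition."""

    ordered_probes: list[str]
    relevance: np.ndarray
    mean_redundancy: np.ndarray
    q_score: np.ndarray

    def __post_init__(self) -> None:
        self.ordered_probes = [str(p) for p in self.ordered_probes]
        self.relevance = np.asarray(self.relevance, dtype=float)
        self.mean_redundancy = np.asarray(self.mean_redundancy, dtype=float)
        self.q_score = np.asarray(self.q_score, dtype=float)
        n = len(self.ordered_probes)
        if len(set(self.ordered_probes)) != n:
            raise ValueError("duplicate probes in ranking")
        for name in ("relevance", "mean_redundancy", "q_score"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} must have one entry per step")

    def __len__(self) -> int:
        return len(self.ordered_probes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": np.arange(1, len(self) + 1),
                "probe_id": self.ordered_probes,
                "relevance": self.relevance,
                "mean_redundancy": self.mean_redundancy,
                "q": self.q_score,
            }
        )


# ---------------------------------------------------------------------------
# Mutual-information estimator
# ---------------------------------------------------------------------------

def mutual_information(rho):
    """MI (nats) of a bivariate Gaussian with correlation ``rho``.

    Accepts a scalar or array; rho^2 is clamped at ``RHO_SQ_CLAMP`` so
    |rho| = 1 maps to ``MAX_MI`` rather than infinity.
    """
    arr = np.asarray(rho, dtype=float)
    if np.any(np.abs(arr) > 1.0 + 1e-9):
        raise ValueError("correlation coefficient outside [-1, 1]")
    r2 = np.minimum(arr * arr, RHO_SQ_CLAMP)
    out = -0.5 * np.log1p(-r2)
    if np.isscalar(rho) or np.ndim(rho) == 0:
        return float(out)
    return out


def _rank_transform(a: np.ndarray) -> np.ndarray:
    """Row-wise midrank transform (Spearman = Pearson on these ranks)."""
    if a.ndim == 1:
        return stats.rankdata(a)
    return np.apply_along_axis(stats.rankdata, 1, a)


def _correlations_with_vector(
    values: np.ndarray, target: np.ndarray, method: str = "pearson"
) -> np.ndarray:
    """Correlation of every row of ``values`` with ``target``.

    Zero-variance rows (or a zero-variance target) get rho = 0 by
    convention so that undefined correlations never poison an argmax.
    """
    if method not in CORRELATION_METHODS:
        raise ValueError(f"unknown correlation method: {method!r}")
    X = np.asarray(values, dtype=float)
    t = np.asarray(target, dtype=float)
    if method == "spearman":
        X = _rank_transform(X)
        t = _rank_transform(t)
    Xc = X - X.mean(axis=1, keepdims=True)
    tc = t - t.mean()
    sx = np.sqrt(np.einsum("ij,ij->i", Xc, Xc))
    st = float(np.sqrt(tc @ tc))
    denom = sx * st
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, Xc @ tc / np.where(denom > 0, denom, 1.0), 0.0)
    return np.clip(r, -1.0, 1.0)


def feature_label_correlation(
    feature: Sequence[float],
    labels: Sequence[str],
    class_order: Sequence[str],
    method: str = "pearson",
) -> float:
    """Correlation of one feature with the ordinally encoded phenotype.

    Labels are mapped to 0, 1, 2, ... by their position in
    ``class_order``; a zero-variance feature returns exactly 0.
    """
    feat = np.asarray(feature, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if feat.ndim != 1 or feat.shape != labels.shape:
        raise ValueError("feature and labels must be equal-length vectors")
    if feat.size < 3:
        raise ValueError("need at least 3 samples for a correlation")
    pos = {c: i for i, c in enumerate(class_order)}
    unknown = sorted(set(labels) - set(pos))
    if unknown:
        raise ValueError(f"labels not in class_order: {unknown}")
    if len(set(labels.tolist())) < 2:
        raise DegenerateTargetError("all samples share one class")
    target = np.array([pos[l] for l in labels], dtype=float)
    return float(_correlations_with_vector(feat[None, :], target, method)[0])


# ---------------------------------------------------------------------------
# mRMR scoring and greedy ranking
# ---------------------------------------------------------------------------

def _ordinal_target(matrix: LabeledExpressionMatrix) -> np.ndarray:
    target = matrix.ordinal_labels()
    if len(set(matrix.labels.tolist())) < 2:
        raise DegenerateTargetError("all samples share one class")
    return target


def mrmr_score(
    candidate: str,
    selected,
    matrix: LabeledExpressionMatrix,
    method: str = "pearson",
) -> float:
    """q-score of one candidate probe against an already-selected set.

    ``selected`` may be a :class:`FeatureRanking` or any sequence of
    probe ids.  With an empty selected set, q equals the relevance alone
    (the initialization step of the greedy search).
    """
    if isinstance(selected, FeatureRanking):
        selected_ids = list(selected.ordered_probes)
    else:
        selected_ids = [str(p) for p in selected]
    if candidate in selected_ids:
        raise ValueError(f"candidate {candidate!r} already selected")
    target = _ordinal_target(matrix)
    cand = matrix.probe_values(candidate)
    relevance = mutual_information(
        _correlations_with_vector(cand[None, :], target, method)[0]
    )
    if not selected_ids:
        return float(relevance)
    red = 0.0
    for pid in selected_ids:
        rho = _correlations_with_vector(
            cand[None, :], matrix.probe_values(pid), method
        )[0]
        red += mutual_information(rho)
    return float(relevance - red / len(selected_ids))


def mrmr_rank(
    matrix: LabeledExpressionMatrix,
    n_features: int,
    method: str = "pearson",
) -> FeatureRanking:
    """Greedy mRMR ranking of ``n_features`` probes.

    Step 1 takes the probe with maximal relevance; every later step
    takes the probe maximizing q over the remaining candidates.  Exact
    ties are broken by the smallest probe index in input order, so the
    ranking is deterministic.  Because the search is greedy, the first k
    entries of a length-n ranking equal the length-k ranking (prefix
    consistency), which is what lets incremental feature selection
    evaluate prefixes of a single ranking.
    """
    if not 1 <= n_features <= matrix.n_probes:
        raise ValueError(
            f"n_features must be in [1, {matrix.n_probes}], got {n_features}"
        )
    if method not in CORRELATION_METHODS:
        raise ValueError(f"unknown correlation method: {method!r}")
    target = _ordinal_target(matrix)

    # Pre-transform once for Spearman; the incremental redundancy update
    # below is then a plain Pearson pass on the transformed rows.
    work = matrix.values
    if method == "spearman":
        work = _rank_transform(work)
        target = _rank_transform(target)

    relevance = mutual_information(
        _correlations_with_vector(work, target, "pearson")
    )

    n_probes = matrix.n_probes
    red_sum = np.zeros(n_probes)
    available = np.ones(n_probes, dtype=bool)
    order: list[int] = []
    rel_out = np.empty(n_features)
    red_out = np.empty(n_features)
    q_out = np.empty(n_features)

    for step in range(n_features):
        if step == 0:
            score = relevance.copy()
            mean_red = np.zeros(n_probes)
        else:
            mean_red = red_sum / step
            score = relevance - mean_red
        score[~available] = -np.inf
        idx = int(np.argmax(score))  # ties -> smallest input index
        order.append(idx)
        available[idx] = False
        rel_out[step] = relevance[idx]
        red_out[step] = mean_red[idx]
        q_out[step] = relevance[idx] - mean_red[idx]
        if step + 1 < n_features:
            rho = _correlations_with_vector(work, work[idx], "pearson")
            red_sum += mutual_information(rho)

    return FeatureRanking(
        ordered_probes=[matrix.probe_ids[i] for i in order],
        relevance=rel_out,
        mean_redundancy=red_out,
        q_score=q_out,
    )
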