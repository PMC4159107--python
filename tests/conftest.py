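"""Shared fixtures and independent oracle implementations.

The oracles deliberately avoid the package's internals: the mRMR oracle
re-derives every correlation with ``np.corrcoef`` and evaluates the
selection criterion exhaustively per step; the shortest-path oracle is
``scipy.sparse.csgraph.floyd_warshall`` on a dense weight matrix.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from surrogenes import ExpressionSimConfig, LabeledExpressionMatrix
from surrogenes import generate_expression_dataset


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _mi(rho: float) -> float:
    r2 = min(rho * rho, 1.0 - 1e-12)
    return -0.5 * math.log(1.0 - r2)


def oracle_mrmr_order(values: np.ndarray, target: np.ndarray,
                      n_features: int) -> list[int]:
    """Exhaustive per-step argmax of relevance minus mean redundancy."""
    n_probes = values.shape[0]
    relevance = [_mi(_safe_corr(values[i], target)) for i in range(n_probes)]
    selected: list[int] = []
    remaining = list(range(n_probes))
    for _ in range(n_features):
        best_idx, best_q = None, -math.inf
        for cand in remaining:
            if selected:
                red = sum(_mi(_safe_corr(values[cand], values[s]))
                          for s in selected) / len(selected)
            else:
                red = 0.0
            q = relevance[cand] - red
            if q > best_q:  # strict: ties keep the smallest index
                best_q, best_idx = q, cand
        selected.append(best_idx)
        remaining.remove(best_idx)
    return selected


def random_labeled_matrix(rng: np.random.Generator,
                          n_probes: int = 8,
                          n_samples: int = 30) -> LabeledExpressionMatrix:
    """Pure-noise matrix with a 3-class label for oracle comparisons."""
    values = rng.normal(10.0, 2.0, size=(n_probes, n_samples))
    classes = ("NT", "PT", "MT")
    labels = np.array([classes[i % 3] for i in range(n_samples)], dtype=object)
    return LabeledExpressionMatrix(
        values=values,
        probe_ids=[f"P{i}" for i in range(n_probes)],
        sample_ids=[f"S{j}" for j in range(n_samples)],
        labels=labels,
        class_order=classes,
    )


def oracle_all_pairs_lengths(nodes: list[str], weight: np.ndarray) -> np.ndarray:
    """Floyd–Warshall all-pairs lengths on a dense weight matrix."""
    from scipy.sparse.csgraph import floyd_warshall
    return floyd_warshall(weight, directed=False)


@pytest.fixture(scope="session")
def default_sim():
    """One seeded dataset at the study-scale defaults (167 samples)."""
    return generate_expression_dataset(ExpressionSimConfig(seed=1))


@pytest.fixture(scope="session")
def separable_sim():
    """Well-separated dataset (effect_size=5) for exact-limit checks."""
    return generate_expression_dataset(
        ExpressionSimConfig(effect_size=5.0, seed=1))
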