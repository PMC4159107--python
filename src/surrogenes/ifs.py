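"""Incremental feature selection (IFS) over a fixed mRMR ranking.

For N = 1..max_n the first N probes of one ranking are scored by
jackknife validation under each requested prediction engine.  Because
the greedy mRMR search nests (the length-k ranking is a prefix of the
length-n ranking), evaluating prefixes of a single ranking is identical
to re-running the selection at every N.  The optimal feature count is
the smallest N attaining the maximum accuracy of the selecting engine
("best accuracy, smallest feature number").
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from typing import Sequence

import pandas as pd

from .classify import ENGINES, jackknife_predictions, pairwise_accuracy
from .mrmr import FeatureRanking, LabeledExpressionMatrix

logger = logging.getLogger(__name__)

#: Resolution below which two jackknife accuracies (ratios of counts over
#: the same denominator) are considered tied.
_ACC_TOL = 1e-12


@dataclasses.dataclass
class IFSCurve:
    """Per-N jackknife accuracies plus the selected optimum.

    ``points`` has one row per N with an ``acc_<engine>`` column per
    engine and ``acc_<engine>_<a>_vs_<b>`` columns for every unordered
    class pair (accuracy restricted to samples truly in that pair).
    """

    points: pd.DataFrame
    max_n: int
    ranking_probes: list[str]
    engines: tuple[str, ...]
    selecting_engine: str
    optimal_n: int
    optimal_features: list[str]

    def accuracy_column(self, engine: str) -> str:
        col = f"acc_{engine}"
        if col not in self.points.columns:
            raise KeyError(f"engine {engine!r} not present in curve")
        return col


def select_optimal(
    points: pd.DataFrame | IFSCurve,
    engine: str,
    ranking_probes: Sequence[str] | None = None,
) -> tuple[int, list[str]]:
    """Smallest N attaining the maximum accuracy for ``engine``.

    Accepts either an :class:`IFSCurve` or its ``points`` frame (the
    latter requires ``ranking_probes`` to materialize the feature list).
    """
    if isinstance(points, IFSCurve):
        ranking_probes = points.ranking_probes
        frame = points.points
    else:
        frame = points
    col = f"acc_{engine}"
    if col not in frame.columns:
        raise KeyError(f"engine {engine!r} not present in curve")
    if len(frame) == 0:
        raise ValueError("empty curve")
    acc = frame[col].to_numpy()
    best = acc.max()
    n_col = frame["n"].to_numpy()
    optimal_n = int(n_col[acc >= best - _ACC_TOL][0])
    features = (
        [str(p) for p in ranking_probes[:optimal_n]]
        if ranking_probes is not None
        else []
    )
    return optimal_n, features


def run_ifs(
    matrix: LabeledExpressionMatrix,
    ranking: FeatureRanking,
    max_n: int | None = None,
    engines: Sequence[str] = ENGINES,
    selecting_engine: str = "nn1",
) -> IFSCurve:
    """Sweep prefix sizes N = 1..max_n and score each by jackknife.

    ``max_n`` defaults to min(400, ranking length), mirroring a sweep of
    up to 400 candidate features.  ``selecting_engine`` (default the
    1-nearest-neighbor engine) picks the reported optimum.
    """
    engines = tuple(engines)
    if selecting_engine not in engines:
        raise ValueError(
            f"selecting engine {selecting_engine!r} not among {engines}")
    if max_n is None:
        max_n = min(400, len(ranking))
    if not 1 <= max_n <= len(ranking):
        raise ValueError(
            f"max_n must be in [1, {len(ranking)}], got {max_n}")

    class_pairs = list(itertools.combinations(matrix.class_order, 2))
    rows = []
    for n in range(1, max_n + 1):
        subset = ranking.ordered_probes[:n]
        preds = jackknife_predictions(matrix, subset, engines=engines)
        row: dict[str, float] = {"n": n}
        for e in engines:
            row[f"acc_{e}"] = float(preds[f"correct_{e}"].mean())
            for a, b in class_pairs:
                row[f"acc_{e}_{a}_vs_{b}"] = pairwise_accuracy(
                    preds, a, b, predicted_col=e)
        rows.append(row)
    points = pd.DataFrame(rows)
    points["n"] = points["n"].astype(int)

    optimal_n, optimal_features = select_optimal(
        points, selecting_engine, ranking.ordered_probes)
    logger.info("IFS optimum: N=%d, %s accuracy %.4f",
                optimal_n, selecting_engine,
                float(points[f"acc_{selecting_engine}"].max()))
    return IFSCurve(
        points=points,
        max_n=max_n,
        ranking_probes=list(ranking.ordered_probes),
        engines=engines,
        selecting_engine=selecting_engine,
        optimal_n=optimal_n,
        optimal_features=optimal_features,
    )


def plot_ifs_curve(curve: IFSCurve, path) -> None:
    """Write a plot of the per-engine IFS accuracy curves to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for e in curve.engines:
        ax.plot(curve.points["n"], curve.points[f"acc_{e}"], label=e)
    ax.axvline(curve.optimal_n, color="grey", ls="--", lw=0.8,
               label=f"optimum N={curve.optimal_n}")
    ax.set_xlabel("number of features (N)")
    ax.set_ylabel("jackknife accuracy")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
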