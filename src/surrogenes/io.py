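"""Reading and writing the pipeline's tab-separated artifacts.

Expression matrices are probes-in-rows TSV with a header row of sample
identifiers (GEO series-matrix orientation); phenotype labels are a
2-column TSV (sample_id, label); interaction networks use the STRING
flat-file convention (``protein1 protein2 combined_score``).  Floats
are written with Python's shortest round-trip representation, so every
write-then-read cycle reproduces the in-memory values exactly.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ifs import IFSCurve
from .mrmr import FeatureRanking, LabeledExpressionMatrix
from .network import InteractionGraph, SubnetworkResult
from .synth import SimulatedExpression

logger = logging.getLogger(__name__)


class ExpressionParseError(ValueError):
    """Raised on a non-numeric expression cell (carries its coordinates)."""


class LabelMappingError(ValueError):
    """Raised when expression samples lack phenotype labels."""


# ---------------------------------------------------------------------------
# Expression + labels
# ---------------------------------------------------------------------------

def read_labels(path) -> dict[str, str]:
    """Read a 2-column (sample_id, label) TSV with a header row."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: expected 2 columns (sample_id, label)")
    ids = frame.iloc[:, 0].astype(str)
    labs = frame.iloc[:, 1].astype(str)
    return dict(zip(ids, labs))


def read_expression(
    path,
    labels_path,
    class_order: Sequence[str],
) -> LabeledExpressionMatrix:
    """Load a probes x samples TSV and align phenotype labels to it.

    Sample order is taken from the expression header, restricted to
    samples present in the labels file; labeled samples absent from the
    expression table are ignored with a warning, expression samples
    without a label are an error.  Probes containing any missing value
    are dropped with a logged count; non-numeric cells raise
    :class:`ExpressionParseError` with their coordinates.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0,
                        float_precision="round_trip")
    blank_mask = frame.isna()
    for col in frame.columns:
        if frame[col].dtype == object:
            coerced = pd.to_numeric(frame[col], errors="coerce")
            bad = coerced.isna() & frame[col].notna()
            if bad.any():
                probe = frame.index[bad.to_numpy().nonzero()[0][0]]
                raise ExpressionParseError(
                    f"{path}: non-numeric value at probe {probe!r}, "
                    f"sample {col!r}")
            frame[col] = coerced
    frame = frame.astype(float)

    labels_map = read_labels(labels_path)
    samples = [str(s) for s in frame.columns]
    unmapped = [s for s in samples if s not in labels_map]
    if unmapped:
        raise LabelMappingError(
            f"samples without phenotype label: {unmapped}")
    extra = sorted(set(labels_map) - set(samples))
    if extra:
        logger.warning("%d labeled samples absent from expression table "
                       "ignored: %s", len(extra), extra[:5])

    missing_rows = blank_mask.any(axis=1)
    if missing_rows.any():
        logger.info("dropping %d probes with missing values",
                    int(missing_rows.sum()))
        frame = frame.loc[~missing_rows]

    return LabeledExpressionMatrix(
        values=frame.to_numpy(dtype=float),
        probe_ids=[str(p) for p in frame.index],
        sample_ids=samples,
        labels=np.array([labels_map[s] for s in samples], dtype=object),
        class_order=tuple(class_order),
    )


def write_expression(matrix: LabeledExpressionMatrix, path) -> None:
    frame = pd.DataFrame(matrix.values, index=matrix.probe_ids,
                         columns=matrix.sample_ids)
    frame.index.name = "probe_id"
    frame.to_csv(path, sep="\t")


def write_labels(matrix: LabeledExpressionMatrix, path) -> None:
    pd.DataFrame({"sample_id": matrix.sample_ids,
                  "label": [str(l) for l in matrix.labels]}
                 ).to_csv(path, sep="\t", index=False)


def write_simulated_expression(sim: SimulatedExpression, out_dir) -> dict[str, Path]:
    """Write expression, labels and ground-truth sidecar into a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "labels": out / "labels.tsv",
        "truth": out / "truth.tsv",
    }
    write_expression(sim.matrix, paths["expression"])
    write_labels(sim.matrix, paths["labels"])
    sim.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# Ranking / curve / predictions
# ---------------------------------------------------------------------------

def write_ranking(ranking: FeatureRanking, path) -> None:
    ranking.to_frame().to_csv(path, sep="\t", index=False)


def read_ranking(path) -> FeatureRanking:
    frame = pd.read_csv(path, sep="\t", dtype={"probe_id": str},
                        float_precision="round_trip")
    return FeatureRanking(
        ordered_probes=frame["probe_id"].tolist(),
        relevance=frame["relevance"].to_numpy(),
        mean_redundancy=frame["mean_redundancy"].to_numpy(),
        q_score=frame["q"].to_numpy(),
    )


def write_curve(curve: IFSCurve, path) -> None:
    curve.points.to_csv(path, sep="\t", index=False)


def write_predictions(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Graphs / mapping / subnetworks
# ---------------------------------------------------------------------------

def write_graph(igraph: InteractionGraph, path) -> None:
    """STRING flat-file convention: space-separated with header row."""
    frame = igraph.edge_frame()
    with Path(path).open("w") as fh:
        fh.write("protein1 protein2 combined_score\n")
        for row in frame.itertuples(index=False):
            fh.write(f"{row.protein1} {row.protein2} {row.combined_score}\n")


def read_mapping(path) -> dict[str, str]:
    """2-column (probe_id, gene_id) TSV with a header row."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: expected 2 columns (probe_id, gene_id)")
    return dict(zip(frame.iloc[:, 0].astype(str), frame.iloc[:, 1].astype(str)))


def map_probes_to_genes(
    probes: Sequence[str],
    mapping: dict[str, str],
) -> list[str]:
    """Translate probe ids, deduplicating while preserving order.

    Probes without a mapping entry are dropped with a warning.
    """
    genes: list[str] = []
    missing = []
    for p in probes:
        g = mapping.get(str(p))
        if g is None:
            missing.append(p)
        elif g not in genes:
            genes.append(g)
    if missing:
        logger.warning("%d probes without gene mapping dropped: %s",
                       len(missing), missing[:5])
    return genes


def write_subnetwork(result: SubnetworkResult, out_dir) -> dict[str, Path]:
    """Edge list, seed/bridge node table, and per-pair path table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "edges": out / "subnetwork_edges.tsv",
        "nodes": out / "subnetwork_nodes.tsv",
        "paths": out / "subnetwork_paths.tsv",
    }
    pd.DataFrame(result.edges,
                 columns=["gene1", "gene2", "combined_score"]
                 ).to_csv(paths["edges"], sep="\t", index=False)
    node_rows = [{"gene": n,
                  "role": "seed" if n in set(result.seed_genes) else "bridge"}
                 for n in sorted(result.nodes)]
    pd.DataFrame(node_rows, columns=["gene", "role"]
                 ).to_csv(paths["nodes"], sep="\t", index=False)
    frame = result.paths.copy()
    if result.unresolved_pairs:
        unresolved = pd.DataFrame(
            [{"source": a, "target": b, "length": np.nan, "path": f"<{why}>"}
             for a, b, why in result.unresolved_pairs])
        frame = pd.concat([frame, unresolved], ignore_index=True)
    frame.to_csv(paths["paths"], sep="\t", index=False)
    return paths
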