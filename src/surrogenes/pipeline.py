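"""End-to-end surrogate-gene pipeline: rank -> IFS -> subnetwork.

Stages run in method order: mRMR ranking of the expression probes,
incremental feature selection with jackknife validation, probe-to-gene
mapping of the optimal feature set, and shortest-path subnetwork
extraction on the interaction network.  The network stage is optional:
without an edge file the pipeline stops after feature selection with an
explicit notice.  All outputs are deterministic given config + seed;
per-stage timings go to the log stream only, so reruns are
byte-identical file for file.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from importlib import metadata
from pathlib import Path
from typing import Sequence

import yaml

from . import io as sio
from .classify import ENGINES
from .ifs import IFSCurve, run_ifs
from .mrmr import mrmr_rank
from .network import (DEFAULT_SCORE_THRESHOLD, SubnetworkResult,
                      build_subnetwork, load_interactions)

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """Paths and parameters for a full pipeline run."""

    expression_path: str
    labels_path: str
    out_dir: str
    class_order: tuple[str, ...] = ("NT", "PT", "MT")
    method: str = "pearson"
    max_n: int = 400
    engines: tuple[str, ...] = ENGINES
    selecting_engine: str = "nn1"
    mapping_path: str | None = None
    edges_path: str | None = None
    score_threshold: int = DEFAULT_SCORE_THRESHOLD
    weight_mode: str = "hop"
    all_shortest: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("class_order", "engines"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["class_order"] = list(self.class_order)
        d["engines"] = list(self.engines)
        return d


@dataclasses.dataclass
class PipelineResult:
    ranking_path: Path
    curve: IFSCurve
    optimal_genes: list[str]
    subnetwork: SubnetworkResult | None
    report_path: Path


def _package_version() -> str:
    try:
        return metadata.version("surrogenes")
    except metadata.PackageNotFoundError:
        return "unknown"


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every configured stage and write all artifacts to out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config": config.to_dict(),
        "seed": config.seed,
        "versions": {"surrogenes": _package_version()},
        "stages": {},
    }

    t0 = time.perf_counter()
    matrix = sio.read_expression(config.expression_path, config.labels_path,
                                 config.class_order)
    logger.info("loaded expression: %d probes x %d samples (%.2fs)",
                matrix.n_probes, matrix.n_samples, time.perf_counter() - t0)
    report["stages"]["ingest"] = {
        "n_probes": matrix.n_probes,
        "n_samples": matrix.n_samples,
        "class_counts": matrix.class_counts(),
    }

    t0 = time.perf_counter()
    n_rank = min(config.max_n, matrix.n_probes)
    ranking = mrmr_rank(matrix, n_rank, method=config.method)
    ranking_path = out / "ranking.tsv"
    sio.write_ranking(ranking, ranking_path)
    logger.info("mRMR ranking of %d features done (%.2fs)",
                n_rank, time.perf_counter() - t0)
    report["stages"]["rank"] = {"n_features": n_rank, "method": config.method}

    t0 = time.perf_counter()
    curve = run_ifs(matrix, ranking, max_n=n_rank, engines=config.engines,
                    selecting_engine=config.selecting_engine)
    sio.write_curve(curve, out / "ifs_curve.tsv")
    from .classify import jackknife_predictions
    preds = jackknife_predictions(matrix, curve.optimal_features,
                                  engines=config.engines)
    sio.write_predictions(preds, out / "predictions.tsv")
    acc_col = curve.accuracy_column(config.selecting_engine)
    optimal_acc = float(curve.points[acc_col].max())
    logger.info("IFS sweep to N=%d done: optimum N=%d, accuracy %.4f (%.2fs)",
                n_rank, curve.optimal_n, optimal_acc, time.perf_counter() - t0)
    report["stages"]["ifs"] = {
        "max_n": n_rank,
        "selecting_engine": config.selecting_engine,
        "optimal_n": curve.optimal_n,
        "optimal_accuracy": optimal_acc,
        "optimal_features": curve.optimal_features,
    }

    if config.mapping_path:
        mapping = sio.read_mapping(config.mapping_path)
        genes = sio.map_probes_to_genes(curve.optimal_features, mapping)
    else:
        genes = list(dict.fromkeys(curve.optimal_features))
    report["stages"]["mapping"] = {"optimal_genes": genes}

    subnetwork: SubnetworkResult | None = None
    if config.edges_path:
        t0 = time.perf_counter()
        graph = load_interactions(config.edges_path,
                                  score_threshold=config.score_threshold,
                                  weight_mode=config.weight_mode)
        subnetwork = build_subnetwork(graph, genes,
                                      all_shortest=config.all_shortest)
        sio.write_subnetwork(subnetwork, out)
        logger.info("subnetwork: %d nodes, %d edges, %d bridge genes (%.2fs)",
                    len(subnetwork.nodes), len(subnetwork.edges),
                    len(subnetwork.bridge_genes), time.perf_counter() - t0)
        report["stages"]["subnetwork"] = {
            "n_nodes": len(subnetwork.nodes),
            "n_edges": len(subnetwork.edges),
            "bridge_genes": sorted(subnetwork.bridge_genes),
            "unresolved_pairs": [list(p) for p in subnetwork.unresolved_pairs],
        }
    else:
        logger.info("no interaction edge file configured; "
                    "stopping after feature selection")
        report["stages"]["subnetwork"] = "skipped (no edges file)"

    report_path = out / "report.json"
    with report_path.open("w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return PipelineResult(
        ranking_path=ranking_path,
        curve=curve,
        optimal_genes=genes,
        subnetwork=subnetwork,
        report_path=report_path,
    )
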