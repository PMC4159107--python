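"""Synthetic labeled expression data and scored interaction graphs.

The expression generator emulates the structure of a three-phase
disease-progression microarray study (normal tissue / primary tumor /
metastatic tumor, with unbalanced class sizes): a handful of
phase-informative probes whose class means shift monotonically along
the phase ordering, noisy near-duplicate copies of those probes
(planted redundancy), and a large background of label-independent null
probes.  Ground-truth probe roles are always returned alongside the
matrix so downstream feature selection can be tested as parameter
recovery.

Informative probes alternate direction (half increase along the phase
order, half decrease).  With a shared direction every class-mean vector
would be parallel and the cosine sample distance used by the prediction
engines could not separate the classes; alternating signs keeps the
planted monotone per-probe signal while giving the classes distinct
expression *profiles*, which is what real phase-discriminating gene
sets look like.

The graph generator plants seed genes joined by short bridge paths on
top of an Erdős–Rényi background, returning the bridge node set as
ground truth for shortest-path recovery tests.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .mrmr import LabeledExpressionMatrix
from .network import InteractionGraph, build_graph

logger = logging.getLogger(__name__)


class InvalidConfigError(ValueError):
    """Raised when a simulation configuration is inconsistent."""


@dataclasses.dataclass
class ExpressionSimConfig:
    """Configuration of the class-conditional Gaussian expression model.

    Defaults mirror the scale of the emulated study: 167 samples split
    77/66/24 across the three phases, 4 informative probes with 2 noisy
    copies each, and 188 null probes (200 probes total).

    Parameters
    ----------
    n_samples_per_class
        Sample count per phenotype, aligned with ``class_labels``.
    n_informative
        Number of phase-informative probes.
    n_redundant_per_informative
        Noisy copies planted per informative probe.
    n_null
        Label-independent background probes.
    effect_size
        Class-mean shift per phase step, in within-class SD units.
    redundancy_noise_sd
        SD of the Gaussian noise added to each redundant copy.
    baseline_range
        Per-probe baseline expression levels are spread evenly (for
        informative probes) or drawn uniformly (null probes) over this
        interval, in arbitrary units; within-class SD is fixed at 1.
    signature_noise_share
        Fraction of the within-class variance of informative probes
        contributed by a shared per-sample factor loading on the
        progression direction (emulating sample-level variation such
        as tumor purity, which moves all signature genes coherently).
        The per-probe within-class SD remains exactly 1.
    seed
        Seed for the NumPy generator; identical config + seed gives
        bit-identical output.
    """

    n_samples_per_class: tuple[int, ...] = (77, 66, 24)
    class_labels: tuple[str, ...] = ("NT", "PT", "MT")
    n_informative: int = 4
    n_redundant_per_informative: int = 2
    n_null: int = 188
    effect_size: float = 3.0
    redundancy_noise_sd: float = 0.5
    baseline_range: tuple[float, float] = (5.0, 15.0)
    signature_noise_share: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        self.n_samples_per_class = tuple(int(n) for n in self.n_samples_per_class)
        self.class_labels = tuple(str(c) for c in self.class_labels)
        if len(self.n_samples_per_class) != len(self.class_labels):
            raise InvalidConfigError(
                "n_samples_per_class and class_labels must align")
        if len(self.class_labels) == 0:
            raise InvalidConfigError("at least one class is required")
        if any(n <= 0 for n in self.n_samples_per_class):
            raise InvalidConfigError("every requested class needs >= 1 sample")
        for name in ("n_informative", "n_redundant_per_informative", "n_null"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0")
        if self.effect_size < 0:
            raise InvalidConfigError("effect_size must be >= 0")
        if self.redundancy_noise_sd < 0:
            raise InvalidConfigError("redundancy_noise_sd must be >= 0")
        lo, hi = self.baseline_range
        if not lo <= hi:
            raise InvalidConfigError("baseline_range must be (low, high)")
        if not 0.0 <= self.signature_noise_share < 1.0:
            raise InvalidConfigError(
                "signature_noise_share must be in [0, 1)")

    @property
    def n_probes(self) -> int:
        return (self.n_informative * (1 + self.n_redundant_per_informative)
                + self.n_null)

    @property
    def n_samples(self) -> int:
        return sum(self.n_samples_per_class)


@dataclasses.dataclass
class SimulatedExpression:
    """Generated matrix plus the ground-truth probe-role sidecar.

    ``truth`` columns: ``probe_id``, ``role`` (informative / redundant /
    null) and ``parent`` (the informative parent of a redundant copy,
    empty otherwise).
    """

    matrix: LabeledExpressionMatrix
    truth: pd.DataFrame
    config: ExpressionSimConfig

    def informative_probes(self) -> list[str]:
        return self.truth.loc[self.truth["role"] == "informative",
                              "probe_id"].tolist()

    def probe_family(self, probe_id: str) -> str:
        """Informative parent of a probe (itself if informative)."""
        row = self.truth.loc[self.truth["probe_id"] == probe_id].iloc[0]
        return row["probe_id"] if row["role"] == "informative" else row["parent"]

    def informative_coverage(self, probe_subset: Sequence[str]) -> bool:
        """True if every informative probe is represented in the subset,
        either by itself or by one of its redundant copies."""
        covered = set()
        roles = self.truth.set_index("probe_id")
        for p in probe_subset:
            if p not in roles.index:
                continue
            role = roles.loc[p, "role"]
            if role == "informative":
                covered.add(p)
            elif role == "redundant":
                covered.add(roles.loc[p, "parent"])
        return covered >= set(self.informative_probes())


def generate_expression_dataset(config: ExpressionSimConfig) -> SimulatedExpression:
    """Draw a labeled expression matrix with planted probe roles.

    Informative probe i has per-class mean ``baseline_i + s_i * k *
    effect_size`` (within-class SD 1), where k is the 0-based phase
    index and the sign s_i alternates +1/-1 with i.  Its within-class
    noise mixes an independent component with a per-sample factor
    loading on s_i (``signature_noise_share`` of the variance), so
    informative probes co-vary coherently along the progression axis
    within each class, as signature genes do in heterogeneous tissue.
    Redundant copies are their parent's values plus
    N(0, redundancy_noise_sd) noise.  Null probes are
    label-independent Gaussians.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    labels = np.repeat(cfg.class_labels, cfg.n_samples_per_class)
    k = np.repeat(np.arange(len(cfg.class_labels), dtype=float),
                  cfg.n_samples_per_class)
    n = cfg.n_samples
    lo, hi = cfg.baseline_range

    rows: list[np.ndarray] = []
    probe_ids: list[str] = []
    truth_rows: list[dict] = []

    if cfg.n_informative > 0:
        baselines = np.linspace(lo, hi, cfg.n_informative)
    share = cfg.signature_noise_share
    factor = rng.standard_normal(n)  # shared per-sample signature factor
    informative_values = []
    for i in range(cfg.n_informative):
        sign = 1.0 if i % 2 == 0 else -1.0
        mean = baselines[i] + sign * k * cfg.effect_size
        noise = (np.sqrt(1.0 - share) * rng.standard_normal(n)
                 + np.sqrt(share) * sign * factor)
        vals = mean + noise
        informative_values.append(vals)
        pid = f"INF{i + 1:03d}"
        rows.append(vals)
        probe_ids.append(pid)
        truth_rows.append({"probe_id": pid, "role": "informative", "parent": ""})

    for i in range(cfg.n_informative):
        for c in range(cfg.n_redundant_per_informative):
            vals = informative_values[i] + (
                rng.standard_normal(n) * cfg.redundancy_noise_sd
                if cfg.redundancy_noise_sd > 0 else 0.0)
            pid = f"INF{i + 1:03d}_COPY{c + 1}"
            rows.append(np.asarray(vals, dtype=float))
            probe_ids.append(pid)
            truth_rows.append({"probe_id": pid, "role": "redundant",
                               "parent": f"INF{i + 1:03d}"})

    for m in range(cfg.n_null):
        baseline = rng.uniform(lo, hi)
        vals = baseline + rng.standard_normal(n)
        pid = f"NULL{m + 1:04d}"
        rows.append(vals)
        probe_ids.append(pid)
        truth_rows.append({"probe_id": pid, "role": "null", "parent": ""})

    if not rows:
        raise InvalidConfigError("configuration yields zero probes")

    values = np.vstack(rows)
    sample_ids = [f"S{j + 1:03d}_{labels[j]}" for j in range(n)]
    matrix = LabeledExpressionMatrix(
        values=values,
        probe_ids=probe_ids,
        sample_ids=sample_ids,
        labels=labels,
        class_order=cfg.class_labels,
    )
    truth = pd.DataFrame(truth_rows, columns=["probe_id", "role", "parent"])
    return SimulatedExpression(matrix=matrix, truth=truth, config=cfg)


# ---------------------------------------------------------------------------
# Interaction-graph simulation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class GraphSimConfig:
    """Configuration of the planted-bridge interaction graph.

    ``planted_bridges`` maps seed pairs to ordered bridge-node lists:
    ``(("A", "C"), ("B1", "B2"))`` inserts the chain A-B1-B2-C, every
    planted edge at the maximum of ``score_range``.  The Erdős–Rényi
    background with ``edge_probability`` is drawn among the
    ``n_background_nodes`` background nodes, with uniform integer
    scores over ``score_range``.
    """

    n_background_nodes: int = 50
    edge_probability: float = 0.05
    seed_genes: tuple[str, ...] = ()
    planted_bridges: tuple[tuple[tuple[str, str], tuple[str, ...]], ...] = ()
    score_range: tuple[int, int] = (400, 900)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_background_nodes < 0:
            raise InvalidConfigError("n_background_nodes must be >= 0")
        if not 0.0 <= self.edge_probability <= 1.0:
            raise InvalidConfigError("edge_probability must be in [0, 1]")
        lo, hi = self.score_range
        if not (0 <= lo <= hi <= 1000):
            raise InvalidConfigError("score_range must satisfy 0 <= lo <= hi <= 1000")
        self.seed_genes = tuple(str(s) for s in self.seed_genes)
        bridges = []
        for (a, b), chain in self.planted_bridges:
            a, b = str(a), str(b)
            if a not in self.seed_genes or b not in self.seed_genes:
                raise InvalidConfigError(
                    f"planted bridge endpoints ({a}, {b}) must be declared seed genes")
            bridges.append(((a, b), tuple(str(c) for c in chain)))
        self.planted_bridges = tuple(bridges)


@dataclasses.dataclass
class SimulatedGraph:
    """Generated graph plus the planted bridge-node ground truth."""

    graph: InteractionGraph
    bridge_genes: set[str]
    config: GraphSimConfig


def generate_interaction_graph(config: GraphSimConfig) -> SimulatedGraph:
    """Erdős–Rényi background plus planted seed-to-seed bridge chains.

    Planted chain edges carry the maximum score of ``score_range`` so
    they survive any in-range confidence threshold.  The graph is
    undirected with no self-loops or duplicate edges; identical config
    and seed reproduce the edge list exactly.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    bg_nodes = [f"BG{i + 1:04d}" for i in range(cfg.n_background_nodes)]

    triples: list[tuple[str, str, int]] = []
    lo, hi = cfg.score_range
    for i in range(len(bg_nodes)):
        for j in range(i + 1, len(bg_nodes)):
            if rng.random() < cfg.edge_probability:
                triples.append((bg_nodes[i], bg_nodes[j],
                                int(rng.integers(lo, hi + 1))))

    bridge_genes: set[str] = set()
    for (a, b), chain in cfg.planted_bridges:
        nodes = [a, *chain, b]
        bridge_genes.update(chain)
        for u, v in zip(nodes, nodes[1:]):
            triples.append((u, v, hi))

    graph = build_graph(triples, weight_mode="hop")
    # Seeds with no planted edges still belong to the node set.
    for s in cfg.seed_genes:
        graph.graph.add_node(s)
    logger.info("simulated graph: %d nodes, %d edges, %d planted bridge genes",
                graph.n_nodes, graph.n_edges, len(bridge_genes))
    return SimulatedGraph(graph=graph, bridge_genes=bridge_genes, config=cfg)
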