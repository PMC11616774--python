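"""Gatekeeper classification: rank, select, and score the rank mismatch.

The screening method ranks all nodes on vertex betweenness (VB),
determinative power (DP), and z-transformed connectivity (C).  A node is
*selected* when it ranks within the top ⌈T·n⌉ on **both** VB and DP — T
defaults to 0.73, the threshold that balanced sensitivity and specificity
when the selection was calibrated against exhaustive dynamic-impact labels
on small networks.  Among the selected nodes, the *mismatch*

    mismatch(g) = rank_C(g) − (rank_VB(g) + rank_DP(g)) / 2

is positive when g ranks higher (numerically smaller rank) on the static
impact measures than on connectivity.  Selected nodes with positive mismatch
are *gatekeepers*: sparsely connected components whose perturbation is
nevertheless predicted to reshape the attractor landscape — attractive
intervention targets precisely because they avoid the lethality and
targeting problems of hubs.  Hubs (C ≥ 2.5) are flagged but not excluded: a
hub can also be a gatekeeper.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

from .determinative_power import determinative_power_all
from .interaction_graph import (
    DEFAULT_HUB_THRESHOLD,
    build_interaction_graph,
    connectivity_zscores,
    vertex_betweenness,
)
from .model_io import BooleanNetwork

__all__ = [
    "rank_nodes",
    "ScoreTable",
    "compute_scores",
    "SelectionConfig",
    "select_nodes",
    "compute_mismatch",
    "NodeClass",
    "ClassificationResult",
    "classify",
]


def rank_nodes(values: Mapping[str, float]) -> dict[str, int]:
    """Descending competition ("min") ranking: largest value gets rank 1.

    Ties share the smallest applicable rank; the next distinct value's rank is
    1 + the count of strictly larger values.  Non-finite values are rejected.
    """
    for v, x in values.items():
        if not math.isfinite(x):
            raise ValueError(f"non-finite score for node {v!r}: {x}")
    ordered = sorted(values.values(), reverse=True)
    return {
        v: 1 + sum(1 for y in ordered if y > x) for v, x in values.items()
    }


@dataclass(frozen=True)
class ScoreTable:
    """Per-node structural scores and their rankings (rank 1 = highest)."""

    nodes: tuple[str, ...]
    vb: dict[str, float]
    dp: dict[str, float]
    degree: dict[str, int]
    zscore: dict[str, float]
    rank_vb: dict[str, int]
    rank_dp: dict[str, int]
    rank_z: dict[str, int]

    @property
    def n(self) -> int:
        return len(self.nodes)


def compute_scores(net: BooleanNetwork) -> ScoreTable:
    """Score every node on VB, DP, degree and connectivity z-score."""
    graph = build_interaction_graph(net)
    vb = vertex_betweenness(graph)
    dp = determinative_power_all(net)
    stats = connectivity_zscores(graph)
    return ScoreTable(
        nodes=net.nodes,
        vb=vb,
        dp=dp,
        degree=stats.degrees,
        zscore=stats.zscores,
        rank_vb=rank_nodes(vb),
        rank_dp=rank_nodes(dp),
        rank_z=rank_nodes(stats.zscores),
    )


@dataclass(frozen=True)
class SelectionConfig:
    """Threshold parameters: T as a fraction in (0, 1], hub cutoff on C_i."""

    T: float = 0.73
    hub_threshold: float = DEFAULT_HUB_THRESHOLD

    def __post_init__(self):
        if not 0.0 < self.T <= 1.0:
            raise ValueError(f"selection threshold T must be in (0, 1], got {self.T}")


def _cutoff_rank(T: float, n: int) -> int:
    # ⌈T·n⌉ with guard against float representation noise (e.g. 0.7*10)
    return int(math.ceil(round(T * n, 9)))


def select_nodes(scores: ScoreTable, T: float) -> set[str]:
    """Nodes ranking within the top ⌈T·n⌉ on both VB and DP."""
    if not 0.0 < T <= 1.0:
        raise ValueError(f"selection threshold T must be in (0, 1], got {T}")
    cutoff = _cutoff_rank(T, scores.n)
    return {
        v
        for v in scores.nodes
        if scores.rank_vb[v] <= cutoff and scores.rank_dp[v] <= cutoff
    }


def compute_mismatch(scores: ScoreTable) -> dict[str, float]:
    """rank_C − mean(rank_VB, rank_DP); positive = impactful but sparse."""
    return {
        v: scores.rank_z[v] - (scores.rank_vb[v] + scores.rank_dp[v]) / 2.0
        for v in scores.nodes
    }


class NodeClass(str, Enum):
    GATEKEEPER = "gatekeeper"
    SELECTED_NON_GATEKEEPER = "selected_non_gatekeeper"
    NON_SELECTED = "non_selected"


@dataclass(frozen=True)
class ClassificationResult:
    """Outcome of the screening for one network and one configuration."""

    node_class: dict[str, NodeClass]
    is_hub: dict[str, bool]
    mismatch: dict[str, float]
    #: gatekeepers in descending mismatch order, ties broken by node name
    recommendations: tuple[str, ...]
    config: SelectionConfig = field(default_factory=SelectionConfig)

    @property
    def gatekeepers(self) -> tuple[str, ...]:
        return tuple(
            v for v, c in self.node_class.items() if c is NodeClass.GATEKEEPER
        )


def classify(
    scores: ScoreTable, config: SelectionConfig | None = None
) -> ClassificationResult:
    """Partition nodes into gatekeepers / selected / non-selected.

    A gatekeeper is a selected node with strictly positive mismatch; selected
    nodes with mismatch ≤ 0 are reported but not recommended.  The hub flag
    is an annotation, independent of the class.
    """
    config = config or SelectionConfig()
    selected = select_nodes(scores, config.T)
    mismatch = compute_mismatch(scores)
    stats_z = scores.zscore
    hubs = {v for v, c in stats_z.items() if c >= config.hub_threshold}
    node_class: dict[str, NodeClass] = {}
    for v in scores.nodes:
        if v in selected and mismatch[v] > 0:
            node_class[v] = NodeClass.GATEKEEPER
        elif v in selected:
            node_class[v] = NodeClass.SELECTED_NON_GATEKEEPER
        else:
            node_class[v] = NodeClass.NON_SELECTED
    recommendations = tuple(
        sorted(
            (v for v, c in node_class.items() if c is NodeClass.GATEKEEPER),
            key=lambda v: (-mismatch[v], v),
        )
    )
    return ClassificationResult(
        node_class=node_class,
        is_hub={v: v in hubs for v in scores.nodes},
        mismatch=mismatch,
        recommendations=recommendations,
        config=config,
    )
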