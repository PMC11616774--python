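"""Exhaustive synchronous dynamics: attractors, perturbations, impact.

This module is the ground-truth validator for the structure-based screening.
Under the synchronous scheme every node recomputes its value simultaneously,
so the state space of an n-node network is a deterministic functional graph
on 2^n states whose terminal cycles are the attractors — fixed points or
limit cycles, each interpreted as a biological phenotype.  Because the state
space doubles with every added node, exhaustive enumeration is capped (20
nodes ≈ 10^6 states by default); the structural screening exists precisely
so that large models never need this oracle.

A perturbation pins one node to a constant (0 = knockout, 1 =
overexpression).  The impact of a perturbation is summarized by how
different the perturbed attractor landscape is from the original one: the
fraction of original attractors lost, the number of genuinely new
attractors, and — for each new attractor — its minimal Hamming distance to
any original attractor state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .errors import CapacityError
from .model_io import BooleanNetwork, Rule
from .expressions import Const

__all__ = [
    "synchronous_step",
    "Attractor",
    "AttractorSet",
    "find_attractors",
    "Perturbation",
    "apply_perturbation",
    "ImpactMetrics",
    "impact_metrics",
    "attractors_to_json",
]

MAX_EXHAUSTIVE_NODES = 20


def _compile(net: BooleanNetwork):
    """Per-node (input positions, truth table) for fast integer-state updates."""
    index = {name: i for i, name in enumerate(net.nodes)}
    compiled = []
    for name in net.nodes:
        rule = net.rules[name]
        compiled.append(([index[g] for g in rule.inputs], rule.table))
    return compiled


def _step_int(compiled, state: int) -> int:
    nxt = 0
    for i, (positions, table) in enumerate(compiled):
        b = 0
        for j, pos in enumerate(positions):
            b |= ((state >> pos) & 1) << j
        nxt |= table[b] << i
    return nxt


def _int_to_tuple(state: int, n: int) -> tuple[int, ...]:
    return tuple((state >> i) & 1 for i in range(n))


def synchronous_step(
    net: BooleanNetwork, state: Sequence[int]
) -> tuple[int, ...]:
    """One synchronous update: every node reads the *current* state."""
    if len(state) != net.n:
        raise ValueError(
            f"state length {len(state)} does not match network size {net.n}"
        )
    compiled = _compile(net)
    packed = 0
    for i, v in enumerate(state):
        if v not in (0, 1):
            raise ValueError(f"state entries must be 0/1, got {v!r}")
        packed |= v << i
    return _int_to_tuple(_step_int(compiled, packed), net.n)


@dataclass(frozen=True)
class Attractor:
    """A terminal cycle of the synchronous dynamics, in canonical rotation.

    ``states`` is the cyclic sequence rotated so the lexicographically
    smallest state comes first; consecutive states (wrapping) are one
    synchronous step apart.
    """

    states: tuple[tuple[int, ...], ...]

    def __post_init__(self):
        if not self.states:
            raise ValueError("attractor must contain at least one state")

    @property
    def length(self) -> int:
        return len(self.states)

    @property
    def state_set(self) -> frozenset[tuple[int, ...]]:
        return frozenset(self.states)


def _canonical(cycle: list[tuple[int, ...]]) -> Attractor:
    k = cycle.index(min(cycle))
    return Attractor(tuple(cycle[k:] + cycle[:k]))


@dataclass(frozen=True)
class AttractorSet:
    """All attractors of one network, with basin sizes (states per basin)."""

    nodes: tuple[str, ...]
    attractors: tuple[Attractor, ...]
    basin_sizes: dict[Attractor, int]

    def __len__(self) -> int:
        return len(self.attractors)


def find_attractors(
    net: BooleanNetwork, max_nodes: int = MAX_EXHAUSTIVE_NODES
) -> AttractorSet:
    """Enumerate every synchronous attractor by full state-space traversal.

    Walks each of the 2^n states forward with memoized basin assignment, so
    every state is visited O(1) times.  Refuses networks larger than
    *max_nodes* — the state space grows as 2^n, and this oracle is meant for
    validation, not production screening.
    """
    n = net.n
    if n > max_nodes:
        raise CapacityError(
            f"network has {n} nodes; exhaustive attractor search is capped at "
            f"{max_nodes} (2^{max_nodes} states). Use the structural screening "
            "for larger models."
        )
    compiled = _compile(net)
    size = 1 << n
    assignment = [-1] * size  # attractor index per state; -2 marks "on path"
    attractors: list[Attractor] = []
    basins: list[int] = []
    for start in range(size):
        if assignment[start] != -1:
            continue
        path: list[int] = []
        s = start
        while assignment[s] == -1:
            assignment[s] = -2
            path.append(s)
            s = _step_int(compiled, s)
        if assignment[s] == -2:  # new cycle discovered on this path
            cycle_start = path.index(s)
            cycle = [_int_to_tuple(x, n) for x in path[cycle_start:]]
            attractors.append(_canonical(cycle))
            basins.append(0)
            target = len(attractors) - 1
        else:
            target = assignment[s]
        for x in path:
            assignment[x] = target
        basins[target] += len(path)
    order = sorted(range(len(attractors)), key=lambda i: attractors[i].states)
    ordered = tuple(attractors[i] for i in order)
    basin_sizes = {attractors[i]: basins[i] for i in order}
    return AttractorSet(nodes=net.nodes, attractors=ordered, basin_sizes=basin_sizes)


@dataclass(frozen=True)
class Perturbation:
    """Pin one node to a constant: 0 = knockout, 1 = overexpression."""

    node: str
    value: int

    def __post_init__(self):
        if self.value not in (0, 1):
            raise ValueError("perturbation value must be 0 (KO) or 1 (OE)")


def apply_perturbation(net: BooleanNetwork, p: Perturbation) -> BooleanNetwork:
    """Return a copy of *net* with the perturbed node's rule made constant."""
    if p.node not in net.rules:
        raise ValueError(f"unknown node {p.node!r}")
    rules = dict(net.rules)
    rules[p.node] = Rule((), Const(p.value), (p.value,))
    return BooleanNetwork(net.nodes, rules)


def _hamming(a: tuple[int, ...], b: tuple[int, ...]) -> int:
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class ImpactMetrics:
    """Attractor-landscape change caused by a perturbation.

    ``fraction_lost`` — share of original attractors with no identical
    (state-set equal, all n coordinates) counterpart after perturbation;
    ``n_new`` — perturbed attractors with no identical original counterpart;
    ``min_hamming`` — per new attractor, the minimal Hamming distance from
    any of its states to any state of any original attractor.  Large values
    of all three mean the perturbation replaced the landscape with a
    genuinely different one.
    """

    fraction_lost: float
    n_new: int
    min_hamming: tuple[int, ...]


def impact_metrics(original: AttractorSet, perturbed: AttractorSet) -> ImpactMetrics:
    """Compare two attractor landscapes over the same node universe."""
    if original.nodes != perturbed.nodes:
        raise ValueError("attractor sets belong to different node universes")
    orig_sets = {a.state_set for a in original.attractors}
    pert_sets = {a.state_set for a in perturbed.attractors}
    lost = sum(1 for s in orig_sets if s not in pert_sets)
    new = [a for a in perturbed.attractors if a.state_set not in orig_sets]
    orig_states = [s for a in original.attractors for s in a.states]
    min_hamming = tuple(
        min(_hamming(s, t) for s in a.states for t in orig_states) for a in new
    )
    return ImpactMetrics(
        fraction_lost=lost / len(orig_sets),
        n_new=len(new),
        min_hamming=min_hamming,
    )


def attractors_to_json(aset: AttractorSet) -> list[list[str]]:
    """Attractors as lists of bit-strings in node order (JSON-friendly)."""
    return [
        ["".join(str(b) for b in state) for state in a.states]
        for a in aset.attractors
    ]
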