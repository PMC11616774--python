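"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's algorithms (and networkx): betweenness
is computed by explicit per-pair BFS path enumeration, mutual information by
tabulating the joint distribution, and attractors by building the full
state-transition map and walking it.
"""

from __future__ import annotations

import math
from collections import deque


def bfs_betweenness(nodes, edges) -> dict:
    """Fractional betweenness by explicit shortest-path enumeration.

    For every ordered pair (s, t) all shortest s→t paths are enumerated via
    BFS layering and recursive predecessor expansion; each intermediate node
    of each path receives 1/σ_st.
    """
    adj = {v: [] for v in nodes}
    for u, v in edges:
        if u != v and v not in adj[u]:
            adj[u].append(v)
    score = {v: 0.0 for v in nodes}
    for s in nodes:
        dist = {s: 0}
        preds = {v: [] for v in nodes}
        queue = deque([s])
        while queue:
            u = queue.popleft()
            for w in adj[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    queue.append(w)
                if dist[w] == dist[u] + 1:
                    preds[w].append(u)

        def paths_to(v):
            if v == s:
                return [[s]]
            return [p + [v] for u in preds[v] for p in paths_to(u)]

        for t in nodes:
            if t == s or t not in dist:
                continue
            all_paths = paths_to(t)
            for path in all_paths:
                for inner in path[1:-1]:
                    score[inner] += 1.0 / len(all_paths)
    return score


def _entropy(p: float) -> float:
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return -p * math.log2(p) - (1 - p) * math.log2(1 - p)


def joint_mi(table, input_index: int) -> float:
    """MI between input bit *input_index* and the function output.

    Tabulates the joint distribution of (x_g, f) over all 2^k equiprobable
    input assignments and applies MI = Σ p log2(p / (p_x p_f)).
    """
    k_total = len(table)
    joint = {(x, f): 0.0 for x in (0, 1) for f in (0, 1)}
    for b, f in enumerate(table):
        x = (b >> input_index) & 1
        joint[(x, int(f))] += 1.0 / k_total
    px = {x: joint[(x, 0)] + joint[(x, 1)] for x in (0, 1)}
    pf = {f: joint[(0, f)] + joint[(1, f)] for f in (0, 1)}
    mi = 0.0
    for (x, f), p in joint.items():
        if p > 0:
            mi += p * math.log2(p / (px[x] * pf[f]))
    return mi


def state_graph_attractors(net) -> set[frozenset]:
    """Attractors as frozensets of state tuples, from the full transition map.

    Builds next(s) for every state, then follows each state 2^n steps to
    guarantee arrival on a cycle, and extracts the cycle by repeated stepping.
    """
    n = net.n
    names = net.nodes
    size = 2**n

    def step(state):
        env = dict(zip(names, state))
        return tuple(
            net.rules[v].expr.evaluate(env) if net.rules[v].inputs
            else net.rules[v].table[0]
            for v in names
        )

    nxt = {}
    for b in range(size):
        s = tuple((b >> i) & 1 for i in range(n))
        nxt[s] = step(s)
    attractors = set()
    for s in nxt:
        cur = s
        for _ in range(size):
            cur = nxt[cur]
        cycle = [cur]
        t = nxt[cur]
        while t != cur:
            cycle.append(t)
            t = nxt[t]
        attractors.add(frozenset(cycle))
    return attractors
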