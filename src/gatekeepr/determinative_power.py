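"""Determinative power: mutual information a node carries about its targets.

Under independent uniform Bernoulli(1/2) inputs — the standard assumption in
the determinative-power literature — the mutual information between a
regulator's state x_g and a target's update function f_h is

    MI(x_g; f_h) = H(f_h) − ½·H(f_h | x_g = 0) − ½·H(f_h | x_g = 1)

with H the binary Shannon entropy (bits).  A node's determinative power is
the sum of these MI values over all rules that list it as an input
(self-loops included); it quantifies how strongly knowledge of the node's
state pins down the next state of its outputs, without any simulation of the
dynamics.
"""

from __future__ import annotations

import math

from .model_io import BooleanNetwork

__all__ = [
    "binary_entropy",
    "mutual_information",
    "determinative_power",
    "determinative_power_all",
]


def binary_entropy(p: float) -> float:
    """H(p) = −p·log2 p − (1−p)·log2(1−p), with 0·log2 0 := 0."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability must lie in [0, 1], got {p}")
    if p in (0.0, 1.0):
        return 0.0
    return -p * math.log2(p) - (1.0 - p) * math.log2(1.0 - p)


def mutual_information(net: BooleanNetwork, g: str, h: str) -> float:
    """MI (bits) between regulator *g*'s state and target *h*'s update value.

    Probabilities are exact, obtained by enumerating h's truth table under
    uniform inputs.  Raises ``ValueError`` unless g is an input of h's rule.
    """
    rule = net.rules.get(h)
    if rule is None:
        raise ValueError(f"unknown node {h!r}")
    if g not in rule.inputs:
        raise ValueError(f"{g!r} is not an input of {h!r}'s rule")
    j = rule.inputs.index(g)
    table = rule.table
    ones = [0, 0]  # count of table[b] == 1, split by bit j of b
    size = len(table) // 2
    for b, value in enumerate(table):
        ones[(b >> j) & 1] += value
    p_total = (ones[0] + ones[1]) / len(table)
    h_f = binary_entropy(p_total)
    h_cond = 0.5 * binary_entropy(ones[0] / size) + 0.5 * binary_entropy(
        ones[1] / size
    )
    return max(0.0, h_f - h_cond)


def determinative_power(net: BooleanNetwork, g: str) -> float:
    """DP(g) = Σ_h MI(x_g; f_h) over all rules with g as an input (bits).

    Self-loops contribute; a node regulating nothing has DP = 0.
    """
    if g not in net.rules:
        raise ValueError(f"unknown node {g!r}")
    total = 0.0
    for h in net.nodes:
        if g in net.rules[h].inputs:
            total += mutual_information(net, g, h)
    return total


def determinative_power_all(net: BooleanNetwork) -> dict[str, float]:
    """DP for every node, in one pass over the rules."""
    dp = {v: 0.0 for v in net.nodes}
    for h in net.nodes:
        for g in net.rules[h].inputs:
            dp[g] += mutual_information(net, g, h)
    return dp
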