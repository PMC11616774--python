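"""Random Boolean networks and curated fixtures for testing and examples.

The generator produces classic N-K random Boolean networks: each node draws
k distinct regulators uniformly (self-inputs allowed) and an i.i.d.
Bernoulli(bias) truth table.  All randomness flows through one explicitly
seeded generator — identical configurations yield identical networks.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .model_io import BooleanNetwork, Rule, expression_from_table, parse_boolnet

__all__ = ["GeneratorConfig", "random_boolean_network", "fixture", "FIXTURE_NAMES"]


@dataclass(frozen=True)
class GeneratorConfig:
    """N-K random network parameters.

    n — node count; k — regulators per node; bias — probability that a truth
    table entry is 1; seed — generator seed (all randomness derives from it).
    """

    n: int
    k: int
    bias: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 1 <= self.k <= self.n:
            raise ValueError(f"k must satisfy 1 <= k <= n, got k={self.k}, n={self.n}")
        if not 0.0 <= self.bias <= 1.0:
            raise ValueError("bias must lie in [0, 1]")


def random_boolean_network(config: GeneratorConfig) -> BooleanNetwork:
    """Draw an N-K random Boolean network from *config*.

    Rule expressions are synthesized from the sampled truth tables so that
    every drawn input appears syntactically (round-trip through the BoolNet
    text format preserves input sets and tables).
    """
    rng = np.random.default_rng(config.seed)
    names = tuple(f"n{i}" for i in range(1, config.n + 1))
    rules: dict[str, Rule] = {}
    for name in names:
        picks = rng.choice(config.n, size=config.k, replace=False)
        inputs = tuple(names[i] for i in sorted(picks))
        table = tuple(int(v) for v in rng.random(2**config.k) < config.bias)
        rules[name] = Rule(inputs, expression_from_table(inputs, table), table)
    return BooleanNetwork(names, rules)


FIXTURE_NAMES = ("toggle", "negator", "chain3", "diamond", "star8", "bottleneck12")


def fixture(name: str) -> BooleanNetwork:
    """Load a hand-written fixture network shipped with the package.

    Catalogue:

    * ``toggle`` — two nodes copying each other (A=B, B=A).
    * ``negator`` — one self-inhibiting node (A = !A), a period-2 oscillator.
    * ``chain3`` — linear cascade a → b → c.
    * ``diamond`` — two parallel shortest paths a→b→d and a→c→d.
    * ``star8`` — one source feeding 8 leaves; the center is a hub
      (C ≈ 2.83 ≥ 2.5).
    * ``bottleneck12`` — two dense 5/6-node clusters joined only through a
      degree-2 bridge node; the bridge carries every cross-cluster shortest
      path and fully determines its single target, so the screening should
      recommend it first.
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        )
    text = (
        resources.files("gatekeepr").joinpath(f"data/{name}.bn").read_text("utf-8")
    )
    return parse_boolnet(text)


def fixture_path(name: str):
    """Filesystem path of a fixture's BoolNet file (for CLI examples/tests)."""
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}")
    return resources.files("gatekeepr").joinpath(f"data/{name}.bn")
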