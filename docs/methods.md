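# Methods

## Model and scope

The package analyses synchronous Boolean networks `x(t+1) = f(x(t))` on
`B^n`: every node has an update rule given as a logical expression (AND, OR,
NOT, constants) over an ordered list of distinct inputs, compiled to a truth
table at load time.  Multi-valued logical models (levels > 1) and
probabilistic or temporal rule extensions are explicitly rejected, never
silently coerced.

**Truth-table bit order.**  `table[b]` is the rule value when input *j*
carries bit *j* of *b* — the first listed input is the least-significant
bit.  Neither supported file format fixes this convention, so it is pinned
by tests and observable through `compile_truth_table`.

**Formats.**  BoolNet text (`targets, factors` header; `#` comments; blank
lines ignored; case-sensitive identifiers) and SBML Level 3 qual restricted
to `maxLevel ≤ 1`.  For SBML the species *id* (unique by schema) is the node
name; a transition's function terms are evaluated exhaustively over all
input assignments, with the `defaultTerm` supplying uncovered assignments;
species without a transition become constants at their `initialLevel`
(0 when unset) — the natural reading of a qual document, chosen here because
the format itself leaves it open.  Rule expressions reconstructed from
truth tables (SBML import, random generation) are full-minterm DNF with a
constant guard (`0 & x & …` / `1 | x | …`) so that every declared input
appears syntactically; this keeps write→parse round-trips exact on input
sets as well as tables, at the cost of verbose expressions for dense rules.

## Structural scores

- **Vertex betweenness**: Brandes/Freeman fractional betweenness on the
  directed, unweighted interaction graph, endpoints excluded, unnormalized
  (computed via networkx; an independent per-pair BFS path-enumeration
  oracle checks it exactly in the tests).  Fractional rather than integral
  path counting is the standard definition in the ecosystem this method
  originates from.  Self-loops never lie on shortest paths and are ignored.
- **Connectivity z-score**: `C_i = (δ_i − δ̄)/σ` with δ_i the total degree
  (a self-loop adds 1 in and 1 out) and σ the *population* standard
  deviation — the hub literature does not disambiguate population vs sample;
  population was chosen and pinned.  On degree-regular graphs σ = 0 and all
  `C_i` are defined as 0, so no hubs exist — this avoids a 0/0 rather than
  inventing one.  The hub cutoff `C_i ≥ 2.5` is a closed inequality.
- **Determinative power**: `DP(g) = Σ_h MI(x_g; f_h)` in bits, probabilities
  enumerated exactly from truth tables under independent Bernoulli(1/2)
  inputs — the standard assumption of the determinative-power literature.
  Self-loop edges contribute to the sum (a deliberate choice, pinned by
  tests).  Syntactically present but non-essential inputs contribute MI = 0
  automatically, so no essentiality pruning is performed.  Tiny negative MI
  from float cancellation is clamped to 0.

## Selection and classification

Ranking is descending competition ranking (ties share the minimal rank), so
boundary ties at the cutoff are all-in.  A node is selected iff its VB rank
and DP rank are both `≤ ⌈T·n⌉`; T defaults to 0.73, the threshold reported
to balance sensitivity and specificity when the selection was calibrated
against exhaustive dynamic-impact labels, and is exposed as a percentage at
the CLI.  The ceiling is computed on `round(T·n, 9)` to keep exact products
(e.g. 0.7·10) from drifting across the integer boundary.

The mismatch combines the two static ranks by arithmetic mean,
`rank_C − (rank_VB + rank_DP)/2`; mean rather than min or sum because it is
symmetric in the two measures and keeps the mismatch on the rank scale.
Gatekeeper membership requires *strictly* positive mismatch.  Hubs are
annotations, never exclusions — a hub can simultaneously be a gatekeeper
(rendered purple in graph exports).  Recommendation order is descending
mismatch with deterministic node-name tie-break.

## Dynamics oracle

Exhaustive synchronous attractor search walks all 2^n states with memoized
basin assignment (each state visited O(1) times) and is capped at 20 nodes
(~10^6 states) with an explicit capacity error: the structural screening
exists precisely because this computation is exponential, so the oracle is a
validation device.  Attractors are stored in canonical rotation
(lexicographically smallest state first), making equality and set membership
well-defined.  Attractor identity across original and perturbed networks
compares full n-dimensional state sets including the perturbed coordinate —
the stricter, unambiguous option.  Impact metrics report raw
`fraction_lost`, `n_new`, and per-new-attractor minimal Hamming distance;
no composite "high impact" label is derived, since any such label would
need weights this package has no basis to set.  Basin sizes are computed
and exposed but are not part of the impact metrics.

## Synthetic networks

The generator produces N-K random Boolean networks: k distinct regulators
per node drawn uniformly (self-inputs allowed, as real models routinely
contain self-loops) and i.i.d. Bernoulli(bias) truth-table entries,
default bias 0.5 — the classic unbiased ensemble.  All randomness flows
through a single numpy generator seeded from the config; identical configs
give identical networks.  With bias 0 or 1 the dynamics are analytically
known (a single constant fixed point), which cross-checks the attractor
oracle.

What the ensemble does *not* emulate: scale-free or otherwise heterogeneous
in-degree distributions, canalizing rule biases, and the modular topology of
curated biological models.  Passing tests on this ensemble therefore
demonstrate correctness of the computations, not biological performance of
the screening; the `bottleneck12` fixture is engineered (two dense clusters
joined by a single low-degree bridge) to exhibit the gatekeeper signature by
construction.

## Problem sizes and numerical choices

Oracle cross-checks run on 50 seeded random instances per quantity — graphs
of n ≤ 10 for betweenness (exact agreement within 1e-9 absolute, covering
float accumulation), rules of k ≤ 4 for mutual information (1e-12), and
networks of n ≤ 8 for attractors (exact set equality) — sizes at which the
brute-force oracles are unquestionably correct yet the runs complete in
seconds.  Graph exports use linear attribute scalings (opacity from 1.0 for
the top recommendation down to 0.4 for the last; node width 0.3 + 0.1·δ):
the original visualization's exact scalings are presentation choices, and
rendering is delegated to DOT/GraphML consumers.

## Known limitations

- Exhaustive dynamics only; no SAT/BDD attractor search and no asynchronous
  update schemes.
- Edge signs (activation/inhibition) are not annotated; centralities are
  unweighted.
- DP assumes uniform independent inputs; biased or empirically estimated
  state distributions are out of scope.
- The selection threshold default is taken as given, not re-derived.
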