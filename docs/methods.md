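# Methods

This note documents the models implemented in `emphybrid`, their
assumptions, the defaults that matter, and the design choices made where
the design was genuinely open.

## Topology model

A GRN is a signed directed graph: nodes are genes, an edge `j → i` carries
sign +1 (activation) or −1 (inhibition) and a weight in (0, 1] (1 unless a
weighted variant is constructed).  At most one edge per ordered pair;
self-loops are allowed (the MISSA motif requires self-activation).  The
interaction matrix `J` is oriented row = target, column = source:
`J[i, j] = sign · weight` of the edge `j → i`.  I/O uses the RACIPE
`.topo` convention (`Source Target Type`, Type 1/2), extended with an
optional `Weight` column that is only written when a weight differs from 1.

**Signal nodes** are nodes with no incoming edge from *other* nodes (a
pure self-loop does not disqualify).  They carry no steady-state
information — in the ODE engine they settle at P/D, in the Boolean engine
they freeze at their initial bit — and are trimmed from reported state
strings.  Their *outgoing* edges still count for frustration, which divides
by the total edge count.

## Random-parameter ODE ensemble

Each gene follows

    dX_i/dt = P_i · Π_{j→i} H^S(X_j; Y0_ji, n_ji, λ_ji) − D_i · X_i

with the shifted Hill multiplier `H^S(x) = λ + (1 − λ)/(1 + (x/x₀)ⁿ)`
(`H^S(0) = 1`, `H^S → λ`; λ < 1 represses, λ > 1 activates).  Multiple
regulators combine multiplicatively.

Sampling defaults (all config-exposed through `SamplingConfig`):

| parameter | range | note |
| --- | --- | --- |
| production P | [1, 100] (conc/time) | uniform |
| degradation D | [0.1, 1] (1/time) | uniform |
| fold change λ⁻ (inhibition) | (0.01, 1] | reciprocal of a uniform draw on [1, 100]: repression *strength* 1/λ is uniform, so repression is typically strong |
| fold change λ⁺ (activation) | [1, 100] | uniform |
| Hill coefficient n | integers 1..6 | uniform |
| threshold Y0 | [0.02, 1.98] × M | M = P_src/D_src of the same parameter set (the regulator's unregulated level) |

A truncated-Gaussian option (mid-range mean, SD = range/4, truncated at the
range bounds) exists for all continuous parameters.  The reciprocal-uniform
rule for λ⁻ matters: with λ⁻ sampled flat on (0.01, 1], half the inhibitory
edges barely repress, the ensemble decouples, and both multistability and
the node–node correlation structure collapse.

Integration is forward Euler with step `dt = 0.1`, run in up to 20
windows of 50 time units; a run is converged when its node-wise change
across one window falls below the cutoff 1.0 (the same 1.0 is the merge
tolerance for calling two states of one parameter set distinct).  Levels
are clipped at 0; NaN/overflow marks the run unconverged.  Initial
conditions are uniform on [0, 1.5·P/D] per node.  The inner loop is
JIT-compiled with numba when available; a pure-numpy path gives identical
results (cross-checked to 1e-13) and is used otherwise.

**Binarization** is z-score per node over all converged runs of a repeat
(Z > 0 → 1), with no log transform by default; a `log2_transform` option
exists for pipelines whose upstream tooling emits log-scale levels.  A node
with zero variance is an error naming the node.  Frequencies are fractions
of converged runs, renormalized; the three independent repeats are averaged
at the distribution level and renormalized.  **Multistability** is the
fraction of parameter sets with more than one distinct merged state,
averaged over repeats.

## Asynchronous threshold Boolean engine

State bits evolve by `S_i ← 1 if Σ_j J_ij σ_j > 0, 0 if < 0, hold at 0`,
with one uniformly random node updated per step.  The default `ising`
convention maps bits to spins σ ∈ {−1, +1} before the sum — this matches
the spin-model lineage of the update rule and avoids the all-zero state
being trivially fixed; the `literal01` convention (σ = S ∈ {0, 1}, inactive
regulators contribute nothing) is retained as a flag because the threshold
equation is sometimes written that way.  The two conventions genuinely
disagree and are never merged.

A run is a fixed point when the state is invariant under the update of
*every* node (checked exactly, not by quiescence).  Runs not fixed after
`max_steps = 1000` are excluded and frequencies renormalized over converged
runs — networks whose only attractors are cyclic (e.g. a pure negative
3-cycle) therefore raise rather than fabricate a distribution.  Weighted
networks use the same code path through the weighted interaction matrix.

## Phenotype scoring

Node partitioning clusters the rows of the node–node Pearson correlation
matrix (steady-state levels across runs for the ODE engine;
frequency-weighted fixed-point bits for the Boolean engine) with Euclidean
distance and complete linkage, cut at two clusters.  Cluster labels come
from anchor nodes (known markers, e.g. miR200 → E); with no anchors the
cluster holding the lexicographically first node is labelled E and a
warning is logged — label choice does not affect hybridness, which is
symmetric under label swap.

EMT score of a binarized state = mean E bit − mean M bit ∈ [−1, 1];
a state is hybrid when |score| ≤ 0.5 (boundary inclusive), else E/M by
sign.  Hybridness = total frequency of hybrid states.

Jensen–Shannon divergence uses log base 2 on the union support with
zero-fill, so values lie in [0, 1]; it is computed as the square of scipy's
JS distance.  The J metric is the strict upper-triangle sum of the
correlation matrix.  Frustration of a full state maps bits to spins
(0 → −1) and counts edges with `sign(J)·σ_src·σ_tgt = −1` over total edges;
network frustration reports min/mean/max over the distinct steady states
(mean unweighted by default — each state counts once — with a
frequency-weighted option).

## Topology metrics

Directed simple cycles are enumerated exactly (networkx) for networks up to
30 nodes; above that a default length cap of 10 applies and the census is
flagged `capped`.  A loop is positive iff it has an even number of negative
edges.  Weighted loop counts weight each loop by its edge count (a
1/length option exists; the direction of downstream correlations does not
disambiguate the two readings, so both are available).  Predicted
frustration counts negative loops of length ≤ 6.

The influence matrix accumulates signed adjacency powers,
`(1/l_max) Σ_{l=1..l_max} A^l ./ A_max^l` with 0/0 := 0 and `A_max` the
unsigned binarization of A; `l_max` defaults to 10.  Pairwise feedback
strength is `I_ij · I_ji` summed per sign over unordered pairs.

HiLoop censuses count instances, not presence, so they can be correlated
with hybridness: Type-I = unordered triples of distinct positive loops
sharing a common node; Type-II = unordered triples of pairwise
edge-disjoint positive loops where one loop hosts two nodes u, v and the
other two attach at u (avoiding v) and v (avoiding u); MISSA = mutually
inhibiting pairs with a self-activation on either partner (a looser
reading — either partner on any other positive loop — is behind a flag).

Inconsistency operates on the underlying undirected signed multigraph
(antiparallel edge pairs are kept as distinct parallel edges; self-loops are
excluded as they lie on no undirected cycle with other edges).  The default
cycle space is a fundamental cycle basis — a signed graph is balanced iff
every basis cycle is positive, so the zero/nonzero decision is exact while
staying polynomial; the basis is built by hand because library cycle bases
drop parallel-edge identity, which signed 2-cycles need.  The greedy flips
the edge on the most currently-negative cycles (ties: fewest positive
cycles disturbed, then edge order); in basis mode, when that edge would not
shrink the negative set, the fallback flips the edge with the largest net
reduction — a fundamental basis always offers one, so termination is
guaranteed.  An `all_simple_capped` mode reproduces the enumerate-all-loops
procedure literally (each edge flipped at most once).  Greedy may exceed
the true minimum; tests verify it never undercounts against exhaustive
search.

## Experiments

A perturbation sweep simulates the wild type and its 2E single-edge
variants (every deletion, every sign flip).  The scored node set and the
E/M partition are fixed from the wild type and reused for all variants so
EMT scores and JSD supports stay comparable (a deletion can turn a node
into a signal node; re-trimming per variant would silently change the state
space).  Variants whose simulation fails (e.g. a sign flip leaves only
cyclic attractors) stay in the table flagged with the error, their topology
metrics still computed.  Correlation reports use Spearman rank correlation
with average ranks, two-sided p, significance marked at p < 0.05, no
multiple-testing correction; constant metrics are reported missing, never
as 0.  Randomization percentiles place the wild-type metric among
degree-preserving double-edge-swap rewirings (signs ride with their edges;
an option shuffles the sign multiset instead), with the midpoint tie rule.
Note that small dense circuits can be rigid — the 4-node example network
admits no legal swap at all — so percentile analysis targets networks of
roughly 8 nodes and up.

## Synthetic data

The generators produce the statistical class the analysis targets: small
signed digraphs (4–60 nodes, ~1.5–4 edges/node), mixed signs, a few
input-only nodes.  `generate_random_grn` draws uniform distinct ordered
pairs with i.i.d. signs.  `generate_team_grn` plants the two-team
organisation characteristic of EMP circuits — two node groups with
activation within a group and inhibition across — and returns the planted
split; `tune_loop_composition` then hill-climbs single-edge sign flips
toward a target positive-loop fraction.  The directionality experiment
generates team networks tuned across pfl_fraction ∈ [0, 1], simulates each
with the Boolean engine (4000 initial conditions), and scores hybridness
against the planted partition.  Team structure is essential: on plain
uniform-random digraphs hybridness degenerates into a count of arbitrary
mid-score fixed points and carries no loop-composition signal.  The
experiment uses 100 networks because the underlying effect is modest
(population Spearman ≈ −0.2 for pfl_fraction in pilot runs): at that size
the sign of both correlations is stable across seeds.

What the synthetic ensemble does **not** emulate: biological degree
distributions, autoregulation frequencies, or curated marker identities.
Passing the directionality checks shows the metrics and engines interact as
designed on the intended network class, not that any particular biological
network behaves this way.

## Problem sizes

Published protocols of this kind run 10,000 parameter sets × 100 initial
conditions (ODE) and 100,000 initial conditions (Boolean), three repeats
each.  Those sizes are reachable through configuration; the defaults used
by the test suite and `scripts/acceptance.py` are scaled working sizes
(ODE: 1000–2000 sets × 10–20 ICs; Boolean: 2000–20,000 ICs) chosen so the
full pipeline runs in minutes on one CPU.  Consequences worth knowing:
Spearman correlations from a 4-node sweep rest on 14–15 variants and carry
wide sampling variability (their sign can flip between seeds for weak
effects like the J metric); the directionality experiment's correlations
are stable at its 100-network size.

## Known limitations

- The greedy inconsistency is an upper bound, not the frustration index;
  no ILP/exact solver is provided.
- Exhaustive cycle enumeration is exponential; large networks are
  length-capped by default and the censuses say so.
- Only fixed points enter Boolean phenotype distributions; cyclic
  attractors are recorded as non-convergence.
- No stochastic (Langevin) dynamics, no bifurcation continuation, no
  transcriptomic EMT scoring.
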