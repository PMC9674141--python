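"""Synthetic regulatory topologies with the statistical structure of EMP networks.

Real epithelial–mesenchymal plasticity circuits are small-to-medium signed
digraphs (4–60 nodes, roughly 1.5–4 edges per node), mix activation and
inhibition, carry a few input-only "signal" nodes, and are organised around
two mutually antagonistic groups of genes.  The generators here emulate that
class so every downstream stage — both simulation engines, all metrics, the
perturbation experiments — can be exercised on reproducible inputs, and ship
a handful of exact analytic fixtures whose loop structure is known by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .topology import GRNTopology

__all__ = [
    "SyntheticSpec",
    "make_fixture",
    "generate_random_grn",
    "generate_team_grn",
    "tune_loop_composition",
]

FIXTURE_NAMES = ("toggle", "toggle_missa", "repressilator", "emt_core", "type1_hub")


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one random signed digraph.

    Attributes
    ----------
    n_nodes, n_edges
        Graph size; edges are distinct ordered pairs (self-loops excluded
        from random placement).
    p_inhibition
        Per-edge probability of sign −1.
    n_signal
        Number of input-only nodes; these are placed first in node order so
        trimmed state strings are stable.
    target_pfl_fraction
        Optional target for :func:`tune_loop_composition` post-processing.
    seed
        Seed for all randomness.
    """

    n_nodes: int
    n_edges: int
    p_inhibition: float = 0.5
    n_signal: int = 0
    target_pfl_fraction: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_inhibition <= 1.0):
            raise ValueError("p_inhibition must lie in [0, 1]")
        if self.n_signal >= self.n_nodes:
            raise ValueError("n_signal must be smaller than n_nodes")


def make_fixture(name: str) -> GRNTopology:
    """Small named circuits with known loop structure.

    ``toggle``
        Mutual inhibition A⊣B, B⊣A — one positive loop, the canonical
        bistable switch.
    ``toggle_missa``
        Toggle plus a self-activation A→A: exactly one
        mutual-inhibition-single-self-activation (MISSA) motif.
    ``repressilator``
        Three-cycle of inhibitions A⊣B⊣C⊣A — one negative loop, no fixed
        point under the threshold update.
    ``emt_core``
        A documented 4-node EMT-like circuit over miR200, ZEB, GRHL2 and
        SNAIL (7 edges): the mutual miR200⊣ZEB / ZEB⊣miR200 toggle, the
        mutual ZEB⊣GRHL2 / GRHL2⊣ZEB antagonism, SNAIL activating ZEB and
        inhibiting miR200, and ZEB self-activation.  This is an
        approximation of the published smallest EMP network, not a
        transcription of it.
    ``type1_hub``
        A hub node H on three otherwise disjoint mutual-activation loops —
        exactly one Type-I HiLoop.
    """
    if name == "toggle":
        return GRNTopology.from_edges("toggle", [("A", "B", -1), ("B", "A", -1)])
    if name == "toggle_missa":
        return GRNTopology.from_edges(
            "toggle_missa", [("A", "B", -1), ("B", "A", -1), ("A", "A", 1)]
        )
    if name == "repressilator":
        return GRNTopology.from_edges(
            "repressilator", [("A", "B", -1), ("B", "C", -1), ("C", "A", -1)]
        )
    if name == "emt_core":
        return GRNTopology.from_edges(
            "emt_core",
            [
                ("miR200", "ZEB", -1),
                ("ZEB", "miR200", -1),
                ("ZEB", "GRHL2", -1),
                ("GRHL2", "ZEB", -1),
                ("SNAIL", "ZEB", 1),
                ("SNAIL", "miR200", -1),
                ("ZEB", "ZEB", 1),
            ],
            nodes=("miR200", "ZEB", "GRHL2", "SNAIL"),
        )
    if name == "type1_hub":
        return GRNTopology.from_edges(
            "type1_hub",
            [
                ("H", "P1", 1),
                ("P1", "H", 1),
                ("H", "P2", 1),
                ("P2", "H", 1),
                ("H", "P3", 1),
                ("P3", "H", 1),
            ],
        )
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")


def generate_random_grn(spec: SyntheticSpec) -> GRNTopology:
    """Uniform random signed digraph under a :class:`SyntheticSpec`.

    Edges are drawn uniformly without replacement from the ordered node
    pairs whose target is not a signal node (and that are not self-loops);
    each edge is inhibitory with probability ``p_inhibition``.
    """
    rng = np.random.default_rng(spec.seed)
    nodes = [f"G{i+1}" for i in range(spec.n_nodes)]
    signal = set(nodes[: spec.n_signal])
    pairs = [
        (s, t)
        for s in nodes
        for t in nodes
        if s != t and t not in signal
    ]
    if spec.n_edges > len(pairs):
        raise ValueError(
            f"{spec.n_edges} edges requested but only {len(pairs)} legal ordered pairs"
        )
    chosen = rng.choice(len(pairs), size=spec.n_edges, replace=False)
    signs = np.where(rng.random(spec.n_edges) < spec.p_inhibition, -1, 1)
    edges = [(*pairs[k], int(s)) for k, s in zip(chosen, signs)]
    net = GRNTopology.from_edges(
        f"rand{spec.n_nodes}N{spec.n_edges}E_s{spec.seed}", edges, nodes=nodes
    )
    if spec.target_pfl_fraction is not None:
        net = tune_loop_composition(
            net, spec.target_pfl_fraction, max_iters=10 * spec.n_edges, seed=spec.seed
        )
    return net


def generate_team_grn(spec: SyntheticSpec) -> tuple[GRNTopology, frozenset[str]]:
    """Random digraph with the two-team sign structure of EMP networks.

    Real EMP circuits are organised as two mutually antagonistic groups of
    genes (epithelial vs mesenchymal): regulation within a group activates,
    regulation across groups inhibits.  This generator plants that structure
    — nodes are split into two teams of (near-)equal size and each randomly
    placed edge takes its sign from the team relation of its endpoints, so
    ``p_inhibition`` is ignored.  Returns the network and the first team
    (the planted "epithelial" group); the planted split is the ground-truth
    node partition for scoring hybridness on these networks.

    Signal nodes (first ``n_signal`` nodes, no in-edges) still belong to a
    team but drop out of scored state strings as usual.
    """
    rng = np.random.default_rng(spec.seed)
    nodes = [f"G{i+1}" for i in range(spec.n_nodes)]
    # interleave teams so signal nodes (placed first) do not exhaust a team
    team_a = frozenset(nodes[0::2])
    signal = set(nodes[: spec.n_signal])
    pairs = [(s, t) for s in nodes for t in nodes if s != t and t not in signal]
    if spec.n_edges > len(pairs):
        raise ValueError(
            f"{spec.n_edges} edges requested but only {len(pairs)} legal ordered pairs"
        )
    chosen = rng.choice(len(pairs), size=spec.n_edges, replace=False)
    edges = []
    for k in chosen:
        s, t = pairs[k]
        sign = 1 if ((s in team_a) == (t in team_a)) else -1
        edges.append((s, t, sign))
    net = GRNTopology.from_edges(
        f"team{spec.n_nodes}N{spec.n_edges}E_s{spec.seed}", edges, nodes=nodes
    )
    if spec.target_pfl_fraction is not None:
        net = tune_loop_composition(
            net, spec.target_pfl_fraction, max_iters=10 * spec.n_edges, seed=spec.seed
        )
    return net, team_a


def tune_loop_composition(
    net: GRNTopology,
    target_pfl_fraction: float,
    max_iters: int = 100,
    seed: int = 0,
) -> GRNTopology:
    """Hill-climb single-edge sign flips toward a target positive-loop fraction.

    At each iteration every single-edge sign flip is scored by
    ``|pfl_fraction − target|`` and the best strictly-improving flip is
    applied (ties broken by edge order); the search stops at a local optimum
    or after ``max_iters`` rounds.  The objective never worsens.  ``seed``
    is accepted for interface symmetry with the other generators; the climb
    itself is deterministic.
    """
    from dataclasses import replace as _replace

    from .topo_metrics import loop_census

    if not (0.0 <= target_pfl_fraction <= 1.0):
        raise ValueError("target_pfl_fraction must lie in [0, 1]")

    def fraction(n: GRNTopology) -> float:
        c = loop_census(n)
        total = c.pfl + c.nfl
        if total == 0:
            raise ValueError("network has no directed cycle; PFL fraction undefined")
        return c.pfl / total

    current = net
    best_obj = abs(fraction(net) - target_pfl_fraction)
    for _ in range(max_iters):
        if best_obj == 0.0:
            break
        improved = None
        improved_obj = best_obj
        for i in range(current.n_edges):
            flipped = list(current.edges)
            flipped[i] = _replace(flipped[i], sign=-flipped[i].sign)
            cand = GRNTopology(name=current.name, nodes=current.nodes, edges=tuple(flipped))
            obj = abs(fraction(cand) - target_pfl_fraction)
            if obj < improved_obj:
                improved, improved_obj = cand, obj
        if improved is None:
            break
        current, best_obj = improved, improved_obj
    return current
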