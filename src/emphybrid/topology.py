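"""Signed directed gene-regulatory-network topologies.

The central data structure is :class:`GRNTopology`: a signed directed graph
with named nodes, at most one edge per ordered node pair, and an optional
weight in (0, 1] per edge.  Topologies are read and written in the RACIPE
``.topo`` convention (header line, then whitespace-delimited
``Source Target Type`` rows with Type 1 = activation, 2 = inhibition; an
optional fourth ``Weight`` column extends the format for weighted variants).

Besides I/O this module provides the topology manipulations used throughout:
the interaction matrix consumed by the Boolean update and the influence
matrix, signal-node detection, exhaustive single-edge perturbation
enumeration, degree-preserving edge-swap randomization, and random edge
weighting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "Edge",
    "GRNTopology",
    "EdgePerturbation",
    "TopoParseError",
    "parse_topo",
    "write_topo",
    "interaction_matrix",
    "find_signal_nodes",
    "enumerate_edge_perturbations",
    "swap_edges_random",
    "assign_edge_weights",
]

ACTIVATION = 1
INHIBITION = -1

#: RACIPE edge-type codes <-> signs
_TYPE_TO_SIGN = {1: ACTIVATION, 2: INHIBITION}
_SIGN_TO_TYPE = {ACTIVATION: 1, INHIBITION: 2}


class TopoParseError(ValueError):
    """Raised when a .topo stream violates the format contract."""


@dataclass(frozen=True)
class Edge:
    """One signed regulatory interaction ``source -> target``."""

    source: str
    target: str
    sign: int
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.sign not in (ACTIVATION, INHIBITION):
            raise ValueError(f"edge sign must be +1 or -1, got {self.sign}")
        if not (0.0 < self.weight <= 1.0):
            raise ValueError(f"edge weight must lie in (0, 1], got {self.weight}")


@dataclass(frozen=True)
class GRNTopology:
    """A named, signed, directed regulatory network.

    Parameters
    ----------
    name
        Text label (conventionally ``<N>N <E>E`` or the source file stem).
    nodes
        Ordered unique node names.  Node order fixes the bit order of every
        state string produced downstream.
    edges
        Signed, optionally weighted interactions; at most one per ordered
        (source, target) pair.  Self-loops are allowed.
    """

    name: str
    nodes: tuple[str, ...]
    edges: tuple[Edge, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node names")
        declared = set(self.nodes)
        seen: set[tuple[str, str]] = set()
        for e in self.edges:
            if e.source not in declared or e.target not in declared:
                raise ValueError(f"edge {e.source}->{e.target} uses undeclared node")
            key = (e.source, e.target)
            if key in seen:
                raise ValueError(f"duplicate edge {e.source}->{e.target}")
            seen.add(key)

    # -- basic views ------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.nodes)}

    def has_edge(self, source: str, target: str) -> bool:
        return any(e.source == source and e.target == target for e in self.edges)

    def __iter__(self) -> Iterator[Edge]:
        return iter(self.edges)

    def relabel(self, name: str) -> "GRNTopology":
        return replace(self, name=name)

    def to_networkx(self):
        """Signed DiGraph view (edge attrs ``sign``, ``weight``)."""
        import networkx as nx

        g = nx.DiGraph(name=self.name)
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.source, e.target, sign=e.sign, weight=e.weight)
        return g

    @classmethod
    def from_edges(
        cls,
        name: str,
        edges: Iterable[tuple],
        nodes: Sequence[str] | None = None,
    ) -> "GRNTopology":
        """Build from ``(source, target, sign[, weight])`` tuples.

        Node order is first-appearance order unless ``nodes`` is given.
        """
        edge_objs = [Edge(*t) for t in edges]
        if nodes is None:
            order: list[str] = []
            for e in edge_objs:
                for n in (e.source, e.target):
                    if n not in order:
                        order.append(n)
            nodes = order
        return cls(name=name, nodes=tuple(nodes), edges=tuple(edge_objs))


@dataclass(frozen=True)
class EdgePerturbation:
    """A single-edge modification of a parent topology.

    ``label`` follows the ``SRC-TGT_<origType>-<newType>`` convention, where
    type codes are the RACIPE 1/2 codes and deletion is coded ``0``
    (e.g. ``ZEB-GRHL2_2-1`` for a sign flip of an inhibition).
    """

    kind: str  # "delete" | "sign_flip"
    edge: tuple[str, str]
    label: str


# ---------------------------------------------------------------------------
# I/O


def parse_topo(stream, name: str = "network") -> GRNTopology:
    """Parse a RACIPE ``.topo`` stream into a :class:`GRNTopology`.

    The first line is a header and is skipped.  Data rows are
    ``Source Target Type`` (whitespace-delimited) with Type 1 = activation,
    2 = inhibition; an optional fourth column carries an edge weight in
    (0, 1].  Node order is first-appearance order.

    Raises
    ------
    TopoParseError
        On a malformed row, unknown Type code, or duplicate ordered edge;
        the message names the offending line number.
    """
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = stream.read().splitlines()
    edges: list[Edge] = []
    seen: set[tuple[str, str]] = set()
    order: list[str] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if lineno == 1 or not line:
            continue
        parts = line.split()
        if len(parts) not in (3, 4):
            raise TopoParseError(f"line {lineno}: expected 3 or 4 columns, got {len(parts)}")
        src, tgt, type_str = parts[:3]
        try:
            type_code = int(type_str)
        except ValueError:
            raise TopoParseError(f"line {lineno}: Type {type_str!r} is not an integer") from None
        if type_code not in _TYPE_TO_SIGN:
            raise TopoParseError(f"line {lineno}: unknown Type code {type_code} (expected 1 or 2)")
        weight = 1.0
        if len(parts) == 4:
            try:
                weight = float(parts[3])
            except ValueError:
                raise TopoParseError(f"line {lineno}: Weight {parts[3]!r} is not a number") from None
            if not (0.0 < weight <= 1.0):
                raise TopoParseError(f"line {lineno}: Weight {weight} outside (0, 1]")
        if (src, tgt) in seen:
            raise TopoParseError(f"line {lineno}: duplicate edge {src}->{tgt}")
        seen.add((src, tgt))
        for n in (src, tgt):
            if n not in order:
                order.append(n)
        edges.append(Edge(src, tgt, _TYPE_TO_SIGN[type_code], weight))
    return GRNTopology(name=name, nodes=tuple(order), edges=tuple(edges))


def read_topo(path) -> GRNTopology:
    """Read a ``.topo`` file; the network name is the file stem."""
    from pathlib import Path

    p = Path(path)
    with open(p) as fh:
        return parse_topo(fh, name=p.stem)


def write_topo(net: GRNTopology) -> str:
    """Serialize to RACIPE ``.topo`` text.

    A ``Weight`` column is emitted only when some edge weight differs
    from 1, keeping unweighted files byte-compatible with RACIPE.
    """
    weighted = any(e.weight != 1.0 for e in net.edges)
    if weighted:
        out = ["Source Target Type Weight"]
        out += [
            f"{e.source} {e.target} {_SIGN_TO_TYPE[e.sign]} {e.weight:.10g}" for e in net.edges
        ]
    else:
        out = ["Source Target Type"]
        out += [f"{e.source} {e.target} {_SIGN_TO_TYPE[e.sign]}" for e in net.edges]
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Matrices and structural queries


def interaction_matrix(net: GRNTopology) -> np.ndarray:
    """Signed, weighted interaction matrix J.

    Orientation contract: ``J[i, j]`` is the signed weight of the edge
    ``node j -> node i`` (row = target, column = source), zero when absent.
    The Boolean threshold update and the influence matrix both consume this
    orientation.
    """
    idx = net.node_index()
    J = np.zeros((net.n_nodes, net.n_nodes))
    for e in net.edges:
        J[idx[e.target], idx[e.source]] = e.sign * e.weight
    return J


def find_signal_nodes(net: GRNTopology) -> set[str]:
    """Nodes with no incoming edge from *other* nodes.

    Such "signal"/input nodes carry no regulatory information in a steady
    state and are dropped from reported state strings.  A node whose only
    input is its own self-loop still counts as a signal node.
    """
    regulated = {e.target for e in net.edges if e.source != e.target}
    return {n for n in net.nodes if n not in regulated}


# ---------------------------------------------------------------------------
# Perturbations and null models


def _perturbation_label(e: Edge, new_type: int) -> str:
    return f"{e.source}-{e.target}_{_SIGN_TO_TYPE[e.sign]}-{new_type}"


def enumerate_edge_perturbations(
    net: GRNTopology,
) -> list[tuple[EdgePerturbation, GRNTopology]]:
    """All 2E single-edge perturbations: one deletion and one sign flip per edge.

    Order is deterministic: deletions in edge-file order, then sign flips in
    edge-file order.  Deletion labels use new-type code 0.
    """
    if net.n_edges < 1:
        raise ValueError("network has no edges to perturb")
    out: list[tuple[EdgePerturbation, GRNTopology]] = []
    for kind, new_type_of in (
        ("delete", lambda e: 0),
        ("sign_flip", lambda e: _SIGN_TO_TYPE[-e.sign]),
    ):
        for i, e in enumerate(net.edges):
            label = _perturbation_label(e, new_type_of(e))
            if kind == "delete":
                new_edges = net.edges[:i] + net.edges[i + 1 :]
            else:
                new_edges = (
                    net.edges[:i] + (replace(e, sign=-e.sign),) + net.edges[i + 1 :]
                )
            pert = EdgePerturbation(kind=kind, edge=(e.source, e.target), label=label)
            out.append(
                (pert, GRNTopology(name=f"{net.name}:{label}", nodes=net.nodes, edges=new_edges))
            )
    return out


def swap_edges_random(
    net: GRNTopology,
    n_swaps: int,
    seed: int,
    shuffle_signs: bool = False,
) -> GRNTopology:
    """Degree-preserving randomization by repeated double-edge swaps.

    Each swap picks two edges ``a->b`` and ``c->d`` and rewires them to
    ``a->d`` and ``c->b``; every edge keeps its own sign (and weight), so
    in/out degree sequences and the global sign multiset are conserved.
    Swaps that would create a duplicate edge or a self-loop are rejected and
    redrawn, capped at ``100 * n_swaps`` attempts.

    With ``shuffle_signs=True`` the sign/weight multiset is additionally
    shuffled across edges after swapping (signs then travel independently of
    the wiring; the per-node signed degrees are no longer conserved).
    """
    if net.n_edges < 2:
        raise ValueError("need at least 2 edges to swap")
    rng = np.random.default_rng(seed)
    edges = list(net.edges)
    existing = {(e.source, e.target) for e in edges}
    done = 0
    attempts = 0
    max_attempts = 100 * max(n_swaps, 1)
    while done < n_swaps:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not find {n_swaps} legal swaps in {max_attempts} attempts"
            )
        attempts += 1
        i, j = rng.choice(len(edges), size=2, replace=False)
        a, b = edges[i].source, edges[i].target
        c, d = edges[j].source, edges[j].target
        if a == d or c == b:  # would create self-loop
            continue
        if (a, d) in existing or (c, b) in existing:
            continue
        existing -= {(a, b), (c, d)}
        existing |= {(a, d), (c, b)}
        edges[i] = replace(edges[i], target=d)
        edges[j] = replace(edges[j], target=b)
        done += 1
    if shuffle_signs:
        perm = rng.permutation(len(edges))
        signed = [(edges[k].sign, edges[k].weight) for k in perm]
        edges = [replace(e, sign=s, weight=w) for e, (s, w) in zip(edges, signed)]
    return GRNTopology(name=f"{net.name}:swap{n_swaps}", nodes=net.nodes, edges=tuple(edges))


def assign_edge_weights(net: GRNTopology, seed: int) -> GRNTopology:
    """Random edge magnitudes: weight ~ Uniform(0, 1) per edge, signs kept.

    This is the weighted-Boolean perturbation: wiring and signs are those of
    the parent network, only the interaction magnitudes change.
    """
    rng = np.random.default_rng(seed)
    edges = tuple(
        replace(e, weight=float(w))
        for e, w in zip(net.edges, 1.0 - rng.random(net.n_edges))  # (0, 1]
    )
    return GRNTopology(name=f"{net.name}:weighted", nodes=net.nodes, edges=edges)
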