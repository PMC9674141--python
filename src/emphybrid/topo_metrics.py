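"""Simulation-free metrics of a signed topology.

These metrics depend only on the wiring and signs of a network, never on a
dynamical simulation: directed feedback-loop censuses (positive/negative,
plain and length-weighted), predicted frustration (short negative loops),
the influence matrix and the feedback strengths it implies, HiLoop motif
counts (Type-I, Type-II, MISSA — interconnected arrangements of positive
feedback loops), and inconsistency (the greedy estimate of how many edge
signs must flip to make every undirected cycle positive, i.e. to balance
the signed graph).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .topology import GRNTopology, interaction_matrix

__all__ = [
    "LoopCensus",
    "InfluenceMatrix",
    "HiLoopCensus",
    "InconsistencyResult",
    "enumerate_cycles",
    "loop_census",
    "predicted_frustration",
    "influence_matrix",
    "influence_loop_strengths",
    "hiloop_census",
    "inconsistency",
]

#: Above this node count, cycle enumeration defaults to a length cap.
_UNCAPPED_NODE_LIMIT = 30
_DEFAULT_LENGTH_CAP = 10

#: Negative loops no longer than this predict dynamical frustration.
PREDICTED_FRUSTRATION_MAX_LEN = 6


@dataclass(frozen=True)
class DirectedCycle:
    """A simple directed cycle, canonically rotated to start at the smallest
    node index; ``sign`` is the product of its edge signs."""

    nodes: tuple[str, ...]
    sign: int

    def __len__(self) -> int:
        return len(self.nodes)

    def edge_pairs(self) -> tuple[tuple[str, str], ...]:
        n = self.nodes
        return tuple((n[i], n[(i + 1) % len(n)]) for i in range(len(n)))


@dataclass(frozen=True)
class LoopCensus:
    """Counts of positive (PFL) and negative (NFL) directed feedback loops.

    ``weighted_pfl``/``weighted_nfl`` weight each loop by its edge count
    (with ``inverse_length_weights`` the weight is 1/length instead);
    ``pfl_strength``/``nfl_strength`` sum, per sign, the product of edge
    weights around each loop (the loop-strength reading used for
    weighted-edge networks; equal to the plain counts at unit weights);
    ``by_length`` maps loop length to (pfl, nfl) counts.  ``capped`` records
    whether a length cap truncated the census.
    """

    pfl: int
    nfl: int
    weighted_pfl: float
    weighted_nfl: float
    pfl_strength: float = 0.0
    nfl_strength: float = 0.0
    by_length: dict[int, tuple[int, int]] = field(default_factory=dict)
    capped: bool = False

    @property
    def pfl_fraction(self) -> float:
        total = self.pfl + self.nfl
        return self.pfl / total if total else float("nan")


@dataclass(frozen=True)
class InfluenceMatrix:
    """Path-length-normalized accumulation of signed adjacency powers."""

    matrix: np.ndarray
    nodes: tuple[str, ...]
    lmax: int


@dataclass(frozen=True)
class HiLoopCensus:
    """Counts of the three interconnected-PFL motifs."""

    type1: int
    type2: int
    missa: int


@dataclass(frozen=True)
class InconsistencyResult:
    """Greedy balance deficit: sign flips applied and the edges flipped."""

    value: int
    flipped_edges: tuple[tuple[str, str], ...]


# ---------------------------------------------------------------------------
# Directed cycles


def enumerate_cycles(net: GRNTopology, max_len: int | None = None) -> list[DirectedCycle]:
    """All simple directed cycles, each reported once.

    Self-loops are length-1 cycles.  For networks above
    ``_UNCAPPED_NODE_LIMIT`` nodes a default length cap of
    ``_DEFAULT_LENGTH_CAP`` is applied unless ``max_len`` is given
    (exhaustive enumeration is exponential in general).
    """
    if max_len is None and net.n_nodes > _UNCAPPED_NODE_LIMIT:
        max_len = _DEFAULT_LENGTH_CAP
    g = net.to_networkx()
    sign_of = {(e.source, e.target): e.sign for e in net.edges}
    idx = net.node_index()
    cycles: list[DirectedCycle] = []
    for nodes in nx.simple_cycles(g, length_bound=max_len):
        # canonical rotation: start at the smallest node index
        k = min(range(len(nodes)), key=lambda i: idx[nodes[i]])
        rot = tuple(nodes[k:] + nodes[:k])
        sign = 1
        for i in range(len(rot)):
            sign *= sign_of[(rot[i], rot[(i + 1) % len(rot)])]
        cycles.append(DirectedCycle(nodes=rot, sign=sign))
    cycles.sort(key=lambda c: (len(c), tuple(idx[n] for n in c.nodes)))
    return cycles


def loop_census(
    net: GRNTopology,
    max_len: int | None = None,
    inverse_length_weights: bool = False,
) -> LoopCensus:
    """Census of positive and negative directed feedback loops.

    A loop is positive when it carries an even number of inhibitory edges.
    Weighted counts weight each loop by the number of edges participating in
    it (or by 1/length with ``inverse_length_weights``).  Loop strengths —
    the product of edge weights around each loop, summed per sign — carry
    the weighted-edge reading and reduce to the plain counts at unit
    weights.
    """
    cycles = enumerate_cycles(net, max_len=max_len)
    weight_of = {(e.source, e.target): e.weight for e in net.edges}
    pfl = nfl = 0
    wpfl = wnfl = 0.0
    spfl = snfl = 0.0
    by_length: dict[int, list[int]] = {}
    for c in cycles:
        length = len(c)
        strength = 1.0
        for pair in c.edge_pairs():
            strength *= weight_of[pair]
        w = 1.0 / length if inverse_length_weights else float(length)
        counts = by_length.setdefault(length, [0, 0])
        if c.sign > 0:
            pfl += 1
            wpfl += w
            spfl += strength
            counts[0] += 1
        else:
            nfl += 1
            wnfl += w
            snfl += strength
            counts[1] += 1
    capped = max_len is not None or net.n_nodes > _UNCAPPED_NODE_LIMIT
    return LoopCensus(
        pfl=pfl,
        nfl=nfl,
        weighted_pfl=wpfl,
        weighted_nfl=wnfl,
        pfl_strength=spfl,
        nfl_strength=snfl,
        by_length={k: tuple(v) for k, v in sorted(by_length.items())},
        capped=capped,
    )


def predicted_frustration(net: GRNTopology) -> int:
    """Number of negative directed loops of length ≤ 6.

    Short negative feedback loops are a purely topological proxy for the
    dynamical frustration a network's steady states will exhibit.
    """
    cycles = enumerate_cycles(net, max_len=PREDICTED_FRUSTRATION_MAX_LEN)
    return sum(1 for c in cycles if c.sign < 0)


# ---------------------------------------------------------------------------
# Influence matrix


def influence_matrix(net: GRNTopology, lmax: int = 10) -> InfluenceMatrix:
    """Accumulated, normalized signed adjacency powers.

    With A the signed (weighted) interaction matrix and A_max its unsigned
    binarization, ``InfMat = (1/lmax) * Σ_{l=1..lmax} A^l ./ A_max^l``
    where ``./`` is elementwise and 0/0 := 0.  Entry (i, j) quantifies the
    net effective regulation of node j on node i through paths up to length
    lmax, and always lies in [−1, 1].
    """
    if lmax < 1:
        raise ValueError("lmax must be >= 1")
    A = interaction_matrix(net)
    Amax = (A != 0).astype(float)
    acc = np.zeros_like(A)
    Al = np.eye(A.shape[0])
    Amaxl = np.eye(A.shape[0])
    for _ in range(lmax):
        Al = Al @ A
        Amaxl = Amaxl @ Amax
        if np.any((Al != 0) & (Amaxl == 0)):  # pragma: no cover - structurally impossible
            raise AssertionError("signed path exists where unsigned count is zero")
        with np.errstate(invalid="ignore", divide="ignore"):
            term = np.where(Amaxl != 0, Al / np.where(Amaxl == 0, 1.0, Amaxl), 0.0)
        acc += term
    M = acc / lmax
    assert np.all(np.abs(M) <= 1 + 1e-12)
    return InfluenceMatrix(matrix=M, nodes=net.nodes, lmax=lmax)


def influence_loop_strengths(inf: InfluenceMatrix) -> tuple[float, float]:
    """Total positive and negative feedback strength between node pairs.

    For each unordered pair i < j the feedback strength is the product of
    mutual influences ``I_ij * I_ji``; products > 0 accumulate into the
    positive total, products < 0 into the negative total (diagonal
    excluded).  Returns ``(positive_total, negative_total)`` with
    ``negative_total <= 0``.
    """
    M = inf.matrix
    n = M.shape[0]
    pos = neg = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            p = M[i, j] * M[j, i]
            if p > 0:
                pos += p
            elif p < 0:
                neg += p
    return pos, neg


# ---------------------------------------------------------------------------
# HiLoops


def hiloop_census(
    net: GRNTopology,
    max_len: int | None = None,
    missa_loose: bool = False,
) -> HiLoopCensus:
    """Census of interconnected positive-feedback-loop motifs.

    Type-I
        Unordered sets of three distinct PFLs (distinct as edge sets) all
        sharing at least one common node.
    Type-II
        Unordered triples {L0, L1, L2} of pairwise edge-disjoint PFLs such
        that for some pair of distinct nodes u, v on L0, L1 passes through
        u avoiding v and L2 passes through v avoiding u.
    MISSA
        Node pairs (u, v) with mutual inhibition u⊣v, v⊣u and a
        self-activation on u or v; each qualifying pair counts once.  With
        ``missa_loose`` the self-activation requirement relaxes to u or v
        lying on any other positive loop.
    """
    cycles = enumerate_cycles(net, max_len=max_len)
    pfls = [c for c in cycles if c.sign > 0]
    edge_sets = [frozenset(c.edge_pairs()) for c in pfls]
    node_sets = [set(c.nodes) for c in pfls]

    type1 = 0
    for a, b, c in itertools.combinations(range(len(pfls)), 3):
        if edge_sets[a] == edge_sets[b] or edge_sets[a] == edge_sets[c] or edge_sets[b] == edge_sets[c]:
            continue
        if node_sets[a] & node_sets[b] & node_sets[c]:
            type1 += 1

    type2 = 0
    for a, b, c in itertools.combinations(range(len(pfls)), 3):
        if (
            edge_sets[a] & edge_sets[b]
            or edge_sets[a] & edge_sets[c]
            or edge_sets[b] & edge_sets[c]
        ):
            continue
        if _is_type2_triple(node_sets[a], node_sets[b], node_sets[c]):
            type2 += 1

    sign_of = {(e.source, e.target): e.sign for e in net.edges}
    self_act = {e.source for e in net.edges if e.source == e.target and e.sign > 0}
    missa = 0
    for i, u in enumerate(net.nodes):
        for v in net.nodes[i + 1 :]:
            if sign_of.get((u, v)) == -1 and sign_of.get((v, u)) == -1:
                if missa_loose:
                    # any PFL other than the double-negative loop itself
                    dn = frozenset({(u, v), (v, u)})
                    ok = any(
                        (u in ns or v in ns) and es != dn
                        for ns, es in zip(node_sets, edge_sets)
                    )
                else:
                    ok = u in self_act or v in self_act
                if ok:
                    missa += 1
    return HiLoopCensus(type1=type1, type2=type2, missa=missa)


def _is_type2_triple(n0: set[str], n1: set[str], n2: set[str]) -> bool:
    """One loop hosts u and v; the other two attach at u (avoiding v) and v
    (avoiding u) respectively, in some assignment of roles."""
    for host, s1, s2 in ((n0, n1, n2), (n1, n0, n2), (n2, n0, n1)):
        for u in host:
            for v in host:
                if u == v:
                    continue
                if (u in s1 and v not in s1 and v in s2 and u not in s2) or (
                    u in s2 and v not in s2 and v in s1 and u not in s1
                ):
                    return True
    return False


# ---------------------------------------------------------------------------
# Inconsistency (signed-graph balance deficit, greedy)


def _undirected_edges(net: GRNTopology) -> list[tuple[str, str, int]]:
    """Underlying undirected signed edges (self-loops dropped: they form no
    undirected cycle with other edges and a negative self-loop cannot be
    balanced by any flip of other edges)."""
    return [(e.source, e.target, e.sign) for e in net.edges if e.source != e.target]


def _cycle_basis_edge_ids(edges: list[tuple[str, str, int]]) -> list[list[int]]:
    """Fundamental cycle basis of the undirected multigraph, as lists of edge
    indices.  Parallel edges (A→B and B→A collapse to two undirected edges)
    each contribute their own basis cycle, which plain ``cycle_basis`` on a
    simple graph would miss."""
    parent: dict[str, str] = {}
    parent_edge: dict[str, int] = {}

    adj: dict[str, list[tuple[str, int]]] = {}
    for k, (u, v, _s) in enumerate(edges):
        adj.setdefault(u, []).append((v, k))
        adj.setdefault(v, []).append((u, k))

    tree_edges: set[int] = set()
    visited: set[str] = set()
    for root in adj:
        if root in visited:
            continue
        visited.add(root)
        stack = [root]
        while stack:
            x = stack.pop()
            for y, k in adj[x]:
                if y not in visited:
                    visited.add(y)
                    parent[y] = x
                    parent_edge[y] = k
                    tree_edges.add(k)
                    stack.append(y)

    def tree_path(u: str, v: str) -> list[int]:
        # edge ids on the unique tree path u..v
        anc_u: list[str] = [u]
        x = u
        while x in parent:
            x = parent[x]
            anc_u.append(x)
        anc_set = set(anc_u)
        path_v: list[int] = []
        x = v
        while x not in anc_set:
            path_v.append(parent_edge[x])
            x = parent[x]
        meet = x
        path_u: list[int] = []
        x = u
        while x != meet:
            path_u.append(parent_edge[x])
            x = parent[x]
        return path_u + path_v[::-1]

    basis: list[list[int]] = []
    for k, (u, v, _s) in enumerate(edges):
        if k in tree_edges:
            continue
        basis.append([k] + tree_path(u, v))
    return basis


def _all_simple_cycles_edge_ids(
    edges: list[tuple[str, str, int]], max_len: int
) -> list[list[int]]:
    """All edge-simple undirected cycles up to ``max_len`` edges, as edge-id
    lists: node cycles of the simple graph expanded over parallel-edge
    choices, plus the 2-cycles formed by each parallel pair."""
    par: dict[frozenset, list[int]] = {}
    for k, (u, v, _s) in enumerate(edges):
        par.setdefault(frozenset((u, v)), []).append(k)

    out: list[list[int]] = []
    for ids in par.values():
        for a, b in itertools.combinations(ids, 2):
            out.append([a, b])

    g = nx.Graph()
    for key in par:
        u, v = tuple(key)
        g.add_edge(u, v)
    for nodes in nx.simple_cycles(g, length_bound=max_len):
        if len(nodes) < 3:
            continue
        pair_ids = [
            par[frozenset((nodes[i], nodes[(i + 1) % len(nodes)]))]
            for i in range(len(nodes))
        ]
        for combo in itertools.product(*pair_ids):
            out.append(list(combo))
    return out


def inconsistency(
    net: GRNTopology,
    cycle_space: str = "basis",
    max_len: int = 10,
) -> InconsistencyResult:
    """Greedy estimate of the minimum sign flips balancing the signed graph.

    A network is consistent (balanced) when every undirected cycle carries
    an even number of negative edges; negative cycles — negative feedback
    loops and incoherent feed-forward loops alike — are inconsistent.  The
    procedure repeatedly flips the edge lying on the most currently-negative
    cycles (ties: fewest positive cycles disturbed, then edge order) until
    no negative cycle remains, and reports the number of flips.

    ``cycle_space='basis'`` (default) checks a fundamental cycle basis: a
    signed graph is balanced iff every basis cycle is positive, so the
    zero/nonzero decision is exact while staying polynomial.
    ``cycle_space='all_simple_capped'`` enumerates all simple undirected
    cycles up to ``max_len`` edges, reproducing the published enumeration
    more literally.
    """
    edges = _undirected_edges(net)
    if cycle_space == "basis":
        cycles = _cycle_basis_edge_ids(edges)
    elif cycle_space == "all_simple_capped":
        cycles = _all_simple_cycles_edge_ids(edges, max_len=max_len)
    else:
        raise ValueError(f"unknown cycle_space {cycle_space!r}")

    signs = [s for (_u, _v, s) in edges]
    flipped: list[int] = []
    # every accepted flip strictly shrinks the negative cycle set, so the
    # cycle count bounds the iteration
    max_flips = max(len(edges), len(cycles), 1)

    def cycle_sign(c: list[int]) -> int:
        s = 1
        for k in c:
            s *= signs[k]
        return s

    for _ in range(max_flips + 1):
        neg = [c for c in cycles if cycle_sign(c) < 0]
        if not neg:
            break
        pos = [c for c in cycles if cycle_sign(c) > 0]
        neg_count = [0] * len(edges)
        pos_count = [0] * len(edges)
        for c in neg:
            for k in c:
                neg_count[k] += 1
        for c in pos:
            for k in c:
                pos_count[k] += 1
        if cycle_space == "basis":
            best = min(
                range(len(edges)), key=lambda k: (-neg_count[k], pos_count[k], k)
            )
            if neg_count[best] <= pos_count[best]:
                # flipping `best` would not shrink the negative set: fall back
                # to the edge with the largest net reduction (a fundamental
                # basis always offers one — each cycle's defining non-tree
                # edge lies on that cycle alone)
                best = min(
                    (k for k in range(len(edges)) if neg_count[k] > 0),
                    key=lambda k: (pos_count[k] - neg_count[k], k),
                )
                if neg_count[best] <= pos_count[best]:
                    raise RuntimeError(
                        "greedy cannot make progress (pathological cycle space)"
                    )
        else:
            # literal procedure over the enumerated cycles: flip edges in
            # order of negative-cycle commonality, each edge at most once
            candidates = [
                k for k in range(len(edges)) if neg_count[k] > 0 and k not in flipped
            ]
            if not candidates:
                raise RuntimeError(
                    "negative cycles remain after exhausting single flips "
                    "(pathological cycle space)"
                )
            best = min(candidates, key=lambda k: (-neg_count[k], pos_count[k], k))
        signs[best] = -signs[best]
        flipped.append(best)
    else:
        raise RuntimeError(
            f"greedy made no progress after {max_flips} flips (pathological cycle space)"
        )
    return InconsistencyResult(
        value=len(flipped),
        flipped_edges=tuple((edges[k][0], edges[k][1]) for k in flipped),
    )
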