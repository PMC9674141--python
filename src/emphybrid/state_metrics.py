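"""Metrics over steady states and phenotype distributions.

Everything downstream of a simulation lives here: partitioning nodes into
epithelial/mesenchymal groups from their steady-state correlations, the EMT
score of a binarized state, hybridness of a distribution, the
Jensen–Shannon divergence between two distributions, the J metric
(correlation cohesion), and frustration of states and networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import jensenshannon

from .phenotypes import PhenotypeDistribution
from .topology import GRNTopology

__all__ = [
    "NodePartition",
    "FrustrationStats",
    "partition_nodes",
    "emt_score",
    "classify_state",
    "hybridness",
    "jensen_shannon_divergence",
    "j_metric",
    "state_frustration",
    "network_frustration",
    "state_correlations",
]

logger = logging.getLogger(__name__)

#: |EMT score| at or below this is a hybrid state (boundary inclusive).
HYBRID_THRESHOLD = 0.5


@dataclass(frozen=True)
class NodePartition:
    """Epithelial/mesenchymal split of the scored nodes.

    ``nodes`` fixes the bit order of the state strings the partition will
    score; ``e_nodes`` and ``m_nodes`` are disjoint, jointly cover
    ``nodes``, and are both non-empty.
    """

    nodes: tuple[str, ...]
    e_nodes: frozenset[str]
    m_nodes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.e_nodes or not self.m_nodes:
            raise ValueError("both E and M groups must be non-empty")
        if self.e_nodes & self.m_nodes:
            raise ValueError("E and M groups overlap")
        if self.e_nodes | self.m_nodes != set(self.nodes):
            raise ValueError("E and M groups must jointly cover the scored nodes")

    def swapped(self) -> "NodePartition":
        return NodePartition(nodes=self.nodes, e_nodes=self.m_nodes, m_nodes=self.e_nodes)


@dataclass(frozen=True)
class FrustrationStats:
    """Min/mean/max frustration over the distinct steady states, plus the
    per-state table."""

    min: float
    mean: float
    max: float
    per_state: tuple[tuple[str, float], ...]


def partition_nodes(
    correlations: np.ndarray,
    nodes: tuple[str, ...],
    anchors: dict[str, str] | None = None,
) -> NodePartition:
    """Split nodes into two anticorrelated groups by hierarchical clustering.

    Rows of the (symmetric) correlation matrix are clustered with Euclidean
    distance and complete linkage, and the dendrogram is cut into two
    clusters.  Labels come from ``anchors`` (any known marker node mapped to
    ``"E"`` or ``"M"``); without anchors the cluster containing the
    lexicographically first node is labelled E, with a logged warning.
    """
    C = np.asarray(correlations, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1] or C.shape[0] != len(nodes):
        raise ValueError("correlations must be square and match the node list")
    if len(nodes) < 2:
        raise ValueError("need at least two nodes to partition")
    Z = hierarchy.linkage(C, method="complete", metric="euclidean")
    labels = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    cluster1 = frozenset(n for n, l in zip(nodes, labels) if l == 1)
    cluster2 = frozenset(n for n, l in zip(nodes, labels) if l == 2)
    if not cluster1 or not cluster2:
        raise ValueError("clustering produced an empty cluster")
    if anchors:
        e_cluster = None
        for node, label in anchors.items():
            if node not in nodes:
                raise ValueError(f"anchor node {node!r} is not a scored node")
            if label not in ("E", "M"):
                raise ValueError(f"anchor label must be 'E' or 'M', got {label!r}")
            containing = cluster1 if node in cluster1 else cluster2
            implied_e = containing if label == "E" else (
                cluster2 if containing is cluster1 else cluster1
            )
            if e_cluster is not None and implied_e is not e_cluster:
                raise ValueError("anchors disagree about which cluster is epithelial")
            e_cluster = implied_e
        m_cluster = cluster2 if e_cluster is cluster1 else cluster1
    else:
        first = min(nodes)
        e_cluster = cluster1 if first in cluster1 else cluster2
        m_cluster = cluster2 if e_cluster is cluster1 else cluster1
        logger.warning(
            "no anchors given: labelling the cluster containing %r as epithelial",
            first,
        )
    return NodePartition(nodes=tuple(nodes), e_nodes=e_cluster, m_nodes=m_cluster)


def emt_score(state: str, part: NodePartition) -> float:
    """Mean epithelial bit minus mean mesenchymal bit, in [-1, 1]."""
    if len(state) != len(part.nodes):
        raise ValueError(
            f"state length {len(state)} does not match {len(part.nodes)} scored nodes"
        )
    bits = {n: int(b) for n, b in zip(part.nodes, state)}
    e = sum(bits[n] for n in part.e_nodes) / len(part.e_nodes)
    m = sum(bits[n] for n in part.m_nodes) / len(part.m_nodes)
    return e - m


def classify_state(state: str, part: NodePartition) -> str:
    """``"hybrid"`` when |EMT score| <= 0.5 (boundary inclusive), else
    ``"E"`` or ``"M"`` by the score's sign."""
    score = emt_score(state, part)
    if abs(score) <= HYBRID_THRESHOLD:
        return "hybrid"
    return "E" if score > 0 else "M"


def hybridness(dist: PhenotypeDistribution, part: NodePartition) -> float:
    """Summed normalized frequency of hybrid steady states."""
    return sum(f for s, f in dist.freqs.items() if classify_state(s, part) == "hybrid")


def phenotype_frequencies(
    dist: PhenotypeDistribution, part: NodePartition
) -> dict[str, float]:
    """Total frequency per phenotype class: E, M, hybrid."""
    out = {"E": 0.0, "M": 0.0, "hybrid": 0.0}
    for s, f in dist.freqs.items():
        out[classify_state(s, part)] += f
    return out


def jensen_shannon_divergence(
    f1: PhenotypeDistribution, f2: PhenotypeDistribution
) -> float:
    """JSD(f1 || f2) with log base 2, in [0, 1].

    Supports are aligned on their union with missing states at zero;
    0 * log(0/x) is taken as 0.  Zero iff the distributions coincide, 1 for
    disjoint supports.
    """
    p, q = f1.align(f2)
    # scipy returns the JS *distance* (sqrt of the divergence)
    return float(jensenshannon(p, q, base=2) ** 2)


def j_metric(correlations: np.ndarray) -> float:
    """Sum of the strict upper triangle of the correlation matrix.

    High values mean cohesive (mutually reinforcing) node expression; the
    diagonal is excluded.
    """
    C = np.asarray(correlations, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("correlation matrix must be square")
    return float(C[np.triu_indices_from(C, k=1)].sum())


def state_frustration(state: str, net: GRNTopology) -> float:
    """Fraction of edges in conflict with a binarized state.

    Bits map to Ising spins (0 -> -1, 1 -> +1); an edge j -> i with sign J
    is frustrated when ``sign(J) * spin(j) * spin(i) = -1``.  The state must
    cover every node (signal bits included: their outgoing edges count, and
    the denominator is the total edge count).  A self-inhibition is always
    frustrated, a self-activation never.
    """
    if len(state) != net.n_nodes:
        raise ValueError(
            f"state length {len(state)} does not match {net.n_nodes} nodes "
            "(the full, untrimmed state is required)"
        )
    if net.n_edges == 0:
        raise ValueError("frustration undefined for a network with no edges")
    spin = {n: (1 if b == "1" else -1) for n, b in zip(net.nodes, state)}
    frustrated = sum(
        1 for e in net.edges if e.sign * spin[e.source] * spin[e.target] == -1
    )
    return frustrated / net.n_edges


def network_frustration(
    dist: PhenotypeDistribution,
    net: GRNTopology,
    frequency_weighted_mean: bool = False,
) -> FrustrationStats:
    """Min/mean/max frustration over a distribution's distinct steady states.

    Uses the full (untrimmed) states recorded in ``dist.full_states``.  The
    mean is unweighted over distinct states by default; with
    ``frequency_weighted_mean`` each state's frustration is weighted by its
    frequency instead.
    """
    if not dist.freqs:
        raise ValueError("empty distribution")
    if not dist.full_states:
        raise ValueError("distribution carries no full states; cannot score frustration")
    rows = []
    for s in sorted(dist.freqs):
        rows.append((s, state_frustration(dist.full_states[s], net)))
    values = np.array([f for (_s, f) in rows])
    if frequency_weighted_mean:
        w = np.array([dist.freqs[s] for (s, _f) in rows])
        mean = float(np.average(values, weights=w))
    else:
        mean = float(values.mean())
    return FrustrationStats(
        min=float(values.min()), mean=mean, max=float(values.max()), per_state=tuple(rows)
    )


def state_correlations(
    dist: PhenotypeDistribution, nodes: tuple[str, ...] | None = None
) -> np.ndarray:
    """Frequency-weighted Pearson correlations between node bits.

    Computed over the distribution's states with each state weighted by its
    frequency — for a Boolean ensemble this equals the correlation across
    converged initial conditions.  Pairs involving a constant node get
    correlation 0.
    """
    if nodes is None:
        nodes = dist.nodes
    cols = [dist.nodes.index(n) for n in nodes]
    states = sorted(dist.freqs)
    B = np.array([[int(s[c]) for c in cols] for s in states], dtype=float)
    w = np.array([dist.freqs[s] for s in states])
    mu = w @ B
    Xc = B - mu
    cov = (Xc * w[:, None]).T @ Xc
    sd = np.sqrt(np.diag(cov))
    with np.errstate(invalid="ignore", divide="ignore"):
        C = cov / np.outer(sd, sd)
    C = np.nan_to_num(C)
    np.fill_diagonal(C, 1.0)
    return C
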