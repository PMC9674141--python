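"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the library's own code paths (and
networkx, where the library uses it) so they can serve as independent
cross-checks: a DFS simple-cycle enumerator, a brute-force signed-graph
balance solver, and an exact absorption-probability solver for the
asynchronous Boolean update.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from emphybrid import GRNTopology, make_fixture


@pytest.fixture
def toggle():
    return make_fixture("toggle")


@pytest.fixture
def toggle_missa():
    return make_fixture("toggle_missa")


@pytest.fixture
def repressilator():
    return make_fixture("repressilator")


@pytest.fixture
def emt_core():
    return make_fixture("emt_core")


@pytest.fixture
def type1_hub():
    return make_fixture("type1_hub")


# ---------------------------------------------------------------------------
# Oracle: DFS enumeration of simple directed cycles (independent of networkx)


def dfs_simple_cycles(edges: list[tuple[str, str]], max_len: int | None = None):
    """All simple directed cycles as canonical node tuples, by plain DFS.

    Each cycle is reported once, rotated to start at its smallest node (by
    sorted order of names).  Self-loops are length-1 cycles.
    """
    nodes = sorted({n for e in edges for n in e[:2]})
    order = {n: i for i, n in enumerate(nodes)}
    adj: dict[str, list[str]] = {n: [] for n in nodes}
    for s, t in edges:
        adj[s].append(t)
    found: set[tuple[str, ...]] = set()

    def walk(start: str, path: list[str], on_path: set[str]):
        if max_len is not None and len(path) > max_len:
            return
        for nxt in adj[path[-1]]:
            if order[nxt] < order[start]:
                continue  # canonical: smallest node starts the cycle
            if nxt == start:
                found.add(tuple(path))
            elif nxt not in on_path:
                if max_len is None or len(path) < max_len:
                    walk(start, path + [nxt], on_path | {nxt})

    for n in nodes:
        walk(n, [n], {n})
    return found


def cycle_sign(cycle: tuple[str, ...], sign_of: dict[tuple[str, str], int]) -> int:
    s = 1
    for i in range(len(cycle)):
        s *= sign_of[(cycle[i], cycle[(i + 1) % len(cycle)])]
    return s


# ---------------------------------------------------------------------------
# Oracle: brute-force signed-graph balance (minimum sign flips)


def _is_balanced(edges: list[tuple[str, str, int]]) -> bool:
    """Balanced iff nodes admit +/- labels with every edge sign equal to the
    product of its endpoint labels (parallel edges checked individually;
    undirected view; self-loops: a negative self-loop is never balanceable)."""
    for u, v, s in edges:
        if u == v and s < 0:
            return False
    nodes = sorted({n for (u, v, _s) in edges for n in (u, v)})
    adj: dict[str, list[tuple[str, int]]] = {n: [] for n in nodes}
    for u, v, s in edges:
        if u == v:
            continue
        adj[u].append((v, s))
        adj[v].append((u, s))
    color: dict[str, int] = {}
    for root in nodes:
        if root in color:
            continue
        color[root] = 1
        stack = [root]
        while stack:
            x = stack.pop()
            for y, s in adj[x]:
                want = color[x] * s
                if y not in color:
                    color[y] = want
                    stack.append(y)
                elif color[y] != want:
                    return False
    return True


def brute_force_min_flips(net: GRNTopology) -> int:
    """Smallest number of edge-sign flips making the signed graph balanced,
    by exhaustive search over flip subsets of increasing size."""
    base = [(e.source, e.target, e.sign) for e in net.edges if e.source != e.target]
    m = len(base)
    for k in range(m + 1):
        for subset in itertools.combinations(range(m), k):
            flipped = [
                (u, v, -s if i in subset else s) for i, (u, v, s) in enumerate(base)
            ]
            if _is_balanced(flipped):
                return k
    raise AssertionError("unbalanceable graph (cannot happen: flip everything)")


# ---------------------------------------------------------------------------
# Oracle: exact absorption probabilities of the asynchronous update


def async_absorption(net: GRNTopology, convention: str = "ising", n_iter: int = 20_000):
    """Fixed-point absorption probabilities from a uniform initial state.

    Builds the full 2^N-state Markov chain of the asynchronous dynamics
    (uniform node choice per step, threshold update per the convention) and
    propagates the uniform distribution until the transient mass vanishes.
    Returns {state string: probability} over fixed points, normalized over
    absorbed mass.
    """
    from emphybrid.topology import interaction_matrix

    N = net.n_nodes
    J = interaction_matrix(net)
    n_states = 2**N
    bits = ((np.arange(n_states)[:, None] >> np.arange(N)[::-1]) & 1).astype(float)
    vals = (2 * bits - 1) if convention == "ising" else bits
    P = np.zeros((n_states, n_states))
    fixed = np.zeros(n_states, dtype=bool)
    for s in range(n_states):
        field = J @ vals[s]
        target = np.where(field > 0, 1.0, np.where(field < 0, 0.0, bits[s]))
        if np.array_equal(target, bits[s]):
            fixed[s] = True
            P[s, s] = 1.0
            continue
        for i in range(N):
            ns = bits[s].copy()
            ns[i] = target[i]
            j = int(ns @ (1 << np.arange(N)[::-1]))
            P[s, j] += 1.0 / N
    pi = np.full(n_states, 1.0 / n_states)
    for _ in range(n_iter // 100):
        pi = pi @ np.linalg.matrix_power(P, 100)
        if pi[~fixed].sum() < 1e-12:
            break
    absorbed = pi[fixed].sum()
    out = {}
    for s in np.where(fixed)[0]:
        if pi[s] > 0:
            out["".join(str(int(b)) for b in bits[s])] = pi[s] / absorbed
    return out
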