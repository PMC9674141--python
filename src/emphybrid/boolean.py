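"""Asynchronous threshold Boolean simulation.

Parameter-independent dynamics: each node holds a binary state and is
updated, one randomly chosen node per time step, by the sign of the
weighted sum of its regulators' states.  Runs that reach a state invariant
under the update of every node are fixed points; their frequencies over
many random initial conditions form the phenotype distribution.

Two update conventions are provided.  The default ``ising`` convention maps
states {0, 1} to spins {−1, +1} before the weighted sum, matching the
asynchronous Ising framework this update rule derives from (and avoiding
the all-zero state being spuriously fixed).  The ``literal01`` convention
feeds raw 0/1 values into the sum, as the threshold equation is sometimes
written; inactive regulators then contribute nothing.  Zero net input holds
the current value under both conventions.

The weighted-edge variant is the same code path: edge weights enter the sum
via the interaction matrix, signs unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phenotypes import PhenotypeDistribution
from .topology import GRNTopology, find_signal_nodes, interaction_matrix

__all__ = [
    "threshold_update",
    "simulate_async",
    "run_boolean_ensemble",
    "boolean_fixed_points",
    "BooleanEnsemble",
]

CONVENTIONS = ("ising", "literal01")


def _check_convention(convention: str) -> None:
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}; choose from {CONVENTIONS}")


def _target_states(states: np.ndarray, J: np.ndarray, convention: str) -> np.ndarray:
    """Batch threshold update targets.

    ``states`` is (n_runs, N) in {0,1}; returns the (n_runs, N) matrix whose
    (r, i) entry is the value node i would take if updated now in run r
    (held value where the input sum is zero).
    """
    if convention == "ising":
        inp = (2.0 * states - 1.0) @ J.T
    else:
        inp = states.astype(float) @ J.T
    return np.where(inp > 0, 1, np.where(inp < 0, 0, states)).astype(np.int8)


def threshold_update(
    state, net: GRNTopology, node: int, convention: str = "ising"
) -> np.ndarray:
    """Update one node by the sign of its weighted input sum.

    The node is set to 1 when the sum of ``sign * weight * value`` over its
    in-edges is positive, 0 when negative, and held otherwise (including
    for nodes with no inputs).
    """
    _check_convention(convention)
    s = np.asarray(state, dtype=np.int8).copy()
    if s.shape != (net.n_nodes,):
        raise ValueError(f"state length {s.shape} does not match {net.n_nodes} nodes")
    J = interaction_matrix(net)
    s[node] = _target_states(s[None, :], J, convention)[0, node]
    return s


def is_fixed_point(state, net: GRNTopology, convention: str = "ising") -> bool:
    """True when the state is invariant under the update of every node."""
    _check_convention(convention)
    s = np.asarray(state, dtype=np.int8)
    J = interaction_matrix(net)
    return bool(np.array_equal(_target_states(s[None, :], J, convention)[0], s))


def simulate_async(
    net: GRNTopology,
    ic,
    max_steps: int = 1000,
    seed: int = 0,
    convention: str = "ising",
) -> tuple[bool, np.ndarray]:
    """One asynchronous trajectory from a single initial condition.

    At each step one node, chosen uniformly at random, is updated.  Returns
    ``(reached_fixed_point, final_state)``; a run that has not fixed after
    ``max_steps`` steps is flagged unconverged.
    """
    _check_convention(convention)
    rng = np.random.default_rng(seed)
    s = np.asarray(ic, dtype=np.int8).copy()
    if s.shape != (net.n_nodes,):
        raise ValueError(f"ic length {s.shape} does not match {net.n_nodes} nodes")
    J = interaction_matrix(net)
    for _ in range(max_steps):
        target = _target_states(s[None, :], J, convention)[0]
        if np.array_equal(target, s):
            return True, s
        k = rng.integers(net.n_nodes)
        s[k] = target[k]
    return bool(np.array_equal(_target_states(s[None, :], J, convention)[0], s)), s


@dataclass(frozen=True)
class BooleanEnsemble:
    """Converged fixed points of one ensemble run (before trimming)."""

    states: np.ndarray  # (n_converged, N) int8 fixed points, one row per converged IC
    n_ics: int
    nodes: tuple[str, ...]


def _run_once(
    net: GRNTopology,
    n_ics: int,
    max_steps: int,
    rng: np.random.Generator,
    convention: str,
) -> BooleanEnsemble:
    J = interaction_matrix(net)
    N = net.n_nodes
    states = rng.integers(0, 2, size=(n_ics, N), dtype=np.int8)
    active = np.arange(n_ics)
    done_states = np.empty((0, N), dtype=np.int8)
    collected: list[np.ndarray] = []
    for _ in range(max_steps):
        if active.size == 0:
            break
        S = states[active]
        T = _target_states(S, J, convention)
        fixed = np.all(T == S, axis=1)
        if fixed.any():
            collected.append(S[fixed].copy())
            active = active[~fixed]
            S, T = S[~fixed], T[~fixed]
        if active.size == 0:
            break
        k = rng.integers(0, N, size=active.size)
        rows = np.arange(active.size)
        S = S.copy()
        S[rows, k] = T[rows, k]
        states[active] = S
    if collected:
        done_states = np.concatenate(collected, axis=0)
    return BooleanEnsemble(states=done_states, n_ics=n_ics, nodes=net.nodes)


def _ensemble_to_distribution(
    ens: BooleanEnsemble, signal_nodes: set[str], scored_nodes: tuple[str, ...] | None
) -> PhenotypeDistribution:
    if scored_nodes is None:
        scored_nodes = tuple(n for n in ens.nodes if n not in signal_nodes)
    idx = [ens.nodes.index(n) for n in scored_nodes]
    if ens.states.shape[0] == 0:
        raise RuntimeError("no initial condition converged to a fixed point")
    counts: dict[str, int] = {}
    full: dict[str, str] = {}
    for row in ens.states:
        trimmed = "".join(str(int(b)) for b in row[idx])
        counts[trimmed] = counts.get(trimmed, 0) + 1
        full.setdefault(trimmed, "".join(str(int(b)) for b in row))
    total = sum(counts.values())
    freqs = {s: c / total for s, c in counts.items()}
    return PhenotypeDistribution(freqs=freqs, nodes=scored_nodes, full_states=full)


def run_boolean_ensemble(
    net: GRNTopology,
    n_ics: int = 100_000,
    max_steps: int = 1000,
    repeats: int = 3,
    seed: int = 0,
    convention: str = "ising",
    scored_nodes: tuple[str, ...] | None = None,
) -> PhenotypeDistribution:
    """Phenotype distribution over fixed points from random initial states.

    Initial conditions are uniform over {0,1}^N.  The frequency of each
    fixed point is the fraction of converged initial conditions reaching it,
    renormalized over converged runs; unconverged runs (trajectories still
    wandering after ``max_steps``, e.g. in a network with only cyclic
    attractors) are excluded.  The ``repeats`` independent replicates are
    averaged at the distribution level.  Signal nodes are trimmed from the
    reported strings (``scored_nodes`` overrides the trimmed node set, e.g.
    to keep a perturbation sweep comparable to its wild-type network).
    """
    _check_convention(convention)
    signal = find_signal_nodes(net)
    seeds = np.random.SeedSequence(seed).spawn(repeats)
    dists = []
    for ss in seeds:
        ens = _run_once(net, n_ics, max_steps, np.random.default_rng(ss), convention)
        dists.append(_ensemble_to_distribution(ens, signal, scored_nodes))
    return PhenotypeDistribution.average(dists)


def boolean_fixed_points(
    net: GRNTopology, convention: str = "ising"
) -> list[np.ndarray]:
    """Exhaustive fixed-point set by enumerating all 2^N states (N <= 20)."""
    _check_convention(convention)
    N = net.n_nodes
    if N > 20:
        raise ValueError("exhaustive enumeration is limited to 20 nodes")
    J = interaction_matrix(net)
    grid = ((np.arange(2**N)[:, None] >> np.arange(N)[::-1]) & 1).astype(np.int8)
    T = _target_states(grid, J, convention)
    fixed = np.all(T == grid, axis=1)
    return [row for row in grid[fixed]]
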