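"""Experiment orchestration: perturbation sweeps, correlation reports, and
random-network percentile analysis.

A sweep simulates a wild-type (WT) network and all of its 2E single-edge
perturbations with one engine, scores every variant with the full metric
panel (dynamical and topological), and collects one row per variant into a
:class:`MetricsTable` — the machine-readable twin of the published heatmap
panels.  Spearman correlations of every metric against hybridness summarize
a table; percentile placement of the WT against degree-preserving random
rewirings asks whether a topological metric is special to the biological
wiring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import boolean as bool_engine
from . import racipe
from .phenotypes import PhenotypeDistribution
from .state_metrics import (
    NodePartition,
    hybridness,
    j_metric,
    jensen_shannon_divergence,
    network_frustration,
    partition_nodes,
    state_correlations,
)
from .topo_metrics import (
    hiloop_census,
    inconsistency,
    influence_loop_strengths,
    influence_matrix,
    loop_census,
    predicted_frustration,
)
from .topology import GRNTopology, enumerate_edge_perturbations, find_signal_nodes, swap_edges_random

__all__ = [
    "EngineConfig",
    "SimulationResult",
    "simulate_network",
    "perturbation_sweep",
    "correlation_report",
    "randomization_percentile",
    "METRICS_COLUMNS",
    "TOPOLOGY_METRICS",
]

logger = logging.getLogger(__name__)

#: Fixed, versioned column set of the metrics table (v1).
METRICS_COLUMNS = [
    "label",
    "engine",
    "kind",
    "hybridness",
    "jsd_vs_wt",
    "j_metric",
    "multistability",
    "frustration_min",
    "frustration_mean",
    "frustration_max",
    "predicted_frustration",
    "pfl",
    "nfl",
    "weighted_pfl",
    "weighted_nfl",
    "pfl_fraction",
    "influence_pos",
    "influence_neg",
    "type1",
    "type2",
    "missa",
    "inconsistency",
    "error",
]


@dataclass(frozen=True)
class EngineConfig:
    """Ensemble sizes and knobs for both engines.

    Defaults here are moderate working sizes; the published protocol sizes
    (10,000 parameter sets x 100 initial conditions for the ODE ensemble,
    100,000 initial conditions for the Boolean one, three repeats each) are
    reachable by configuration.
    """

    engine: str = "boolean"
    # Boolean
    n_ics_boolean: int = 10_000
    max_steps: int = 1000
    convention: str = "ising"
    # ODE
    n_sets: int = 1000
    n_ics_ode: int = 20
    dt: float = 0.1
    window: float = 50.0
    n_windows: int = 20
    convergence_cutoff: float = 1.0
    sampling: racipe.SamplingConfig | None = None
    # shared
    repeats: int = 3
    influence_lmax: int = 10
    cycle_max_len: int | None = None

    def __post_init__(self) -> None:
        if self.engine not in ("boolean", "ode"):
            raise ValueError(f"engine must be 'boolean' or 'ode', got {self.engine!r}")


@dataclass(frozen=True)
class SimulationResult:
    """One engine run on one topology."""

    net: GRNTopology
    distribution: PhenotypeDistribution
    correlations: np.ndarray  # over distribution.nodes
    multistability: float | None  # ODE only


def simulate_network(
    net: GRNTopology,
    config: EngineConfig,
    seed: int,
    scored_nodes: tuple[str, ...] | None = None,
) -> SimulationResult:
    """Run one engine on one topology and package the shared outputs.

    ``scored_nodes`` fixes the reported node set (default: the network's own
    non-signal nodes); a perturbation sweep passes the WT scored set so all
    variants report comparable state strings.
    """
    if scored_nodes is None:
        scored_nodes = tuple(n for n in net.nodes if n not in find_signal_nodes(net))
    if config.engine == "boolean":
        dist = bool_engine.run_boolean_ensemble(
            net,
            n_ics=config.n_ics_boolean,
            max_steps=config.max_steps,
            repeats=config.repeats,
            seed=seed,
            convention=config.convention,
            scored_nodes=scored_nodes,
        )
        corr = state_correlations(dist)
        return SimulationResult(net=net, distribution=dist, correlations=corr,
                                multistability=None)
    ens = racipe.run_ensemble(
        net,
        n_sets=config.n_sets,
        n_ics=config.n_ics_ode,
        repeats=config.repeats,
        seed=seed,
        config=config.sampling,
        dt=config.dt,
        window=config.window,
        n_windows=config.n_windows,
        convergence_cutoff=config.convergence_cutoff,
    )
    dist = racipe.binarize(ens, scored_nodes=scored_nodes)
    corr = ens.correlation_matrix(nodes=scored_nodes)
    return SimulationResult(
        net=net,
        distribution=dist,
        correlations=corr,
        multistability=racipe.multistability_fraction(ens),
    )


def _topology_metrics_row(net: GRNTopology, config: EngineConfig) -> dict:
    census = loop_census(net, max_len=config.cycle_max_len)
    inf = influence_matrix(net, lmax=config.influence_lmax)
    pos, neg = influence_loop_strengths(inf)
    hi = hiloop_census(net, max_len=config.cycle_max_len)
    inc = inconsistency(net)
    return {
        "predicted_frustration": predicted_frustration(net),
        "pfl": census.pfl,
        "nfl": census.nfl,
        "weighted_pfl": census.weighted_pfl,
        "weighted_nfl": census.weighted_nfl,
        "pfl_fraction": census.pfl_fraction,
        "influence_pos": pos,
        "influence_neg": neg,
        "type1": hi.type1,
        "type2": hi.type2,
        "missa": hi.missa,
        "inconsistency": inc.value,
    }


def perturbation_sweep(
    net: GRNTopology,
    config: EngineConfig,
    seed: int,
    anchors: dict[str, str] | None = None,
    variants: list[tuple[str, str, GRNTopology]] | None = None,
) -> pd.DataFrame:
    """Simulate WT plus all single-edge perturbations; one metrics row each.

    The E/M node partition is clustered once from the WT correlation matrix
    and reused for every variant so EMT scores stay comparable; JSD is
    computed against the WT distribution on the union support.  Topological
    metrics are recomputed per variant.  A variant whose simulation fails is
    kept as a row with the ``error`` column set, never dropped.

    ``variants`` overrides the default 2E single-edge perturbation list with
    arbitrary labelled topologies (e.g. random-weight variants).
    """
    scored = tuple(n for n in net.nodes if n not in find_signal_nodes(net))
    wt = simulate_network(net, config, seed=seed, scored_nodes=scored)
    part = partition_nodes(wt.correlations, scored, anchors=anchors)
    rows = [
        _variant_row("WT", "wt", net, wt, wt.distribution, part, config)
    ]
    if variants is None:
        variants = [
            (p.label, p.kind, pnet) for (p, pnet) in enumerate_edge_perturbations(net)
        ]
    child_seeds = np.random.SeedSequence(seed).spawn(len(variants))
    for (label, kind, vnet), ss in zip(variants, child_seeds):
        vseed = int(ss.generate_state(1)[0] % (2**31))
        try:
            res = simulate_network(vnet, config, seed=vseed, scored_nodes=scored)
            rows.append(_variant_row(label, kind, vnet, res, wt.distribution, part, config))
        except Exception as exc:  # simulation failure -> flagged row
            logger.warning("variant %s failed: %s", label, exc)
            row = {c: np.nan for c in METRICS_COLUMNS}
            row.update({"label": label, "engine": config.engine, "kind": kind,
                        "error": str(exc)})
            row.update(_topology_metrics_row(vnet, config))
            rows.append(row)
    df = pd.DataFrame(rows, columns=METRICS_COLUMNS)
    return df


def _variant_row(
    label: str,
    kind: str,
    vnet: GRNTopology,
    res: SimulationResult,
    wt_dist: PhenotypeDistribution,
    part: NodePartition,
    config: EngineConfig,
) -> dict:
    frus = network_frustration(res.distribution, vnet)
    row = {
        "label": label,
        "engine": config.engine,
        "kind": kind,
        "hybridness": hybridness(res.distribution, part),
        "jsd_vs_wt": jensen_shannon_divergence(res.distribution, wt_dist),
        "j_metric": j_metric(res.correlations),
        "multistability": res.multistability if res.multistability is not None else np.nan,
        "frustration_min": frus.min,
        "frustration_mean": frus.mean,
        "frustration_max": frus.max,
        "error": "",
    }
    row.update(_topology_metrics_row(vnet, config))
    return row


def correlation_report(table: pd.DataFrame, against: str = "hybridness") -> pd.DataFrame:
    """Spearman rho and two-sided p of each metric against hybridness.

    Ties get average ranks (scipy default).  A constant metric column has no
    defined rank correlation and is reported as missing (NaN), never as 0.
    Rows with a simulation error are excluded.
    """
    ok = table[table["error"].fillna("").astype(str) == ""] if "error" in table else table
    if len(ok) < 3:
        raise ValueError("need at least 3 successful rows to correlate")
    y = ok[against].astype(float)
    records = []
    skip = {"label", "engine", "kind", "error", against}
    for col in ok.columns:
        if col in skip:
            continue
        x = ok[col].astype(float)
        mask = x.notna() & y.notna()
        n = int(mask.sum())
        if n < 3 or x[mask].nunique() <= 1 or y[mask].nunique() <= 1:
            rho, p = np.nan, np.nan
        else:
            rho, p = stats.spearmanr(x[mask], y[mask])
        records.append(
            {
                "metric": col,
                "rho": rho,
                "p_value": p,
                "n": n,
                "significant": bool(p < 0.05) if np.isfinite(p) else False,
            }
        )
    return pd.DataFrame.from_records(records)


def directionality_experiment(
    n_networks: int = 100,
    n_nodes: int = 8,
    n_edges: int = 16,
    n_ics: int = 4000,
    repeats: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic recovery of the loop-composition/hybridness directionality.

    Generates team-structured random networks (two antagonistic node groups,
    the EMP-like sign pattern), tunes their positive-feedback-loop fraction
    toward targets spanning [0, 1] by single-edge sign flips, simulates each
    with the Boolean engine, and scores hybridness against the planted team
    partition and mean frustration over the fixed points.  Networks whose
    tuned variant has no directed cycle or no reachable fixed point are
    skipped and replaced with fresh seeds until ``n_networks`` rows are
    collected.

    Returns a frame with columns ``pfl_fraction``, ``hybridness`` and
    ``frustration_mean`` — across it, positive-loop-poor (negative-loop-
    rich) networks should show higher hybridness and higher frustration.
    """
    from .synth import SyntheticSpec, generate_team_grn, tune_loop_composition
    from .topo_metrics import loop_census

    targets = np.linspace(0.0, 1.0, n_networks)
    rows: list[dict] = []
    attempt = 0
    max_attempts = 10 * n_networks
    while len(rows) < n_networks and attempt < max_attempts:
        target = float(targets[len(rows)])
        spec = SyntheticSpec(
            n_nodes=n_nodes, n_edges=n_edges, n_signal=0, seed=seed + 1000 * attempt
        )
        attempt += 1
        net, team_a = generate_team_grn(spec)
        try:
            net = tune_loop_composition(net, target, max_iters=4 * n_edges, seed=0)
        except ValueError:
            continue  # acyclic draw: fraction undefined
        census = loop_census(net)
        if census.pfl + census.nfl == 0:
            continue
        try:
            dist = bool_engine.run_boolean_ensemble(
                net, n_ics=n_ics, repeats=repeats, seed=seed + attempt
            )
        except RuntimeError:
            continue  # no fixed point (cyclic attractors only)
        e_nodes = frozenset(n for n in dist.nodes if n in team_a)
        m_nodes = frozenset(n for n in dist.nodes if n not in team_a)
        if not e_nodes or not m_nodes:
            continue
        part = NodePartition(nodes=dist.nodes, e_nodes=e_nodes, m_nodes=m_nodes)
        frus = network_frustration(dist, net)
        rows.append(
            {
                "network": net.name,
                "pfl_fraction": census.pfl_fraction,
                "hybridness": hybridness(dist, part),
                "frustration_mean": frus.mean,
            }
        )
    if len(rows) < n_networks:
        raise RuntimeError(
            f"only {len(rows)}/{n_networks} usable networks after {max_attempts} draws"
        )
    return pd.DataFrame(rows)


#: Topology-only metrics usable in randomization percentile analysis.
TOPOLOGY_METRICS = {
    "pfl": lambda net: loop_census(net).pfl,
    "nfl": lambda net: loop_census(net).nfl,
    "weighted_pfl": lambda net: loop_census(net).weighted_pfl,
    "weighted_nfl": lambda net: loop_census(net).weighted_nfl,
    "pfl_fraction": lambda net: loop_census(net).pfl_fraction,
    "predicted_frustration": predicted_frustration,
    "influence_pos": lambda net: influence_loop_strengths(influence_matrix(net))[0],
    "influence_neg": lambda net: influence_loop_strengths(influence_matrix(net))[1],
    "type1": lambda net: hiloop_census(net).type1,
    "type2": lambda net: hiloop_census(net).type2,
    "missa": lambda net: hiloop_census(net).missa,
    "inconsistency": lambda net: inconsistency(net).value,
}


def randomization_percentile(
    net: GRNTopology,
    metric: str,
    n_random: int = 100,
    n_swaps: int | None = None,
    seed: int = 0,
) -> float:
    """Percentile of the WT metric among degree-preserving random rewirings.

    Generates ``n_random`` swap-randomized networks (default swap count:
    2x the edge count), evaluates the named topological metric on each, and
    places the WT value with the midpoint tie rule:
    ``100 * (below + 0.5 * ties) / n_random``.
    """
    if metric not in TOPOLOGY_METRICS:
        raise ValueError(
            f"unknown metric {metric!r}; choose from {sorted(TOPOLOGY_METRICS)}"
        )
    fn = TOPOLOGY_METRICS[metric]
    wt_value = fn(net)
    if n_swaps is None:
        n_swaps = 2 * net.n_edges
    seeds = np.random.SeedSequence(seed).spawn(n_random)
    values = []
    failures = 0
    for ss in seeds:
        s = int(ss.generate_state(1)[0] % (2**31))
        try:
            values.append(fn(swap_edges_random(net, n_swaps, seed=s)))
        except Exception as exc:
            failures += 1
            logger.warning("random network failed for metric %s: %s", metric, exc)
    if failures > 0.1 * n_random:
        raise RuntimeError(f"{failures}/{n_random} random networks failed")
    v = np.asarray(values, dtype=float)
    below = float(np.sum(v < wt_value))
    ties = float(np.sum(v == wt_value))
    return 100.0 * (below + 0.5 * ties) / len(v)
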