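"""Random-parameter ODE ensemble simulation (RACIPE-style).

Each gene's level obeys ``dX/dt = P_X * prod(H^S(regulators)) - D_X * X``
where every incoming regulation contributes a shifted Hill multiplier

    H^S(x; x0, n, lam) = lam + (1 - lam) / (1 + (x / x0)^n)

with fold change ``lam < 1`` for inhibition and ``lam > 1`` for activation
(H^S(0) = 1, H^S -> lam as x -> inf).  Rather than committing to one
kinetic parameterization, the engine samples thousands of parameter sets
from broad ranges and integrates each from many random initial conditions
by forward Euler; the collected converged steady states, z-scored and
binarized per node, form the phenotype distribution.  The fraction of
parameter sets with more than one distinct stable state is the network's
multistability.

Default ranges follow the RACIPE convention: production P in [1, 100],
degradation D in [0.1, 1], inhibitory fold change in [0.01, 1), activating
fold change in (1, 100], integer Hill coefficient in 1..6, and thresholds
scaled to the regulator's unregulated level P/D.  Sampling is uniform by
default with a truncated-Gaussian option (mid-range mean, range/4 SD).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phenotypes import PhenotypeDistribution
from .topology import GRNTopology, find_signal_nodes

__all__ = [
    "SamplingConfig",
    "ParameterEnsemble",
    "SteadyStateEnsemble",
    "shifted_hill",
    "sample_parameters",
    "integrate_circuit",
    "run_ensemble",
    "binarize",
    "multistability_fraction",
]


def shifted_hill(x, x0, n, lam):
    """Shifted Hill regulation multiplier.

    ``lam + (1 - lam) / (1 + (x / x0)^n)``: equals 1 at x = 0 and tends to
    ``lam`` as x -> infinity; monotone decreasing toward ``lam`` for
    inhibition (lam < 1), increasing for activation (lam > 1).
    """
    x0 = np.asarray(x0, dtype=float)
    if np.any(x0 <= 0):
        raise ValueError("Hill threshold x0 must be positive")
    ratio = np.asarray(x, dtype=float) / x0
    return lam + (1.0 - lam) / (1.0 + ratio**np.asarray(n))


@dataclass(frozen=True)
class SamplingConfig:
    """Parameter ranges and sampling distribution for the ensemble.

    ``y0_scale`` bounds the per-edge threshold as multiples of the
    regulator's unregulated level M = P_src / D_src of the same parameter
    set.  ``distribution`` is ``uniform`` or ``gaussian`` (truncated at the
    range bounds, mean at mid-range, SD = range/4).
    """

    production: tuple[float, float] = (1.0, 100.0)
    degradation: tuple[float, float] = (0.1, 1.0)
    lambda_inhibition: tuple[float, float] = (0.01, 1.0)
    lambda_activation: tuple[float, float] = (1.0, 100.0)
    hill_coefficient: tuple[int, int] = (1, 6)
    y0_scale: tuple[float, float] = (0.02, 1.98)
    distribution: str = "uniform"

    def __post_init__(self) -> None:
        for name in ("production", "degradation", "lambda_inhibition",
                     "lambda_activation", "hill_coefficient", "y0_scale"):
            lo, hi = getattr(self, name)
            if lo >= hi:
                raise ValueError(f"{name} range ({lo}, {hi}) has min >= max")
        if self.distribution not in ("uniform", "gaussian"):
            raise ValueError("distribution must be 'uniform' or 'gaussian'")


@dataclass(frozen=True)
class ParameterEnsemble:
    """Sampled kinetic parameters for ``n_sets`` models of one topology."""

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str, int], ...]  # (source, target, sign)
    production: np.ndarray  # (n_sets, N)
    degradation: np.ndarray  # (n_sets, N)
    fold_change: np.ndarray  # (n_sets, E)
    hill: np.ndarray  # (n_sets, E) integer
    threshold: np.ndarray  # (n_sets, E)
    config: SamplingConfig = field(default_factory=SamplingConfig)
    seed: int | None = None

    @property
    def n_sets(self) -> int:
        return self.production.shape[0]


def _draw(rng: np.random.Generator, lo: float, hi: float, size, distribution: str) -> np.ndarray:
    if distribution == "uniform":
        return rng.uniform(lo, hi, size=size)
    from scipy import stats

    mean, sd = (lo + hi) / 2.0, (hi - lo) / 4.0
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def sample_parameters(
    net: GRNTopology,
    n_sets: int,
    config: SamplingConfig | None = None,
    seed: int = 0,
) -> ParameterEnsemble:
    """Draw ``n_sets`` random kinetic parameter sets for a topology.

    Inhibitory edges get fold changes below 1, activating edges above 1;
    Hill coefficients are integers; each edge threshold is drawn relative to
    its source's unregulated level P_src/D_src within the same set.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    cfg = config or SamplingConfig()
    rng = np.random.default_rng(seed)
    N, E = net.n_nodes, net.n_edges
    idx = net.node_index()
    P = _draw(rng, *cfg.production, (n_sets, N), cfg.distribution)
    D = _draw(rng, *cfg.degradation, (n_sets, N), cfg.distribution)
    lam = np.empty((n_sets, E))
    for j, e in enumerate(net.edges):
        if e.sign < 0:
            # reciprocal-of-uniform: fold *strength* 1/lambda is uniform on
            # [1/hi, 1/lo], so repression is typically strong (median
            # lambda ~ 2/(1/lo + 1/hi)) while lambda stays in the range
            lo, hi = cfg.lambda_inhibition
            strength = _draw(rng, 1.0 / hi, 1.0 / lo, n_sets, cfg.distribution)
            lam[:, j] = 1.0 / strength
        else:
            lam[:, j] = _draw(rng, *cfg.lambda_activation, n_sets, cfg.distribution)
    lo_n, hi_n = cfg.hill_coefficient
    hill = rng.integers(lo_n, hi_n + 1, size=(n_sets, E))
    src = np.array([idx[e.source] for e in net.edges], dtype=int)
    M = P[:, src] / D[:, src]  # unregulated level of each edge's source
    u = _draw(rng, *cfg.y0_scale, (n_sets, E), cfg.distribution)
    Y0 = u * M
    return ParameterEnsemble(
        nodes=net.nodes,
        edges=tuple((e.source, e.target, e.sign) for e in net.edges),
        production=P,
        degradation=D,
        fold_change=lam,
        hill=hill,
        threshold=Y0,
        config=cfg,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Integration


def _euler_batch_numpy(
    X: np.ndarray,
    src: np.ndarray,
    tgt: np.ndarray,
    P: np.ndarray,
    D: np.ndarray,
    lam: np.ndarray,
    hill: np.ndarray,
    Y0: np.ndarray,
    dt: float,
    n_steps: int,
) -> np.ndarray:
    """Advance all trajectories ``n_steps`` Euler steps in place.

    ``X`` has shape (..., N); parameter arrays broadcast against the leading
    axes (one parameter set per leading row).
    """
    for _ in range(n_steps):
        prod = np.ones_like(X)
        if src.size:
            xs = X[..., src]
            with np.errstate(over="ignore", invalid="ignore"):
                h = lam + (1.0 - lam) / (1.0 + (xs / Y0) ** hill)
            for j in range(src.size):
                prod[..., tgt[j]] *= h[..., j]
        X += dt * (P * prod - D * X)
        np.maximum(X, 0.0, out=X)
    return X


def _make_euler_numba():
    try:
        import numba
    except ImportError:  # pragma: no cover
        return None

    @numba.njit(cache=True, fastmath=False)
    def _kernel(X, src, tgt, P, D, lam, hill, Y0, dt, n_steps):  # pragma: no cover
        R, N = X.shape
        E = src.shape[0]
        for r in range(R):
            for _ in range(n_steps):
                prod = np.ones(N)
                for j in range(E):
                    ratio = X[r, src[j]] / Y0[r, j]
                    # integer Hill exponent: repeated multiply beats pow
                    rn = ratio
                    for _k in range(hill[r, j] - 1):
                        rn *= ratio
                    h = lam[r, j] + (1.0 - lam[r, j]) / (1.0 + rn)
                    prod[tgt[j]] *= h
                for i in range(N):
                    x_new = X[r, i] + dt * (P[r, i] * prod[i] - D[r, i] * X[r, i])
                    X[r, i] = x_new if x_new > 0.0 else 0.0
        return X

    return _kernel


_euler_numba = _make_euler_numba()


def _euler_batch(X, src, tgt, P, D, lam, hill, Y0, dt, n_steps):
    """Dispatch to the compiled kernel for flat (rows, N) batches."""
    if _euler_numba is not None and X.ndim == 2 and P.shape == X.shape:
        return _euler_numba(
            np.ascontiguousarray(X),
            src,
            tgt,
            np.ascontiguousarray(P),
            np.ascontiguousarray(D),
            np.ascontiguousarray(lam),
            np.ascontiguousarray(hill.astype(np.int64)),
            np.ascontiguousarray(Y0),
            dt,
            n_steps,
        )
    return _euler_batch_numpy(X, src, tgt, P, D, lam, hill, Y0, dt, n_steps)


def integrate_circuit(
    net: GRNTopology,
    params: ParameterEnsemble,
    ic,
    param_set: int = 0,
    dt: float = 0.1,
    window: float = 50.0,
    n_windows: int = 20,
    convergence_cutoff: float = 1.0,
) -> tuple[bool, np.ndarray]:
    """Integrate one parameter set from one initial condition.

    Forward Euler with step ``dt``, run in ``n_windows`` successive windows
    of ``window`` time units; the run is converged once the node-wise
    absolute change across one window falls below ``convergence_cutoff``.
    Levels are clipped at zero.  A trajectory that overflows to NaN is
    reported unconverged.
    """
    idx = net.node_index()
    src = np.array([idx[s] for (s, _t, _g) in params.edges], dtype=int)
    tgt = np.array([idx[t] for (_s, t, _g) in params.edges], dtype=int)
    X = np.asarray(ic, dtype=float).copy()
    if X.shape != (net.n_nodes,) or np.any(X < 0):
        raise ValueError("ic must be a non-negative vector over all nodes")
    k = param_set
    steps = max(int(round(window / dt)), 1)
    args = (
        params.production[k],
        params.degradation[k],
        params.fold_change[k],
        params.hill[k],
        params.threshold[k],
    )
    converged = False
    for _ in range(n_windows):
        prev = X.copy()
        X = _euler_batch(X, src, tgt, *args, dt, steps)
        if not np.all(np.isfinite(X)):
            return False, X
        if np.max(np.abs(X - prev)) < convergence_cutoff:
            converged = True
            break
    return converged, X


@dataclass(frozen=True)
class RepeatBlock:
    """Raw converged states of one repeat: runs indexed (set, ic)."""

    states: np.ndarray  # (n_sets, n_ics, N) final levels
    converged: np.ndarray  # (n_sets, n_ics) bool


@dataclass(frozen=True)
class SteadyStateEnsemble:
    """Converged steady states of a full ensemble simulation.

    Holds one :class:`RepeatBlock` per repeat plus the merge tolerance used
    to call two states of the same parameter set "the same" (maximum
    node-wise absolute difference below the tolerance).
    """

    nodes: tuple[str, ...]
    repeats: tuple[RepeatBlock, ...]
    merge_tolerance: float = 1.0

    def distinct_state_counts(self) -> list[np.ndarray]:
        """Per repeat: array of distinct-stable-state counts per parameter
        set (0 where nothing converged)."""
        out = []
        for block in self.repeats:
            n_sets = block.states.shape[0]
            counts = np.zeros(n_sets, dtype=int)
            for k in range(n_sets):
                states = block.states[k][block.converged[k]]
                counts[k] = len(_merge_states(states, self.merge_tolerance))
            out.append(counts)
        return out

    def pooled_states(self) -> np.ndarray:
        """All converged final states across sets, ICs and repeats: (M, N)."""
        chunks = [b.states[b.converged] for b in self.repeats]
        return np.concatenate(chunks, axis=0) if chunks else np.empty((0, len(self.nodes)))

    def correlation_matrix(self, nodes: tuple[str, ...] | None = None) -> np.ndarray:
        """Pearson correlations of node levels across all converged runs."""
        pooled = self.pooled_states()
        if nodes is not None:
            cols = [self.nodes.index(n) for n in nodes]
            pooled = pooled[:, cols]
        with np.errstate(invalid="ignore"):
            C = np.corrcoef(pooled, rowvar=False)
        return np.nan_to_num(np.atleast_2d(C))


def _merge_states(states: np.ndarray, tol: float) -> list[np.ndarray]:
    """Greedy merge: a state joins the first representative within ``tol``
    (max node-wise absolute difference), else founds a new one."""
    reps: list[np.ndarray] = []
    for s in states:
        for r in reps:
            if np.max(np.abs(s - r)) < tol:
                break
        else:
            reps.append(s)
    return reps


def run_ensemble(
    net: GRNTopology,
    n_sets: int = 10_000,
    n_ics: int = 100,
    repeats: int = 3,
    seed: int = 0,
    config: SamplingConfig | None = None,
    dt: float = 0.1,
    window: float = 50.0,
    n_windows: int = 20,
    convergence_cutoff: float = 1.0,
) -> SteadyStateEnsemble:
    """Simulate the full random-parameter ensemble.

    For each repeat (independent sampling seed): draw ``n_sets`` parameter
    sets, draw ``n_ics`` initial conditions per set uniformly on
    [0, 1.5 * P/D] per node, and integrate all runs by windowed forward
    Euler until the per-window change falls below ``convergence_cutoff`` or
    the horizon (``n_windows * window`` time units) is exhausted.
    Non-convergence is recorded per run, never fatal.
    """
    idx = net.node_index()
    src = np.array([idx[e.source] for e in net.edges], dtype=int)
    tgt = np.array([idx[e.target] for e in net.edges], dtype=int)
    steps = max(int(round(window / dt)), 1)
    N = net.n_nodes
    blocks = []
    seeds = np.random.SeedSequence(seed).spawn(repeats)
    for ss in seeds:
        child = ss.generate_state(1)[0] % (2**31)
        params = sample_parameters(net, n_sets, config=config, seed=int(child))
        rng = np.random.default_rng(ss)
        hi = 1.5 * params.production / params.degradation  # (n_sets, N)
        X0 = rng.uniform(0.0, 1.0, size=(n_sets, n_ics, N)) * hi[:, None, :]
        # flatten runs to rows so converged ones can be retired cheaply
        rows = n_sets * n_ics
        X = X0.reshape(rows, N)
        rep = np.repeat(np.arange(n_sets), n_ics)
        P = params.production[rep]
        D = params.degradation[rep]
        lam = params.fold_change[rep]
        hillc = params.hill[rep]
        Y0 = params.threshold[rep]
        final = np.zeros((rows, N))
        converged = np.zeros(rows, dtype=bool)
        active = np.arange(rows)
        for _ in range(n_windows):
            if active.size == 0:
                break
            prev = X.copy()
            X = _euler_batch(
                X, src, tgt, P[active], D[active], lam[active], hillc[active],
                Y0[active], dt, steps,
            )
            delta = np.max(np.abs(X - prev), axis=-1)
            done = (delta < convergence_cutoff) & np.all(np.isfinite(X), axis=-1)
            if done.any():
                final[active[done]] = X[done]
                converged[active[done]] = True
                active = active[~done]
                X = X[~done]
        if active.size:  # horizon exhausted: record last levels, unconverged
            final[active] = np.nan_to_num(X, nan=0.0, posinf=0.0, neginf=0.0)
        blocks.append(
            RepeatBlock(
                states=final.reshape(n_sets, n_ics, N),
                converged=converged.reshape(n_sets, n_ics),
            )
        )
    return SteadyStateEnsemble(
        nodes=net.nodes, repeats=tuple(blocks), merge_tolerance=convergence_cutoff
    )


def binarize(
    ens: SteadyStateEnsemble,
    signal_nodes: set[str] | None = None,
    scored_nodes: tuple[str, ...] | None = None,
    log2_transform: bool = False,
) -> PhenotypeDistribution:
    """Z-score and binarize converged steady states into a distribution.

    Per repeat and per node, the mean and standard deviation are computed
    over all converged runs across all parameter sets; levels with positive
    z-score map to 1, negative to 0.  Signal nodes are trimmed from the
    reported strings.  Frequencies are fractions of converged runs,
    renormalized; repeats are averaged at the distribution level.

    ``log2_transform`` applies log2(x + eps) before z-scoring (off by
    default).  A node with zero variance raises, naming the node.
    """
    if signal_nodes is None:
        signal_nodes = set()
    nodes = ens.nodes
    if scored_nodes is None:
        scored_nodes = tuple(n for n in nodes if n not in signal_nodes)
    cols = [nodes.index(n) for n in scored_nodes]
    dists = []
    for block in ens.repeats:
        pooled = block.states[block.converged]
        if pooled.shape[0] == 0:
            raise RuntimeError("no converged steady states to binarize")
        levels = np.log2(pooled + 1e-12) if log2_transform else pooled
        mu = levels.mean(axis=0)
        sigma = levels.std(axis=0)
        zero = np.where(sigma == 0)[0]
        if zero.size:
            raise ValueError(
                f"zero variance for node {nodes[zero[0]]!r}; cannot z-score"
            )
        bits = (levels - mu) / sigma > 0
        counts: dict[str, int] = {}
        full: dict[str, str] = {}
        for row in bits:
            trimmed = "".join("1" if row[c] else "0" for c in cols)
            counts[trimmed] = counts.get(trimmed, 0) + 1
            full.setdefault(trimmed, "".join("1" if b else "0" for b in row))
        total = sum(counts.values())
        dists.append(
            PhenotypeDistribution(
                freqs={s: c / total for s, c in counts.items()},
                nodes=scored_nodes,
                full_states=full,
            )
        )
    return PhenotypeDistribution.average(dists)


def multistability_fraction(ens: SteadyStateEnsemble) -> float:
    """Fraction of parameter sets with more than one distinct stable state,
    averaged over repeats."""
    fracs = []
    for counts in ens.distinct_state_counts():
        informative = counts[counts > 0]
        if informative.size == 0:
            raise RuntimeError("no parameter set produced a converged state")
        fracs.append(float(np.mean(informative > 1)))
    return float(np.mean(fracs))
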