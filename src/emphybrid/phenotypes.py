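"""Normalized frequency distributions over binarized steady states.

Both simulation engines emit the same currency: a map from a binarized
state string (bit per scored node, signal nodes trimmed) to the normalized
frequency with which independent runs converged there.  All downstream
metrics — hybridness, Jensen–Shannon divergence, frustration statistics —
consume this object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PhenotypeDistribution"]

_NORM_TOL = 1e-9


@dataclass(frozen=True)
class PhenotypeDistribution:
    """Frequencies over binarized steady states.

    Parameters
    ----------
    freqs
        State string (over ``nodes``, fixed order) -> normalized frequency.
    nodes
        The scored (non-signal) nodes, in bit order.
    full_states
        Optional map from each scored state string to a representative full
        state string over every network node (signal bits included) — needed
        by frustration, which divides by the total edge count and therefore
        sees edges from signal nodes.
    """

    freqs: dict[str, float]
    nodes: tuple[str, ...]
    full_states: dict[str, str] | None = None

    def __post_init__(self) -> None:
        width = len(self.nodes)
        for s, f in self.freqs.items():
            if len(s) != width or set(s) - {"0", "1"}:
                raise ValueError(f"malformed state string {s!r} for {width} nodes")
            if f < 0:
                raise ValueError(f"negative frequency for state {s!r}")
        total = sum(self.freqs.values())
        if self.freqs and abs(total - 1.0) > _NORM_TOL:
            raise ValueError(f"frequencies sum to {total}, expected 1")

    def __len__(self) -> int:
        return len(self.freqs)

    def __getitem__(self, state: str) -> float:
        return self.freqs.get(state, 0.0)

    def support(self) -> tuple[str, ...]:
        return tuple(sorted(self.freqs))

    def align(self, other: "PhenotypeDistribution") -> tuple[np.ndarray, np.ndarray]:
        """Frequency vectors of both distributions on the union support
        (missing states at frequency 0)."""
        if self.nodes != other.nodes:
            raise ValueError("distributions are over different node sets")
        states = sorted(set(self.freqs) | set(other.freqs))
        p = np.array([self[s] for s in states])
        q = np.array([other[s] for s in states])
        return p, q

    @staticmethod
    def average(dists: list["PhenotypeDistribution"]) -> "PhenotypeDistribution":
        """Pointwise average of repeat distributions, renormalized."""
        if not dists:
            raise ValueError("no distributions to average")
        nodes = dists[0].nodes
        if any(d.nodes != nodes for d in dists):
            raise ValueError("distributions are over different node sets")
        acc: dict[str, float] = {}
        full: dict[str, str] = {}
        for d in dists:
            for s, f in d.freqs.items():
                acc[s] = acc.get(s, 0.0) + f
            if d.full_states:
                for s, fs in d.full_states.items():
                    full.setdefault(s, fs)
        total = sum(acc.values())
        freqs = {s: f / total for s, f in acc.items()}
        return PhenotypeDistribution(freqs=freqs, nodes=nodes, full_states=full or None)
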