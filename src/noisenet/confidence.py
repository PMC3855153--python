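"""Bootstrap edge-confidence estimation (Friedman confidence).

The confidence of an edge is the fraction of structure-learning replicates
in which the edge appears.  Two bootstrap modes are provided:

* parametric  — each replicate is an independent simulation from a known
  motif model (used when the generating model is known a priori);
* nonparametric — each replicate resamples rows of an observed dataset with
  replacement (with per-replicate column centering).

Bookkeeping convention (documented in the output schema): a directed arc
a->b in a replicate adds 1 to the (a, b) tally; an undirected edge a-b adds
0.5 to each direction's tally and 1 to the pair's undirected tally.  The
pair-level adjacency confidence (fraction of replicates in which the pair is
connected at all, in any orientation) is exposed separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .motif_models import ExpressionMatrix, LinearMotif, center_columns, simulate
from .structure_learning import PDAG, learn_structure

__all__ = [
    "EdgeConfidenceTable",
    "parametric_confidence",
    "nonparametric_confidence",
    "threshold_edges",
]

log = logging.getLogger(__name__)

#: Rule-of-thumb cutoffs: edges with confidence >= HIGH are deemed
#: significant, those <= LOW unreliable (configurable everywhere they are used).
CONFIDENCE_HIGH = 0.8
CONFIDENCE_LOW = 0.2


@dataclass
class EdgeConfidenceTable:
    """Per-edge bootstrap confidences over R structure-learning replicates."""

    nodes: list[str]
    replicates: int
    directed_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    undirected_counts: dict[frozenset[str], int] = field(default_factory=dict)
    failures: list[int] = field(default_factory=list)
    alpha: float = 0.01
    algorithm: str = "gs"
    mode: str = "parametric"

    def add_replicate(self, pdag: PDAG) -> None:
        for a, b in pdag.directed_arcs:
            self.directed_counts[(a, b)] = self.directed_counts.get((a, b), 0) + 1
        for e in pdag.undirected_edges:
            self.undirected_counts[e] = self.undirected_counts.get(e, 0) + 1

    def confidence(self, a: str, b: str) -> float:
        """Directional confidence of a->b (undirected occurrences count 0.5)."""
        d = self.directed_counts.get((a, b), 0)
        u = self.undirected_counts.get(frozenset((a, b)), 0)
        return (d + 0.5 * u) / self.replicates

    def undirected_fraction(self, a: str, b: str) -> float:
        return self.undirected_counts.get(frozenset((a, b)), 0) / self.replicates

    def adjacency_confidence(self, a: str, b: str) -> float:
        """Fraction of replicates in which a and b are connected at all."""
        d = self.directed_counts.get((a, b), 0) + self.directed_counts.get((b, a), 0)
        u = self.undirected_counts.get(frozenset((a, b)), 0)
        return (d + u) / self.replicates

    @property
    def entries(self) -> dict[tuple[str, str], float]:
        out = {}
        for i, a in enumerate(self.nodes):
            for b in self.nodes[i + 1 :]:
                out[(a, b)] = self.confidence(a, b)
                out[(b, a)] = self.confidence(b, a)
        return out

    def as_rows(self) -> list[dict]:
        rows = []
        for i, a in enumerate(self.nodes):
            for b in self.nodes[i + 1 :]:
                for u, v in ((a, b), (b, a)):
                    rows.append(
                        {
                            "from": u,
                            "to": v,
                            "confidence": self.confidence(u, v),
                            "undirected_fraction": self.undirected_fraction(u, v),
                            "adjacency_confidence": self.adjacency_confidence(u, v),
                        }
                    )
        return rows

    def as_dict(self) -> dict:
        return {
            "replicates": self.replicates,
            "alpha": self.alpha,
            "algorithm": self.algorithm,
            "mode": self.mode,
            "failed_replicates": list(self.failures),
            "edges": self.as_rows(),
        }


def _run_replicates(
    datasets,
    nodes: list[str],
    replicates: int,
    alpha: float,
    algorithm: str,
    symmetry_rule: str,
    mode: str,
) -> EdgeConfidenceTable:
    table = EdgeConfidenceTable(
        nodes=nodes, replicates=replicates, alpha=alpha, algorithm=algorithm, mode=mode
    )
    for r, data in enumerate(datasets):
        try:
            pdag = learn_structure(
                data, algorithm=algorithm, alpha=alpha, symmetry_rule=symmetry_rule
            )
        except ValueError as exc:
            table.failures.append(r)
            log.warning("replicate %d failed: %s", r, exc)
            continue
        table.add_replicate(pdag)
    return table


def parametric_confidence(
    model: LinearMotif,
    n: int = 2000,
    R: int = 200,
    alpha: float = 0.01,
    algorithm: str = "gs",
    symmetry_rule: str = "AND",
    seed: int = 0,
) -> EdgeConfidenceTable:
    """Edge confidences over R independent simulations from a known model.

    Each replicate uses a child RNG stream spawned deterministically from the
    root seed, so any replicate is reproducible in isolation.
    """
    if R < 1:
        raise ValueError("need at least one replicate")
    if n < 10:
        raise ValueError("need n >= 10 per replicate")
    streams = np.random.SeedSequence(seed).spawn(R)
    datasets = (simulate(model, n, np.random.default_rng(s)) for s in streams)
    from .motif_models import MOTIF_NODES

    return _run_replicates(
        datasets, list(MOTIF_NODES), R, alpha, algorithm, symmetry_rule, "parametric"
    )


def nonparametric_confidence(
    data: ExpressionMatrix,
    m: int | None = None,
    R: int = 200,
    alpha: float = 0.01,
    algorithm: str = "gs",
    symmetry_rule: str = "AND",
    seed: int = 0,
) -> EdgeConfidenceTable:
    """Edge confidences over R row-resamples (with replacement, size m).

    Each resample is column-centered before learning, mirroring the
    single-cell analysis protocol.
    """
    if R < 1:
        raise ValueError("need at least one replicate")
    m = data.n if m is None else m
    if m < 10:
        raise ValueError("resample size m must be >= 10")
    streams = np.random.SeedSequence(seed).spawn(R)

    def gen():
        for s in streams:
            rng = np.random.default_rng(s)
            rows = rng.integers(0, data.n, size=m)
            yield center_columns(
                ExpressionMatrix(data.values[rows], list(data.variable_names))
            )

    return _run_replicates(
        gen(), list(data.variable_names), R, alpha, algorithm, symmetry_rule, "nonparametric"
    )


def threshold_edges(table: EdgeConfidenceTable, c: float) -> set[tuple[str, str]]:
    """Ordered node pairs whose directional confidence is at least c."""
    if not 0.0 <= c <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    return {pair for pair, conf in table.entries.items() if conf >= c and conf > 0}
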