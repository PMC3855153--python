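"""Constraint-based Bayesian network structure learning.

Grow-Shrink (GS) and Incremental Association (IAMB) Markov-blanket
discovery, symmetry checking/correction, neighbour resolution, v-structure
orientation and Meek-style orientation propagation, producing a PDAG
(partially directed acyclic graph).

The conditional-independence test is pluggable: the default is the exact
t-test for the (partial) Pearson correlation computed from the data
(:class:`~noisenet.dependence.CorrelationTester`); a
:class:`DSeparationOracle` answering d-separation queries on a known DAG can
be substituted to check soundness of the algorithms independently of any
finite sample.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Protocol

import networkx as nx

from .dependence import CITestResult, CorrelationTester
from .motif_models import ExpressionMatrix

__all__ = [
    "MarkovBlanketSet",
    "PDAG",
    "DSeparationOracle",
    "gs_markov_blanket",
    "iamb_markov_blanket",
    "learn_blankets",
    "check_symmetry",
    "symmetry_correct",
    "blankets_to_skeleton",
    "orient_v_structures",
    "propagate_orientations",
    "learn_structure",
]

log = logging.getLogger(__name__)


class IndependenceTester(Protocol):
    names: list[str]

    def test(self, x: str, y: str, S: Iterable[str] = ()) -> CITestResult: ...


class DSeparationOracle:
    """Answers conditional-independence queries by d-separation on a DAG.

    Used as a drop-in replacement for the sample-based test: on the true
    distribution of a faithful DAG the learners must recover exactly the
    CPDAG of the generating graph.
    """

    def __init__(self, nodes: Iterable[str], edges: Iterable[tuple[str, str]]):
        self.names = list(nodes)
        self.graph = nx.DiGraph()
        self.graph.add_nodes_from(self.names)
        self.graph.add_edges_from(edges)
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("oracle graph must be a DAG")

    def test(self, x: str, y: str, S: Iterable[str] = ()) -> CITestResult:
        S = tuple(S)
        independent = nx.is_d_separator(self.graph, {x}, {y}, set(S))
        # Pseudo-statistics so IAMB's association ranking remains defined.
        stat = 0.0 if independent else 1.0
        return CITestResult(
            r=stat,
            statistic=stat,
            df=1,
            p_value=1.0 if independent else 0.0,
            independent=independent,
            conditioning_set=S,
        )


@dataclass
class MarkovBlanketSet:
    """Per-node Markov blankets at a given significance level."""

    blankets: dict[str, set[str]]
    alpha: float

    @property
    def symmetric(self) -> bool:
        return not check_symmetry(self)


@dataclass
class PDAG:
    """Partially directed acyclic graph with separating-set bookkeeping."""

    nodes: list[str]
    directed_arcs: set[tuple[str, str]] = field(default_factory=set)
    undirected_edges: set[frozenset[str]] = field(default_factory=set)
    separation_sets: dict[frozenset[str], frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for a, b in self.directed_arcs:
            if a == b:
                raise ValueError("self-loops are not allowed")
        for e in self.undirected_edges:
            if len(e) != 2:
                raise ValueError("undirected edges must join two distinct nodes")
        overlap = {frozenset(e) for e in self.directed_arcs} & self.undirected_edges
        if overlap:
            raise ValueError(f"edges both directed and undirected: {sorted(overlap)}")
        if self.has_directed_cycle():
            raise ValueError("directed arcs contain a cycle")

    def adjacent(self, a: str, b: str) -> bool:
        return (
            frozenset((a, b)) in self.undirected_edges
            or (a, b) in self.directed_arcs
            or (b, a) in self.directed_arcs
        )

    def neighbors(self, a: str) -> set[str]:
        out = {b for b in self.nodes if b != a and self.adjacent(a, b)}
        return out

    def has_directed_cycle(self) -> bool:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.directed_arcs)
        return not nx.is_directed_acyclic_graph(g)

    def orient(self, a: str, b: str) -> None:
        """Turn the undirected edge a-b into the arc a->b."""
        self.undirected_edges.discard(frozenset((a, b)))
        self.directed_arcs.add((a, b))

    def copy(self) -> "PDAG":
        return PDAG(
            list(self.nodes),
            set(self.directed_arcs),
            set(self.undirected_edges),
            dict(self.separation_sets),
        )

    def edge_list(self) -> list[tuple[str, str, str]]:
        rows = [(a, b, "directed") for a, b in sorted(self.directed_arcs)]
        rows += [(a, b, "undirected") for a, b in sorted(tuple(sorted(e)) for e in self.undirected_edges)]
        return rows

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PDAG):
            return NotImplemented
        return (
            set(self.nodes) == set(other.nodes)
            and self.directed_arcs == other.directed_arcs
            and self.undirected_edges == other.undirected_edges
        )


def _as_tester(data_or_tester, alpha: float) -> IndependenceTester:
    if isinstance(data_or_tester, ExpressionMatrix):
        return CorrelationTester(data_or_tester, alpha)
    return data_or_tester


# ---------------------------------------------------------------------------
# Markov-blanket discovery
# ---------------------------------------------------------------------------

def gs_markov_blanket(data, target: str, alpha: float = 0.01) -> set[str]:
    """Grow-Shrink Markov blanket of ``target``.

    Growing phase: sweep candidates in fixed column order, adding any
    variable dependent on the target given the current blanket, until a full
    sweep adds nothing.  Shrinking phase: remove any member independent of
    the target given the rest of the blanket, until stable.
    """
    tester = _as_tester(data, alpha)
    if target not in tester.names:
        raise KeyError(f"unknown target {target!r}")
    candidates = [v for v in tester.names if v != target]
    blanket: list[str] = []
    changed = True
    while changed:
        changed = False
        for v in candidates:
            if v in blanket:
                continue
            if not tester.test(target, v, tuple(blanket)).independent:
                blanket.append(v)
                changed = True
    changed = True
    while changed:
        changed = False
        for v in list(blanket):
            rest = tuple(w for w in blanket if w != v)
            if tester.test(target, v, rest).independent:
                blanket.remove(v)
                changed = True
    return set(blanket)


def iamb_markov_blanket(data, target: str, alpha: float = 0.01) -> set[str]:
    """IAMB Markov blanket: forward stepwise selection by strongest
    association (|t| of the CI test), then the same shrinking phase as GS.
    Ties break on fixed column order."""
    tester = _as_tester(data, alpha)
    if target not in tester.names:
        raise KeyError(f"unknown target {target!r}")
    candidates = [v for v in tester.names if v != target]
    blanket: list[str] = []
    while True:
        best: str | None = None
        best_assoc = 0.0
        for v in candidates:
            if v in blanket:
                continue
            res = tester.test(target, v, tuple(blanket))
            if res.independent:
                continue
            assoc = abs(res.statistic)
            if assoc > best_assoc:  # strict: earlier column wins ties
                best, best_assoc = v, assoc
        if best is None:
            break
        blanket.append(best)
    changed = True
    while changed:
        changed = False
        for v in list(blanket):
            rest = tuple(w for w in blanket if w != v)
            if tester.test(target, v, rest).independent:
                blanket.remove(v)
                changed = True
    return set(blanket)


def learn_blankets(data, algorithm: str = "gs", alpha: float = 0.01) -> MarkovBlanketSet:
    """Markov blankets for every variable, by GS or IAMB."""
    tester = _as_tester(data, alpha)
    fn = {"gs": gs_markov_blanket, "iamb": iamb_markov_blanket}.get(algorithm)
    if fn is None:
        raise ValueError(f"unknown algorithm {algorithm!r}; expected 'gs' or 'iamb'")
    return MarkovBlanketSet(
        blankets={v: fn(tester, v, alpha) for v in tester.names}, alpha=alpha
    )


def check_symmetry(blankets: MarkovBlanketSet) -> list[tuple[str, str]]:
    """Ordered pairs (a, b) with b in Mb(a) but a not in Mb(b).

    Markov blankets are symmetric by definition; violations are a
    finite-sample symptom of distorted conditional-independence tests."""
    out = []
    for a in sorted(blankets.blankets):
        for b in sorted(blankets.blankets[a]):
            if a not in blankets.blankets.get(b, set()):
                out.append((a, b))
    return out


def symmetry_correct(blankets: MarkovBlanketSet, rule: str = "AND") -> MarkovBlanketSet:
    """Make the blanket set symmetric.

    AND keeps b in Mb(a) only if a is in Mb(b) (conservative removal);
    OR adds a to Mb(b) whenever b is in Mb(a).  Both are idempotent.
    """
    if rule not in ("AND", "OR"):
        raise ValueError(f"rule must be 'AND' or 'OR', got {rule!r}")
    bl = {a: set(s) for a, s in blankets.blankets.items()}
    out: dict[str, set[str]] = {a: set() for a in bl}
    for a in bl:
        for b in bl[a]:
            if rule == "AND":
                if a in bl.get(b, set()):
                    out[a].add(b)
            else:
                out[a].add(b)
                out.setdefault(b, set()).add(a)
    return MarkovBlanketSet(blankets=out, alpha=blankets.alpha)


# ---------------------------------------------------------------------------
# Skeleton and orientation
# ---------------------------------------------------------------------------

def _subsets_in_order(pool: list[str], max_size: int | None = None):
    """Subsets of ``pool`` by increasing size, then lexicographic order."""
    limit = len(pool) if max_size is None else min(max_size, len(pool))
    for size in range(limit + 1):
        yield from itertools.combinations(sorted(pool), size)


def blankets_to_skeleton(data, blankets: MarkovBlanketSet, alpha: float = 0.01) -> PDAG:
    """Reduce symmetric Markov blankets to an undirected skeleton.

    For every candidate pair, separating sets are searched within the union
    of the two blankets (endpoints removed) in order of increasing size; the
    first separating set found is recorded, and pairs never separated become
    undirected edges.  Separating sets are also recorded for non-blanket
    pairs so that v-structure identification has them available.
    """
    tester = _as_tester(data, alpha)
    if check_symmetry(blankets):
        raise ValueError("blankets must be symmetric; apply symmetry_correct first")
    nodes = list(tester.names)
    pdag = PDAG(nodes=nodes)
    for a, b in itertools.combinations(nodes, 2):
        in_blanket = b in blankets.blankets.get(a, set())
        pool = sorted(
            (blankets.blankets.get(a, set()) | blankets.blankets.get(b, set())) - {a, b}
        )
        sepset: frozenset[str] | None = None
        for S in _subsets_in_order(pool):
            if tester.test(a, b, S).independent:
                sepset = frozenset(S)
                break
        if sepset is not None:
            pdag.separation_sets[frozenset((a, b))] = sepset
        elif in_blanket:
            pdag.undirected_edges.add(frozenset((a, b)))
        # A dependent non-blanket pair stays non-adjacent (blankets bound the
        # neighbour set); no separating set is recorded for it.
    return pdag


def orient_v_structures(skeleton: PDAG) -> PDAG:
    """Orient unshielded triples a-c-b as a->c<-b when c is outside the
    recorded separating set of (a, b).  Conflicting demands on one edge are
    resolved by leaving it undirected (least commitment)."""
    pdag = skeleton.copy()
    demands: set[tuple[str, str]] = set()
    for c in pdag.nodes:
        nbrs = sorted(pdag.neighbors(c))
        for a, b in itertools.combinations(nbrs, 2):
            if pdag.adjacent(a, b):
                continue
            sep = pdag.separation_sets.get(frozenset((a, b)))
            if sep is None:
                continue
            if c not in sep:
                demands.add((a, c))
                demands.add((b, c))
    conflicted = {frozenset((u, v)) for u, v in demands if (v, u) in demands}
    for u, v in sorted(demands):
        if frozenset((u, v)) in conflicted:
            log.warning("conflicting v-structure orientations for edge %s-%s; left undirected", u, v)
            continue
        if frozenset((u, v)) in pdag.undirected_edges:
            pdag.orient(u, v)
    return pdag


def propagate_orientations(pdag: PDAG) -> PDAG:
    """Apply the Meek orientation-propagation rules to a fixpoint.

    R1: a->c, c-b, a and b non-adjacent          => c->b
    R2: a->c->b, a-b                             => a->b
    R3: a-b, a-c->b, a-d->b, c and d non-adjacent => a->b
    (The fourth classical rule is only reachable with orientations from
    background knowledge; starting from v-structures, R1-R3 are complete.)
    Never creates a directed cycle or a new v-structure.
    """
    out = pdag.copy()

    def would_cycle(u: str, v: str) -> bool:
        g = nx.DiGraph()
        g.add_nodes_from(out.nodes)
        g.add_edges_from(out.directed_arcs | {(u, v)})
        return not nx.is_directed_acyclic_graph(g)

    changed = True
    while changed:
        changed = False
        for edge in sorted(out.undirected_edges, key=lambda e: tuple(sorted(e))):
            for u, v in itertools.permutations(sorted(edge)):
                fire = False
                # R1
                for a in out.nodes:
                    if (a, u) in out.directed_arcs and not out.adjacent(a, v) and a != v:
                        fire = True
                        break
                # R2
                if not fire:
                    for c in out.nodes:
                        if (u, c) in out.directed_arcs and (c, v) in out.directed_arcs:
                            fire = True
                            break
                # R3
                if not fire:
                    mids = [
                        c
                        for c in out.nodes
                        if frozenset((u, c)) in out.undirected_edges
                        and (c, v) in out.directed_arcs
                    ]
                    for c, d in itertools.combinations(sorted(mids), 2):
                        if not out.adjacent(c, d):
                            fire = True
                            break
                if fire:
                    if would_cycle(u, v):
                        raise ValueError(
                            f"inconsistent PDAG: orienting {u}->{v} would create a directed cycle"
                        )
                    out.orient(u, v)
                    changed = True
                    break
            if changed:
                break
    return out


def learn_structure(
    data,
    algorithm: str = "gs",
    alpha: float = 0.01,
    symmetry_rule: str = "AND",
) -> PDAG:
    """Full constraint-based pipeline: blankets -> symmetry correction ->
    skeleton -> v-structures -> Meek propagation.  Deterministic given data."""
    tester = _as_tester(data, alpha)
    if isinstance(data, ExpressionMatrix) and data.n < 10 * data.p:
        log.warning("sample size n=%d is small for p=%d variables", data.n, data.p)
    blankets = learn_blankets(tester, algorithm=algorithm, alpha=alpha)
    blankets = symmetry_correct(blankets, rule=symmetry_rule)
    skeleton = blankets_to_skeleton(tester, blankets, alpha=alpha)
    oriented = orient_v_structures(skeleton)
    return propagate_orientations(oriented)
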