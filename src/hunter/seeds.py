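"""Module-seed construction around each vertex.

A module seed MS(v) is the dense, co-expressed "heart" of a candidate
module built around vertex v: the neighbourhood N(v) is first cleaned of
incoherently expressed members using the Bad Module Seed Index (BMSI),
then the surviving components are reduced to a maximal q-connected
subset MQC(v). q-connectivity treats edge weights as interaction
probabilities: a vertex set S is q-connected when, for every bipartition
(U, S-U), the probability that at least one crossing interaction truly
exists, 1 - prod(1 - w(e)), is at least q. The decision reduces to a
global minimum cut with capacities -log(1 - w(e)) compared against
-log(1 - q).

With an unweighted (all weights 1) network every connected set is
q-connected and MQC is the whole cleaned component -- a documented
degenerate behaviour, not an error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import FrozenSet, List, Optional, Sequence, Set, Tuple

import networkx as nx

from hunter.graph_io import ExpressionMatrix, ValidationError, WeightedNetwork

#: Capacity used for a certain edge (w = 1): about -log of the smallest
#: positive normal double, so any cut containing one passes any q < 1.
CERTAIN_EDGE_CAPACITY = 745.0

#: Slack for the min-cut vs -log(1-q) comparison; "at least q" boundaries
#: must not flip on rounding of the log transform.
_CUT_TOLERANCE = 1e-9

#: Default error probability 0.05, i.e. q = 0.95.
DEFAULT_Q = 0.95


@dataclass(frozen=True)
class ModuleSeed:
    """Seed vertex v together with members MQC(v) | {v}; empty if no core.

    A non-empty seed has at least 3 members (|MQC| > 1 plus v itself)
    and induces a connected subgraph of the target PPI.
    """

    vertex: str
    members: FrozenSet[str] = frozenset()

    def __bool__(self) -> bool:
        return bool(self.members)

    def __len__(self) -> int:
        return len(self.members)


def bmsi(
    S: Set[str], u: str, expr: Optional[ExpressionMatrix], t: float
) -> int:
    """Bad Module Seed Index: count of u's weak expression links within S.

    Edges are taken in the gene-expression complete graph restricted to
    S: BMSI(S, u) counts members w of S \\ {u} with both u and w
    profiled and pearson(u, w) <= t. Pairs with an unprofiled member
    contribute 0 (only profiled-profiled pairs can be "bad").
    """
    if u not in S:
        raise ValidationError(f"vertex {u!r} not in the set")
    if expr is None or u not in expr:
        return 0
    return sum(
        1 for w in S if w != u and w in expr and expr.correlation(u, w) <= t
    )


def clean_neighborhood(
    v: str,
    net: WeightedNetwork,
    expr: Optional[ExpressionMatrix],
    t: float,
) -> List[Set[str]]:
    """Target-neighbour collection TN(v): cleaned components of N(v).

    For each connected component NCC of the subgraph induced on N(v),
    the vertex with the maximum BMSI(NCC, u) is removed (recomputing
    BMSI after every removal; ties broken by lexicographic vertex id)
    until every remaining BMSI is 0. TN(v) is the collection of
    connected components of the survivors N'(v), recomputed on the
    induced subgraph. Without expression data no removal occurs.
    """
    if v not in net:
        raise ValidationError(f"vertex {v!r} not in the network")
    neighbours = net.neighbors(v)
    if not neighbours:
        return []
    induced = net.graph.subgraph(neighbours)
    survivors: Set[str] = set()
    for comp in nx.connected_components(induced):
        ncc = set(comp)
        if expr is not None and len(expr) > 0:
            while len(ncc) > 0:
                scores = {u: bmsi(ncc, u, expr, t) for u in ncc}
                worst = min(scores, key=lambda u: (-scores[u], u))
                if scores[worst] == 0:
                    break
                ncc.remove(worst)
        survivors |= ncc
    cleaned = net.graph.subgraph(survivors)
    return [set(c) for c in nx.connected_components(cleaned)]


def _cut_capacity_graph(net: WeightedNetwork, S: Set[str]) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(S)
    for a, b, w in net.subgraph(S).edges():
        if w >= 1.0:
            cap = CERTAIN_EDGE_CAPACITY
        else:
            cap = -math.log1p(-w)
        G.add_edge(a, b, weight=cap)
    return G


def is_q_connected(
    S: Set[str], net: WeightedNetwork, q: float = DEFAULT_Q
) -> bool:
    """Decide whether S is q-connected under the probabilistic edge model.

    TRUE iff for every bipartition (U, S-U) the probability that at
    least one crossing edge exists is >= q. Decided by a Stoer-Wagner
    global minimum cut on -log(1 - w) capacities. A singleton is
    q-connected by convention; a disconnected S is not (some bipartition
    has crossing probability 0).
    """
    if not 0.0 < q < 1.0:
        raise ValidationError(f"q must be in (0, 1), got {q}")
    S = set(S)
    if not S <= set(net.vertices):
        raise ValidationError("S contains vertices absent from the network")
    if len(S) <= 1:
        return True
    G = _cut_capacity_graph(net, S)
    if not nx.is_connected(G):
        return False
    cut_value, _ = nx.stoer_wagner(G)
    return cut_value >= -math.log1p(-q) - _CUT_TOLERANCE


def maximal_q_connected(
    component: Set[str], net: WeightedNetwork, q: float = DEFAULT_Q
) -> Set[str]:
    """Largest q-connected subset of a connected component.

    If the component is q-connected it is returned unchanged; otherwise
    it is split at its global minimum cut and both sides are searched
    recursively, keeping the maximum-cardinality result (ties toward
    the lexicographically smallest member set). Singletons are
    discarded: the empty set is returned when no q-connected subset of
    size >= 2 exists.
    """
    component = set(component)
    if len(component) < 2:
        return set()
    G = _cut_capacity_graph(net, component)
    if not nx.is_connected(G):
        # defensive: recurse on pieces rather than fail the precondition
        parts = [set(c) for c in nx.connected_components(G)]
        candidates = [maximal_q_connected(p, net, q) for p in parts]
        return _largest(candidates)
    cut_value, (side_a, side_b) = nx.stoer_wagner(G)
    if cut_value >= -math.log1p(-q) - _CUT_TOLERANCE:
        return component
    return _largest(
        [
            maximal_q_connected(set(side_a), net, q),
            maximal_q_connected(set(side_b), net, q),
        ]
    )


def _largest(candidates: Sequence[Set[str]]) -> Set[str]:
    non_empty = [c for c in candidates if c]
    if not non_empty:
        return set()
    return min(non_empty, key=lambda c: (-len(c), tuple(sorted(c))))


def module_seed(
    v: str,
    net: WeightedNetwork,
    expr: Optional[ExpressionMatrix] = None,
    t: float = 0.0,
    q: float = DEFAULT_Q,
) -> ModuleSeed:
    """Construct the module seed MS(v) for a vertex.

    Composes neighbourhood cleaning and per-component maximal
    q-connected extraction; MQC(v) is the largest result over all TN(v)
    components (ties toward the lexicographically smallest set). When
    |MQC(v)| > 1 the seed is MQC(v) | {v}; otherwise it is empty.
    """
    tn = clean_neighborhood(v, net, expr, t)
    mqc = _largest([maximal_q_connected(c, net, q) for c in tn])
    if len(mqc) > 1:
        return ModuleSeed(vertex=v, members=frozenset(mqc | {v}))
    return ModuleSeed(vertex=v)
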