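"""Seed growth, weak-community screening, merging — the pipeline tail.

A grown module is a hub-attachment structure: the seed is the densely
connected core and growth attaches peripheral vertices that are closely
related to it. Growth uses a neighbourhood-majority rule — a candidate
u in N(M) joins when 2*|N(u) & M| > |M| — applied in batch: every
qualifying candidate joins simultaneously against the current set, and
the loop repeats until a fixpoint. Grown modules are kept only when
they are weak communities in Radicchi's sense (total internal degree
exceeds total external degree on the unweighted topology). Overlapping
modules U_i, U_j are merged while 2*|U_i & U_j| > min(|U_i|, |U_j|).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

from hunter.graph_io import ExpressionMatrix, ValidationError, WeightedNetwork
from hunter.seeds import DEFAULT_Q, ModuleSeed, module_seed
from hunter.thresholds import filter_network, select_threshold

logger = logging.getLogger(__name__)

#: Modules smaller than this are dropped from the final clustering
#: (matches the size > 2 reporting convention for complex predictions).
DEFAULT_MIN_SIZE = 3


@dataclass(frozen=True)
class GrownModule:
    """A seed after growth: members always contain the seed's members."""

    members: FrozenSet[str]
    seed: ModuleSeed

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class Clustering:
    """Ordered collection of final modules; overlap between modules allowed.

    Modules are sorted by decreasing size then lexicographically, with
    no duplicates and no pair satisfying the merge criterion. The
    provenance log records which grown modules were merged, and
    ``seeds`` maps each final module index to the seed vertices that
    contributed to it.
    """

    modules: List[Set[str]] = field(default_factory=list)
    seed_vertices: List[List[str]] = field(default_factory=list)
    merge_log: List[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.modules)

    def seed_of(self, index: int) -> str:
        if index < len(self.seed_vertices) and self.seed_vertices[index]:
            return ",".join(self.seed_vertices[index])
        return "-"


@dataclass
class PipelineReport:
    """Per-stage counts and resolved parameters of one pipeline run."""

    threshold: Optional[float] = None
    q: float = DEFAULT_Q
    n_vertices: int = 0
    n_edges_input: int = 0
    n_edges_filtered: int = 0
    n_seeds: int = 0
    n_unique_seeds: int = 0
    n_grown: int = 0
    n_weak: int = 0
    n_final: int = 0


def grow(seed: ModuleSeed, net: WeightedNetwork) -> Optional[GrownModule]:
    """Grow a seed by the batch neighbourhood-majority join rule.

    Iterates: collect ALL u in N(current set) with
    2*|N(u) & current| > |current|, add them simultaneously, repeat
    until no additions. The criterion is evaluated against the set as
    it stood at the start of the iteration, so two candidates can join
    together even when joining one first would raise the bar for the
    other. Returns None for an empty seed.
    """
    if not seed:
        return None
    current: Set[str] = set(seed.members)
    while True:
        frontier = set()
        for u in current:
            frontier |= net.neighbors(u)
        frontier -= current
        joined = {
            u for u in frontier if 2 * len(net.neighbors(u) & current) > len(current)
        }
        if not joined:
            break
        current |= joined
    return GrownModule(members=frozenset(current), seed=seed)


def is_weak_community(
    module: Set[str], net: WeightedNetwork, weighted: bool = False
) -> bool:
    """Radicchi weak-community test.

    TRUE iff the total internal degree (each within-module edge counted
    twice) exceeds the total external degree (edges leaving the
    module), on the unweighted topology by default; ``weighted=True``
    sums confidence scores instead of edge counts. A module equal to
    the whole vertex set has no external edges and is weak by
    convention (logged).
    """
    module = set(module)
    if not module:
        raise ValidationError("empty module has no community structure")
    vertices = set(net.vertices)
    if not module <= vertices:
        raise ValidationError("module contains vertices absent from the network")
    if module == vertices:
        logger.warning("module equals the whole vertex set; weak by convention")
        return True
    k_in = 0.0
    k_out = 0.0
    for u in module:
        for w in net.neighbors(u):
            contrib = net.weight(u, w) if weighted else 1
            if w in module:
                k_in += contrib  # each internal edge counted once per endpoint
            else:
                k_out += contrib
    return k_in > k_out


def _mergeable(a: Set[str], b: Set[str]) -> bool:
    return 2 * len(a & b) > min(len(a), len(b))


def merge_modules(grown: Sequence[GrownModule]) -> Clustering:
    """Merge overlapping grown modules to a fixpoint.

    Identical member sets are collapsed first (their seed provenance is
    pooled). Then, repeatedly, the mergeable pair with the largest
    overlap ratio |U_i & U_j| / min(|U_i|, |U_j|) is replaced by its
    union (ties toward the lexicographically smallest pair of module
    indices in the current ordering) until no pair satisfies
    2*|U_i & U_j| > min(|U_i|, |U_j|). Final modules are ordered by
    decreasing size, then lexicographically.
    """
    pools: Dict[FrozenSet[str], List[str]] = {}
    for g in grown:
        pools.setdefault(frozenset(g.members), []).append(g.seed.vertex)
    sets: List[Set[str]] = [set(m) for m in pools]
    seeds: List[List[str]] = [sorted(v) for v in pools.values()]
    log: List[str] = []
    while True:
        best: Optional[Tuple[float, int, int]] = None
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                inter = len(sets[i] & sets[j])
                if 2 * inter > min(len(sets[i]), len(sets[j])):
                    ratio = inter / min(len(sets[i]), len(sets[j]))
                    cand = (-ratio, i, j)
                    if best is None or cand < best:
                        best = cand
        if best is None:
            break
        _, i, j = best
        log.append(
            f"merged modules of sizes {len(sets[i])} and {len(sets[j])} "
            f"(overlap {len(sets[i] & sets[j])})"
        )
        union = sets[i] | sets[j]
        pooled = sorted(set(seeds[i]) | set(seeds[j]))
        keep = [k for k in range(len(sets)) if k not in (i, j)]
        sets = [sets[k] for k in keep] + [union]
        seeds = [seeds[k] for k in keep] + [pooled]
        # the union may now duplicate an existing set
        merged: Dict[FrozenSet[str], List[str]] = {}
        for s, sv in zip(sets, seeds):
            key = frozenset(s)
            if key in merged:
                merged[key] = sorted(set(merged[key]) | set(sv))
            else:
                merged[key] = sv
        sets = [set(k) for k in merged]
        seeds = list(merged.values())
    order = sorted(
        range(len(sets)), key=lambda k: (-len(sets[k]), tuple(sorted(sets[k])))
    )
    return Clustering(
        modules=[sets[k] for k in order],
        seed_vertices=[seeds[k] for k in order],
        merge_log=log,
    )


def run_pipeline(
    net: WeightedNetwork,
    expr: Optional[ExpressionMatrix] = None,
    q: float = DEFAULT_Q,
    t: Optional[float] = None,
    seed: int = 0,
    min_size: int = DEFAULT_MIN_SIZE,
    n_null: int = 5,
) -> Tuple[Clustering, PipelineReport]:
    """Full module detection: filter, seed, grow, screen, merge.

    If expression data are supplied and ``t`` is None, the correlation
    threshold is selected automatically (``seed`` drives the null
    randomizations); the network is then edge-filtered at t. A module
    seed is built for every vertex, non-empty seeds are grown, grown
    modules failing the weak-community test are dropped (not reverted),
    identical grown modules are collapsed, overlapping ones merged, and
    modules smaller than ``min_size`` removed. Returns the clustering
    together with a per-stage report. Deterministic given inputs and
    ``seed``.
    """
    report = PipelineReport(q=q)
    report.n_vertices = net.number_of_vertices()
    report.n_edges_input = net.number_of_edges()
    have_expr = expr is not None and len(expr) > 0
    if have_expr:
        if t is None:
            t = select_threshold(expr, n_null=n_null, seed=seed).threshold
        report.threshold = t
        target = filter_network(net, expr, t)
    else:
        t = 0.0
        target = net
    report.n_edges_filtered = target.number_of_edges()

    seeds = []
    for v in sorted(target.vertices):
        ms = module_seed(v, target, expr if have_expr else None, t, q)
        if ms:
            seeds.append(ms)
    report.n_seeds = len(seeds)
    report.n_unique_seeds = len({s.members for s in seeds})

    grown: List[GrownModule] = []
    for ms in seeds:
        g = grow(ms, target)
        if g is not None:
            grown.append(g)
    report.n_grown = len({g.members for g in grown})

    weak = [g for g in grown if is_weak_community(set(g.members), target)]
    report.n_weak = len({g.members for g in weak})

    clustering = merge_modules(weak)
    kept = [
        (m, sv)
        for m, sv in zip(clustering.modules, clustering.seed_vertices)
        if len(m) >= min_size
    ]
    clustering.modules = [m for m, _ in kept]
    clustering.seed_vertices = [sv for _, sv in kept]
    report.n_final = len(clustering.modules)
    logger.info(
        "pipeline: %d vertices, %d->%d edges, %d seeds (%d unique), "
        "%d grown, %d weak, %d final",
        report.n_vertices,
        report.n_edges_input,
        report.n_edges_filtered,
        report.n_seeds,
        report.n_unique_seeds,
        report.n_grown,
        report.n_weak,
        report.n_final,
    )
    return clustering, report
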