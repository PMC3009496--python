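"""Correlation-threshold selection and expression-based edge filtering.

When expression data accompany the PPI network, edges whose endpoints
are expressed inconsistently are removed before module detection. The
Pearson cutoff t is chosen systematically rather than by hand: for each
candidate cutoff d on the grid d_j = 0.6 + 0.01*j (j = 0..39), build the
correlation graph H (gene pairs with correlation > d) and compare its
clustering coefficient C(H) with the mean clustering coefficient
C_0(H) of degree-preserving randomizations of H. The chosen t is the
grid point maximizing the gap C - C_0 (smallest d on ties): the cutoff
at which the correlation graph is most non-randomly clustered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import networkx as nx
import numpy as np

from hunter.graph_io import ExpressionMatrix, ValidationError, WeightedNetwork

logger = logging.getLogger(__name__)

#: Candidate-cutoff grid d_j = 0.6 + 0.01 * j for j in [0, 39].
DEFAULT_GRID: List[float] = [round(0.6 + 0.01 * j, 2) for j in range(40)]


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation of two equal-length profiles.

    A zero-variance profile makes the correlation undefined; it is
    treated as 0 (such a gene never passes any cutoff >= 0.6) with a
    warning, rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"profile lengths differ: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValidationError("profiles must have length >= 3")
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt((xd * xd).sum() * (yd * yd).sum())
    if denom == 0.0:
        logger.warning("zero-variance profile; correlation defined as 0")
        return 0.0
    r = float((xd * yd).sum() / denom)
    return max(-1.0, min(1.0, r))


def clustering_coefficient(H: nx.Graph, include_low_degree: bool = True) -> float:
    """Mean local clustering coefficient of a simple undirected graph.

    Per-vertex coefficient is 2*E_v / (deg(v)*(deg(v)-1)) where E_v is
    the number of edges among v's neighbours; vertices with deg < 2
    contribute 0 and are included in the mean (Watts-Strogatz
    convention). ``include_low_degree=False`` drops them from the mean
    instead.
    """
    if H.number_of_nodes() == 0:
        raise ValidationError("clustering coefficient of an empty graph is undefined")
    if not include_low_degree:
        kept = [v for v, d in H.degree if d >= 2]
        if not kept:
            return 0.0
        return float(nx.average_clustering(H, nodes=kept, count_zeros=True))
    return float(nx.average_clustering(H, count_zeros=True))


def degree_preserving_null(
    H: nx.Graph, n_swaps: Optional[int] = None, seed: int = 0
) -> nx.Graph:
    """Random graph with the identical degree sequence as H.

    Produced by repeated double-edge swaps that reject self-loops and
    multi-edges; deterministic given ``seed``. Default swap count is
    10*|E|. Graphs with fewer than 2 edges are returned unchanged with
    a warning (no swap is possible).
    """
    H0 = H.copy()
    m = H0.number_of_edges()
    if m < 2:
        logger.warning("graph has %d edge(s); degree-preserving swap is a no-op", m)
        return H0
    if n_swaps is None:
        n_swaps = 10 * m
    try:
        nx.double_edge_swap(H0, nswap=n_swaps, max_tries=100 * n_swaps, seed=seed)
    except nx.NetworkXAlgorithmError:
        # rigid graphs (e.g. a single triangle) can exhaust swap attempts
        logger.warning("degree-preserving swap exhausted its attempts; partial shuffle")
    return H0


@dataclass
class ThresholdScan:
    """Record of the cutoff scan: observed and null clustering curves."""

    grid: List[float]
    observed: List[float] = field(default_factory=list)  # C(K_r, d_j)
    null: List[float] = field(default_factory=list)  # C_0(K_r, d_j)
    edge_counts: List[int] = field(default_factory=list)
    threshold: float = float("nan")  # chosen t, a member of the grid

    @property
    def gap(self) -> List[float]:
        return [c - c0 for c, c0 in zip(self.observed, self.null)]

    def to_rows(self) -> List[tuple]:
        return [
            (d, c, c0, c - c0, m)
            for d, c, c0, m in zip(self.grid, self.observed, self.null, self.edge_counts)
        ]


def correlation_graph(expr: ExpressionMatrix, cutoff: float) -> nx.Graph:
    """Sub-graph H of the complete correlation graph K_r at a cutoff.

    All r genes are kept as nodes; an edge joins two genes whose Pearson
    correlation is strictly greater than ``cutoff``. Edge sets are
    monotone: H at a higher cutoff is a subgraph of H at a lower one.
    """
    genes = expr.genes
    H = nx.Graph()
    H.add_nodes_from(genes)
    corr = _correlation_matrix(expr)
    r = len(genes)
    idx = np.triu_indices(r, k=1)
    mask = corr[idx] > cutoff
    for i, j in zip(idx[0][mask], idx[1][mask]):
        H.add_edge(genes[i], genes[j])
    return H


def _correlation_matrix(expr: ExpressionMatrix) -> np.ndarray:
    cached = getattr(expr, "_corr_matrix", None)
    if cached is not None:
        return cached
    data = np.vstack([expr.profile(g) for g in expr.genes])
    sd = data.std(axis=1)
    safe = np.where(sd == 0, 1.0, sd)
    z = (data - data.mean(axis=1, keepdims=True)) / safe[:, None]
    corr = z @ z.T / data.shape[1]
    corr[sd == 0, :] = 0.0
    corr[:, sd == 0] = 0.0
    np.clip(corr, -1.0, 1.0, out=corr)
    expr._corr_matrix = corr
    return corr


def select_threshold(
    expr: ExpressionMatrix,
    n_null: int = 5,
    seed: int = 0,
    grid: Optional[Sequence[float]] = None,
    include_low_degree: bool = True,
) -> ThresholdScan:
    """Choose the Pearson cutoff t by the clustering-coefficient criterion.

    For each grid point d_j, computes C(K_r, d_j) on the correlation
    graph and C_0(K_r, d_j) as the mean clustering coefficient over
    ``n_null`` degree-preserving randomizations; t is the grid point
    maximizing C - C_0, ties broken toward the smaller d_j.

    Raises if fewer than 3 genes are available or no gene pair exceeds
    the bottom of the grid (no correlated pairs above 0.6).
    """
    if len(expr) < 3:
        raise ValidationError("threshold selection needs >= 3 genes with profiles")
    grid = list(grid) if grid is not None else list(DEFAULT_GRID)
    scan = ThresholdScan(grid=grid)
    rng = np.random.default_rng(seed)
    any_edges = False
    for d in grid:
        H = correlation_graph(expr, d)
        m = H.number_of_edges()
        scan.edge_counts.append(m)
        if m == 0:
            scan.observed.append(0.0)
            scan.null.append(0.0)
            continue
        any_edges = True
        c_obs = clustering_coefficient(H, include_low_degree)
        nulls = []
        for _ in range(n_null):
            rep_seed = int(rng.integers(0, 2**31 - 1))
            nulls.append(
                clustering_coefficient(
                    degree_preserving_null(H, seed=rep_seed), include_low_degree
                )
            )
        scan.observed.append(c_obs)
        scan.null.append(float(np.mean(nulls)))
    if not any_edges:
        raise ValidationError("no correlated pairs above the grid minimum (0.6)")
    gaps = scan.gap
    best = max(range(len(grid)), key=lambda j: (gaps[j], -grid[j]))
    scan.threshold = grid[best]
    return scan


def filter_network(
    net: WeightedNetwork, expr: Optional[ExpressionMatrix], t: float
) -> WeightedNetwork:
    """Drop PPI edges whose endpoints are expressed inconsistently.

    An edge (a, b) is removed iff both endpoints have expression
    profiles and pearson(a, b) <= t (the "at or below threshold"
    convention used everywhere in the seed stage). Edges with an
    unprofiled endpoint are retained; the vertex set is unchanged, so
    filtering may leave isolated vertices. Without expression data the
    network is returned unchanged.
    """
    if expr is None or len(expr) == 0:
        return net.copy()
    if not (-1.0 <= t <= 1.0):
        raise ValidationError(f"correlation threshold {t} outside [-1, 1]")
    out = net.copy()
    for a, b, _ in net.edges():
        if a in expr and b in expr and expr.correlation(a, b) <= t:
            out.graph.remove_edge(a, b)
    return out
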