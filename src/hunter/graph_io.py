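"""Data containers and tab-delimited readers/writers.

All identifiers are case-sensitive opaque strings (yeast data is already
in systematic ORF names, so no gene-name mapping layer is provided).
Formats are line-oriented and plain-text:

- PPI edge list: ``proteinA<TAB>proteinB[<TAB>score]``, score in (0, 1];
  a missing score means an unweighted network and defaults to 1.0.
  A SIF dialect ``a<TAB>pp<TAB>b[<TAB>score]`` is accepted for convenience.
- Expression matrix: ``gene<TAB>x1<TAB>x2...`` with a shared condition axis.
- Localization / complex catalogues: ``key<TAB>protein`` per line.
- Clustering: ``module_id<TAB>seed_vertex<TAB>p1,p2,...`` per module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """A malformed record in an input file; the message names the line."""


class ValidationError(ValueError):
    """An input value violating a container invariant."""


class WeightedNetwork:
    """Undirected simple graph whose edges carry a confidence score in (0, 1].

    The score is interpreted as the probability that the interaction is
    real. Self-loops are rejected; a duplicate edge keeps the maximum
    score (scores are probabilities, so the maximum is the conservative
    choice for downstream connectivity probabilities) and logs a warning.
    Insertion order of vertices is preserved for deterministic iteration.
    """

    def __init__(self) -> None:
        self.graph = nx.Graph()

    @classmethod
    def from_edges(
        cls, edges: Iterable[Tuple[str, str, float]], vertices: Iterable[str] = ()
    ) -> "WeightedNetwork":
        net = cls()
        for v in vertices:
            net.add_vertex(v)
        for a, b, w in edges:
            net.add_edge(a, b, w)
        return net

    def add_vertex(self, v: str) -> None:
        self.graph.add_node(v)

    def add_edge(self, a: str, b: str, weight: float = 1.0) -> None:
        if a == b:
            raise ValidationError(f"self-loop on vertex {a!r} is not allowed")
        if not (0.0 < weight <= 1.0):
            raise ValidationError(
                f"edge ({a!r}, {b!r}) has weight {weight}; must be in (0, 1]"
            )
        if self.graph.has_edge(a, b):
            old = self.graph.edges[a, b]["weight"]
            if weight != old:
                logger.warning(
                    "duplicate edge (%s, %s): keeping max(%g, %g)", a, b, old, weight
                )
            weight = max(weight, old)
        self.graph.add_edge(a, b, weight=weight)

    @property
    def vertices(self) -> List[str]:
        return list(self.graph.nodes)

    def edges(self) -> Iterator[Tuple[str, str, float]]:
        for a, b, data in self.graph.edges(data=True):
            yield a, b, data["weight"]

    def weight(self, a: str, b: str) -> float:
        return self.graph.edges[a, b]["weight"]

    def neighbors(self, v: str) -> Set[str]:
        return set(self.graph.neighbors(v))

    def has_vertex(self, v: str) -> bool:
        return self.graph.has_node(v)

    def has_edge(self, a: str, b: str) -> bool:
        return self.graph.has_edge(a, b)

    def number_of_vertices(self) -> int:
        return self.graph.number_of_nodes()

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()

    def subgraph(self, vertices: Iterable[str]) -> "WeightedNetwork":
        sub = WeightedNetwork()
        sub.graph = nx.Graph(self.graph.subgraph(vertices))
        return sub

    def copy(self) -> "WeightedNetwork":
        net = WeightedNetwork()
        net.graph = self.graph.copy()
        return net

    def __contains__(self, v: str) -> bool:
        return self.graph.has_node(v)

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def __repr__(self) -> str:
        return (
            f"WeightedNetwork({self.number_of_vertices()} vertices, "
            f"{self.number_of_edges()} edges)"
        )


class ExpressionMatrix:
    """Per-gene real-valued expression profiles over a shared condition axis.

    A gene appears at most once and all profiles have identical length
    (>= 3 conditions for a meaningful Pearson correlation). Genes absent
    from a network are retained here and ignored downstream.
    """

    def __init__(self, profiles: Dict[str, np.ndarray]) -> None:
        lengths = {len(v) for v in profiles.values()}
        if len(lengths) > 1:
            raise ValidationError(f"profiles have differing lengths: {sorted(lengths)}")
        self._profiles: Dict[str, np.ndarray] = {
            g: np.asarray(v, dtype=float) for g, v in profiles.items()
        }
        self._corr_cache: Dict[frozenset, float] = {}

    @property
    def genes(self) -> List[str]:
        return list(self._profiles)

    @property
    def condition_count(self) -> int:
        if not self._profiles:
            return 0
        return len(next(iter(self._profiles.values())))

    def profile(self, gene: str) -> np.ndarray:
        return self._profiles[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self._profiles

    def __len__(self) -> int:
        return len(self._profiles)

    def correlation(self, a: str, b: str) -> float:
        """Cached pairwise Pearson correlation; zero-variance profiles give 0."""
        from hunter.thresholds import pearson  # local import avoids a cycle

        key = frozenset((a, b))
        if key not in self._corr_cache:
            self._corr_cache[key] = pearson(self._profiles[a], self._profiles[b])
        return self._corr_cache[key]

    def overlap_with(self, net: WeightedNetwork) -> int:
        """Number of network vertices that have an expression profile."""
        return sum(1 for v in net.vertices if v in self._profiles)


@dataclass
class LocalizationData:
    """Map location-name -> set of proteins observed there.

    A protein may occur in multiple locations; every set is non-empty.
    """

    locations: Dict[str, Set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, members in self.locations.items():
            if not members:
                raise ValidationError(f"location {k!r} has an empty protein set")


@dataclass
class ComplexCatalogue:
    """Gold-standard catalogue: map complex-id -> set of member proteins."""

    complexes: Dict[str, Set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, members in self.complexes.items():
            if not members:
                raise ValidationError(f"complex {k!r} has an empty protein set")

    def __len__(self) -> int:
        return len(self.complexes)


def _lines(path) -> Iterator[Tuple[int, List[str]]]:
    with open(path, "rt", encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_ppi(path, dialect: str = "tab-edge-list") -> WeightedNetwork:
    """Read a weighted PPI edge list.

    ``dialect`` is ``"tab-edge-list"`` (``a<TAB>b[<TAB>score]``) or
    ``"sif"`` (``a<TAB>pp<TAB>b[<TAB>score]``). A missing score defaults
    to 1.0, i.e. an unweighted network.
    """
    if dialect not in ("tab-edge-list", "sif"):
        raise ValueError(f"unknown dialect {dialect!r}")
    net = WeightedNetwork()
    for lineno, fields in _lines(path):
        if dialect == "sif":
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: SIF record needs >= 3 fields")
            fields = [fields[0], fields[2]] + fields[3:4]
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise ParseError(f"{path}:{lineno}: expected two identifiers")
        a, b = fields[0], fields[1]
        if len(fields) >= 3 and fields[2] != "":
            try:
                score = float(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad score {fields[2]!r}") from exc
        else:
            score = 1.0
        try:
            net.add_vertex(a)
            net.add_vertex(b)
            net.add_edge(a, b, score)
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return net


def maximal_connected_component(net: WeightedNetwork) -> WeightedNetwork:
    """Induced subgraph on the largest connected component.

    Ties are broken toward the component containing the lexicographically
    smallest vertex. Isolated vertices count as singleton components.
    """
    if net.number_of_vertices() == 0:
        raise ValidationError("cannot take the component of an empty network")
    components = [set(c) for c in nx.connected_components(net.graph)]
    best = min(components, key=lambda c: (-len(c), min(c)))
    return net.subgraph(best)


def read_expression(path) -> ExpressionMatrix:
    """Read a tab-delimited genes x conditions matrix (no header row).

    First column is the gene id; remaining columns are numeric. Ragged
    rows and non-numeric cells raise :class:`ParseError` naming the spot.
    Duplicate gene ids keep the first occurrence with a warning.
    """
    profiles: Dict[str, np.ndarray] = {}
    width: Optional[int] = None
    for lineno, fields in _lines(path):
        gene, values = fields[0], fields[1:]
        if width is None:
            width = len(values)
        elif len(values) != width:
            raise ParseError(
                f"{path}:{lineno}: row has {len(values)} values, expected {width}"
            )
        try:
            vec = np.array([float(x) for x in values], dtype=float)
        except ValueError:
            bad = next(i for i, x in enumerate(values) if not _is_float(x))
            raise ParseError(
                f"{path}:{lineno}: non-numeric value {values[bad]!r} in column {bad + 2}"
            ) from None
        if gene in profiles:
            logger.warning("duplicate gene %s at %s:%d; keeping first", gene, path, lineno)
            continue
        profiles[gene] = vec
    return ExpressionMatrix(profiles)


def _is_float(x: str) -> bool:
    try:
        float(x)
        return True
    except ValueError:
        return False


def _read_keyed_sets(path, what: str) -> Dict[str, Set[str]]:
    sets: Dict[str, Set[str]] = {}
    empty = True
    for lineno, fields in _lines(path):
        empty = False
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected `key<TAB>protein`")
        sets.setdefault(fields[0], set()).add(fields[1])
    if empty:
        raise ParseError(f"{path}: empty {what} file")
    return sets


def read_localization(path) -> LocalizationData:
    """Read ``location<TAB>protein`` records into per-location protein sets."""
    return LocalizationData(_read_keyed_sets(path, "localization"))


def read_complexes(path) -> ComplexCatalogue:
    """Read ``complex_id<TAB>protein`` records; duplicates collapse (sets)."""
    return ComplexCatalogue(_read_keyed_sets(path, "complex catalogue"))


def write_clustering(clustering, path) -> None:
    """Write one module per line: ``module_id<TAB>seed_vertex<TAB>p1,p2,...``.

    Members are sorted for byte-identical output across runs; the seed
    field is ``-`` when provenance is unknown.
    """
    with open(path, "wt", encoding="utf-8") as handle:
        for i, module in enumerate(clustering.modules, start=1):
            seed = clustering.seed_of(i - 1) if hasattr(clustering, "seed_of") else "-"
            members = ",".join(sorted(module))
            handle.write(f"Cluster_{i}\t{seed}\t{members}\n")


def read_clustering(path) -> List[Set[str]]:
    """Read the clustering format back into a list of vertex sets."""
    modules: List[Set[str]] = []
    for lineno, fields in _lines(path):
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected 3 tab-separated fields")
        modules.append(set(fields[2].split(",")))
    if not modules:
        raise ParseError(f"{path}: empty clustering file")
    return modules
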