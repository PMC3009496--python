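"""Clustering evaluation against Gene Ontology, localization and catalogues.

Four statistics summarize how biologically coherent a clustering is:

- **Enrichment F-measure** — hypergeometric term enrichment per cluster;
  sensitivity is the fraction of (informative) terms enriched in at
  least one cluster at p < alpha, specificity the fraction of clusters
  enriched for at least one term, F their harmonic mean.
- **Co-annotation** — Schlicker relevance similarity between GO terms,
  lifted to protein pairs by best-match averaging, averaged within
  clusters, size-weighted across clusters, and combined as the
  geometric mean of the biological-process and molecular-function
  scores.
- **Co-localization** — the fraction of clustered proteins sharing
  their cluster's plurality subcellular location.
- **Average similarity** — the mean pairwise protein relevance
  similarity pooled over the within-set pairs of a collection of
  vertex sets (used to compare seeds, final modules and the network).

Gold-standard matching treats each catalogued complex as a term and
applies the same hypergeometric machinery.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx
import obonet
from scipy.stats import hypergeom

from hunter.graph_io import ComplexCatalogue, LocalizationData, ValidationError

logger = logging.getLogger(__name__)

ASPECTS = ("BP", "MF", "CC")
_NAMESPACE_TO_ASPECT = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
}
_CODE_TO_ASPECT = {"P": "BP", "F": "MF", "C": "CC"}
#: Ontology relations along which annotations propagate upward.
PROPAGATING_RELATIONS = ("is_a", "part_of")

DEFAULT_ALPHA = 1e-4


def parse_obo(path) -> nx.MultiDiGraph:
    """Read an OBO 1.2 ontology into a child-to-parent term multigraph.

    Obsolete terms are skipped; a cyclic is_a structure is rejected.
    Node data carries the term ``namespace`` used to split aspects.
    """
    dag = obonet.read_obo(path)
    is_a_only = nx.DiGraph(
        (u, v) for u, v, k in dag.edges(keys=True) if k == "is_a"
    )
    if not nx.is_directed_acyclic_graph(is_a_only):
        raise ValidationError("cyclic is_a structure in ontology")
    return dag


@dataclass
class _AspectData:
    dag: nx.DiGraph  # child -> parent, propagating relations only
    direct: Dict[str, Set[str]] = field(default_factory=dict)
    annotations: Dict[str, Set[str]] = field(default_factory=dict)  # propagated
    term_proteins: Dict[str, Set[str]] = field(default_factory=dict)

    @property
    def n_annotated(self) -> int:
        return len(self.annotations)

    def p(self, term: str) -> float:
        """Term probability: annotated-protein count / aspect-annotated total."""
        if self.n_annotated == 0:
            return 0.0
        return len(self.term_proteins.get(term, ())) / self.n_annotated


class AnnotationCorpus:
    """GO DAG plus upward-propagated protein annotations per aspect.

    Propagation closure: a protein annotated to a term is annotated to
    every ancestor of that term along is_a/part_of, so term
    probabilities p(a) are monotonically non-decreasing from child to
    parent and p(root) = 1 whenever the root is reachable from every
    annotation.
    """

    def __init__(self, dag: nx.MultiDiGraph) -> None:
        self.ontology = dag
        self.aspects: Dict[str, _AspectData] = {}
        for aspect in ASPECTS:
            terms = [
                n
                for n, data in dag.nodes(data=True)
                if _NAMESPACE_TO_ASPECT.get(data.get("namespace", "")) == aspect
            ]
            sub = nx.DiGraph()
            sub.add_nodes_from(terms)
            term_set = set(terms)
            for u, v, k in dag.edges(keys=True):
                if k in PROPAGATING_RELATIONS and u in term_set and v in term_set:
                    sub.add_edge(u, v)
            self.aspects[aspect] = _AspectData(dag=sub)
        self._ancestor_cache: Dict[Tuple[str, str], FrozenSet[str]] = {}
        self._term_sim_cache: Dict[Tuple[str, FrozenSet[str]], float] = {}
        self._pair_sim_cache: Dict[Tuple[str, str, FrozenSet[str]], float] = {}

    def add_annotation(self, protein: str, term: str, aspect: str) -> None:
        data = self.aspects[aspect]
        if term not in data.dag:
            logger.warning("annotation to unknown/obsolete term %s skipped", term)
            return
        data.direct.setdefault(protein, set()).add(term)
        closure = self.ancestors_or_self(term, aspect)
        data.annotations.setdefault(protein, set()).update(closure)
        for t in closure:
            data.term_proteins.setdefault(t, set()).add(protein)

    def ancestors_or_self(self, term: str, aspect: str) -> FrozenSet[str]:
        key = (aspect, term)
        if key not in self._ancestor_cache:
            dag = self.aspects[aspect].dag
            self._ancestor_cache[key] = frozenset(nx.descendants(dag, term) | {term})
        return self._ancestor_cache[key]

    def p(self, term: str, aspect: str) -> float:
        return self.aspects[aspect].p(term)

    def annotated_proteins(self, aspect: str) -> Set[str]:
        return set(self.aspects[aspect].annotations)


def parse_annotations(path, dag: nx.MultiDiGraph) -> AnnotationCorpus:
    """Build a corpus from a GAF-like association file.

    Accepts the standard tab-delimited GAF column layout (protein id in
    column 2, GO id in column 5, aspect code P/F/C in column 9; NOT
    qualifiers skipped) and, for compactness in fixtures, a minimal
    3-column dialect ``protein<TAB>GO_id<TAB>P|F|C``.
    """
    corpus = AnnotationCorpus(dag)
    with open(path, "rt", encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("!") or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) >= 9:
                protein, qualifier, term, code = (
                    fields[1],
                    fields[3],
                    fields[4],
                    fields[8],
                )
                if "NOT" in qualifier:
                    continue
            elif len(fields) == 3:
                protein, term, code = fields
            else:
                raise ValidationError(
                    f"{path}:{lineno}: expected GAF (>=9 cols) or 3-col record"
                )
            aspect = _CODE_TO_ASPECT.get(code)
            if aspect is None:
                raise ValidationError(f"{path}:{lineno}: bad aspect code {code!r}")
            corpus.add_annotation(protein, term, aspect)
    return corpus


def enrichment_pvalue(N: int, M: int, n: int, x: int) -> float:
    """Hypergeometric upper tail: P(X >= x) drawing n from N with M marked.

    The probability of observing x or more annotated proteins in a
    cluster of n, when M of the N background proteins carry the term.
    Computed by scipy's survival function (log-space internally).
    """
    if not (0 <= M <= N and 0 <= n <= N and 0 <= x <= min(n, M)):
        raise ValidationError(
            f"inconsistent counts N={N}, M={M}, n={n}, x={x}"
        )
    return float(hypergeom.sf(x - 1, N, M, n))


def f_measure(
    clustering: Sequence[Set[str]],
    corpus: AnnotationCorpus,
    aspect: str,
    alpha: float = DEFAULT_ALPHA,
    background: Optional[Set[str]] = None,
    bonferroni: bool = False,
) -> Tuple[float, float, float]:
    """GO-term retrieval scores: (sensitivity, specificity, F).

    Sensitivity is the fraction of terms enriched in at least one
    cluster at p < alpha; specificity the fraction of clusters enriched
    with at least one term; F their harmonic mean (0 when both are 0).
    The background defaults to every annotated protein in the aspect;
    pass the network's vertex set to use a network background. Terms
    annotating the entire background are uninformative (their p-value
    is identically 1) and are excluded from the term universe. The raw
    p < alpha cutoff is the default protocol; ``bonferroni=True``
    divides alpha by the number of informative terms.
    """
    if not clustering:
        raise ValidationError("empty clustering cannot be scored")
    if not (0.0 < alpha < 1.0):
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    data = corpus.aspects[aspect]
    annotated = set(data.annotations)
    if background is not None:
        annotated &= set(background)
    N = len(annotated)
    if N == 0:
        raise ValidationError(f"no annotated proteins in aspect {aspect}")
    term_counts = {
        t: len(members & annotated)
        for t, members in data.term_proteins.items()
        if members & annotated
    }
    terms = [t for t, M in term_counts.items() if M < N]
    if bonferroni and terms:
        alpha = alpha / len(terms)
    enriched_terms: Set[str] = set()
    enriched_clusters = 0
    for cluster in clustering:
        members = set(cluster) & annotated
        n = len(members)
        hit = False
        if n:
            cluster_terms: Dict[str, int] = {}
            for prot in members:
                for t in data.annotations[prot]:
                    cluster_terms[t] = cluster_terms.get(t, 0) + 1
            for t, x in cluster_terms.items():
                M = term_counts[t]
                if M >= N:
                    continue
                if enrichment_pvalue(N, M, n, x) < alpha:
                    enriched_terms.add(t)
                    hit = True
        if hit:
            enriched_clusters += 1
    sensitivity = len(enriched_terms) / len(terms) if terms else 0.0
    specificity = enriched_clusters / len(clustering)
    if sensitivity + specificity == 0:
        return 0.0, 0.0, 0.0
    f = 2 * sensitivity * specificity / (sensitivity + specificity)
    return sensitivity, specificity, f


def term_similarity(a1: str, a2: str, corpus: AnnotationCorpus, aspect: str) -> float:
    """Schlicker relevance similarity of two GO terms.

    max over common ancestors c (including the terms themselves) of
    ``(2 ln p(c) / (ln p(a1) + ln p(a2))) * (1 - p(c))``: the
    information-content ratio of the best common ancestor, damped by
    (1 - p(c)) so that shallow, uninformative ancestors (p near 1)
    contribute little and the root contributes 0.
    """
    data = corpus.aspects[aspect]
    for a in (a1, a2):
        if a not in data.dag:
            raise ValidationError(f"term {a!r} not in aspect {aspect}")
    key = (aspect, frozenset((a1, a2)))
    cached = corpus._term_sim_cache.get(key)
    if cached is not None:
        return cached
    p1, p2 = data.p(a1), data.p(a2)
    if p1 <= 0.0 or p2 <= 0.0:
        corpus._term_sim_cache[key] = 0.0
        return 0.0
    denom = math.log(p1) + math.log(p2)
    common = corpus.ancestors_or_self(a1, aspect) & corpus.ancestors_or_self(a2, aspect)
    best = 0.0
    for c in common:
        pc = data.p(c)
        if pc <= 0.0 or pc >= 1.0:
            continue  # unannotated ancestors carry no information; root gives 0
        if denom == 0.0:
            continue  # both terms annotate everything; no information either
        score = (2.0 * math.log(pc) / denom) * (1.0 - pc)
        best = max(best, score)
    corpus._term_sim_cache[key] = best
    return best


def protein_pair_similarity(
    p1: str,
    p2: str,
    corpus: AnnotationCorpus,
    aspect: str,
    mode: str = "bma",
) -> Optional[float]:
    """Relevance similarity of two proteins from their direct term sets.

    ``mode="bma"`` (default) is the best-match average: the mean of the
    per-term best matches in both directions. ``mode="max"`` takes the
    maximum over all term pairs. Returns None when either protein has
    no direct annotation in the aspect.
    """
    data = corpus.aspects[aspect]
    terms1 = data.direct.get(p1)
    terms2 = data.direct.get(p2)
    if not terms1 or not terms2:
        return None
    key = (aspect, mode, frozenset((p1, p2)))
    cached = corpus._pair_sim_cache.get(key)
    if cached is not None:
        return cached
    sims = {
        (a, b): term_similarity(a, b, corpus, aspect) for a in terms1 for b in terms2
    }
    if mode == "max":
        value = max(sims.values())
    elif mode == "bma":
        row = sum(max(sims[(a, b)] for b in terms2) for a in terms1) / len(terms1)
        col = sum(max(sims[(a, b)] for a in terms1) for b in terms2) / len(terms2)
        value = 0.5 * (row + col)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    corpus._pair_sim_cache[key] = value
    return value


def _cluster_annotation_score(
    cluster: Set[str], corpus: AnnotationCorpus, aspect: str, mode: str
) -> Optional[float]:
    members = sorted(cluster)
    sims = []
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            s = protein_pair_similarity(members[i], members[j], corpus, aspect, mode)
            if s is not None:
                sims.append(s)
    if not sims:
        return None
    return sum(sims) / len(sims)


def coannotation_score(
    clustering: Sequence[Set[str]],
    corpus: AnnotationCorpus,
    mode: str = "bma",
    weighted: bool = True,
) -> float:
    """Geometric mean of the BP and MF clustering annotation scores.

    A cluster's annotation score is the mean relevance similarity over
    its annotated protein pairs; the clustering score is the
    size-weighted mean over scoreable clusters (``weighted=False`` for
    a plain mean). Raises when no cluster has an annotated pair in
    either aspect.
    """
    per_aspect: Dict[str, float] = {}
    for aspect in ("BP", "MF"):
        scores = []
        weights = []
        for cluster in clustering:
            s = _cluster_annotation_score(set(cluster), corpus, aspect, mode)
            if s is None:
                continue
            scores.append(s)
            weights.append(len(cluster) if weighted else 1.0)
        if not scores:
            raise ValidationError(f"no annotated protein pair in aspect {aspect}")
        per_aspect[aspect] = sum(s * w for s, w in zip(scores, weights)) / sum(weights)
    return math.sqrt(per_aspect["BP"] * per_aspect["MF"])


def colocalization_score(
    clustering: Sequence[Set[str]], loc: LocalizationData
) -> float:
    """Fraction of clustered proteins in their cluster's plurality location.

    sum over clusters of max_k |C_j & O_k|, normalized by sum |C_j|;
    proteins absent from every location stay in the denominator.
    """
    if not loc.locations:
        raise ValidationError("empty localization data")
    num = 0
    den = 0
    any_present = False
    for cluster in clustering:
        cluster = set(cluster)
        den += len(cluster)
        best = max((len(cluster & O) for O in loc.locations.values()), default=0)
        if best:
            any_present = True
        num += best
    if den == 0:
        raise ValidationError("empty clustering cannot be scored")
    if not any_present:
        raise ValidationError("no cluster protein appears in the localization data")
    return num / den


def average_similarity(
    sets: Sequence[Set[str]],
    corpus: AnnotationCorpus,
    aspect: str,
    mode: str = "bma",
) -> float:
    """Mean pairwise protein relevance similarity pooled over within-set pairs.

    Every unordered annotated pair inside each member set contributes
    one observation (pair-count weighting across sets). Raises when no
    set contains an annotated pair.
    """
    sims: List[float] = []
    for s in sets:
        members = sorted(s)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                v = protein_pair_similarity(members[i], members[j], corpus, aspect, mode)
                if v is not None:
                    sims.append(v)
    if not sims:
        raise ValidationError("no scoreable protein pair in any set")
    return sum(sims) / len(sims)


def match_gold_standard(
    clustering: Sequence[Set[str]],
    catalogue: ComplexCatalogue,
    alpha: float = DEFAULT_ALPHA,
    universe: Optional[Set[str]] = None,
) -> Tuple[int, float, float, float]:
    """Match clusters to catalogued complexes by hypergeometric overlap.

    Each complex is treated as a term over the protein universe
    (default: the union of clustered and catalogued proteins); a
    cluster matches a complex when the overlap p-value is < alpha.
    Returns (matched-cluster count, precision, recall, F) where
    precision is the fraction of clusters matching >= 1 complex and
    recall the fraction of complexes matched by >= 1 cluster.
    """
    if not catalogue.complexes:
        raise ValidationError("empty complex catalogue")
    if universe is None:
        universe = set()
        for c in clustering:
            universe |= set(c)
        for members in catalogue.complexes.values():
            universe |= members
    N = len(universe)
    matched_clusters = 0
    matched_complexes: Set[str] = set()
    for cluster in clustering:
        members = set(cluster) & universe
        n = len(members)
        hit = False
        for cid, complex_members in catalogue.complexes.items():
            marked = complex_members & universe
            M = len(marked)
            x = len(members & marked)
            if n == 0 or M == 0 or x == 0:
                continue
            if enrichment_pvalue(N, M, n, x) < alpha:
                matched_complexes.add(cid)
                hit = True
        if hit:
            matched_clusters += 1
    precision = matched_clusters / len(clustering) if clustering else 0.0
    recall = len(matched_complexes) / len(catalogue.complexes)
    f = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return matched_clusters, precision, recall, f
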