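"""Planted-module synthetic data for every pipeline and evaluator input.

The generator emulates the statistical structure the method assumes: a
functional module induces a dense, high-confidence region of the PPI
network, and genes of the same module share an expression program.
Modules are planted as high-density blocks with edge confidences drawn
from a high range; the background is a sparse low-confidence graph.
Expression profiles are a per-module latent condition profile plus
i.i.d. Gaussian noise, calibrated so the mean within-module Pearson
correlation hits a target; background genes get independent profiles.
Optional decoy vertices carry profiles anticorrelated with a module's
program while being wired to it with high-confidence edges — exactly
the edges expression filtering exists to remove.

Evaluation inputs mirror the planted truth: a toy ontology with one
leaf term per module per aspect under a per-aspect root, localization
sets and a gold-standard catalogue per module, each with configurable
annotation dropout and contamination.

One RNG seed threads through all generators; everything is
reproducible bit-for-bit given the model.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from hunter.graph_io import (
    ComplexCatalogue,
    ExpressionMatrix,
    LocalizationData,
    ValidationError,
    WeightedNetwork,
)

_ASPECT_CODES = {"BP": "P", "MF": "F", "CC": "C"}
_ROOTS = {"BP": "GO:0000001", "MF": "GO:0000002", "CC": "GO:0000003"}
_NAMESPACES = {
    "BP": "biological_process",
    "MF": "molecular_function",
    "CC": "cellular_component",
}


@dataclass(frozen=True)
class PlantedModel:
    """Study conditions for one synthetic dataset.

    Defaults describe a small, clearly modular network: three modules
    of 8-12 proteins at within-block density 0.9 with edge confidences
    in [0.9, 0.99], a 30-protein background at density 0.02 with
    confidences in [0.1, 0.5], 10% of consecutive modules' vertices
    shared, and expression calibrated to a within-module Pearson
    correlation of 0.9 over 20 conditions.
    """

    n_modules: int = 3
    module_size_range: Tuple[int, int] = (8, 12)
    within_density: float = 0.9
    within_weight_range: Tuple[float, float] = (0.9, 0.99)
    n_background: int = 30
    background_density: float = 0.02
    background_weight_range: Tuple[float, float] = (0.1, 0.5)
    overlap_fraction: float = 0.1
    expression_within_correlation: float = 0.9
    n_conditions: int = 20
    noise_sd: Optional[float] = None  # derived from the correlation target if None
    profiled_fraction: float = 1.0
    n_decoys: int = 0
    decoy_edges_per_vertex: int = 3
    n_attachments_per_module: int = 0
    attachment_weight_range: Tuple[float, float] = (0.25, 0.4)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("within_density", "background_density"):
            d = getattr(self, name)
            if not 0.0 <= d <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {d}")
        for name in (
            "within_weight_range",
            "background_weight_range",
            "attachment_weight_range",
        ):
            lo, hi = getattr(self, name)
            if not (0.0 < lo <= hi <= 1.0):
                raise ValidationError(f"{name} must be within (0, 1], got {(lo, hi)}")
        if self.n_conditions < 3:
            raise ValidationError("n_conditions must be >= 3")

    @property
    def derived_noise_sd(self) -> float:
        """Noise level giving the target within-module correlation.

        With unit-variance latent profiles, corr = 1 / (1 + sd^2), so
        sd = sqrt(1/target - 1).
        """
        if self.noise_sd is not None:
            return self.noise_sd
        target = self.expression_within_correlation
        if not (0.0 < target < 1.0):
            return 0.0
        return math.sqrt(1.0 / target - 1.0)


def preset(name: str, seed: int = 0) -> PlantedModel:
    """Named study conditions: ``easy``, ``overlap`` or ``hard``.

    ``easy`` plants disjoint modules for exact-recovery checks;
    ``overlap`` shares 10% of vertices between consecutive modules to
    exercise merging; ``hard`` lowers densities, confidences and
    expression coherence.
    """
    if name == "easy":
        return PlantedModel(overlap_fraction=0.0, seed=seed)
    if name == "overlap":
        return PlantedModel(overlap_fraction=0.1, seed=seed)
    if name == "hard":
        return PlantedModel(
            within_density=0.7,
            within_weight_range=(0.7, 0.95),
            background_density=0.05,
            expression_within_correlation=0.7,
            overlap_fraction=0.1,
            seed=seed,
        )
    raise ValueError(f"unknown preset {name!r}")


@dataclass
class GroundTruth:
    """Planted structure returned alongside each generated artifact."""

    modules: List[Set[str]] = field(default_factory=list)
    background: Set[str] = field(default_factory=set)
    decoys: Set[str] = field(default_factory=set)
    decoy_edges: List[Tuple[str, str]] = field(default_factory=list)
    within_edges: List[Tuple[str, str]] = field(default_factory=list)
    module_of: Dict[str, int] = field(default_factory=dict)  # first module wins
    attachments: Set[str] = field(default_factory=set)
    attachment_of: Dict[str, int] = field(default_factory=dict)


def generate_network(model: PlantedModel) -> Tuple[WeightedNetwork, GroundTruth]:
    """Plant modules in a sparse background network.

    Modules are dense high-confidence blocks (a spanning path is forced
    so every planted module is connected even at moderate density);
    background edges join any pair not sharing a module. Attachment
    vertices model peripheral complex members: each is wired to a
    strict majority of one module's core with low-confidence edges, so
    growth adopts it while the q-connected core excludes it. Decoy
    vertices are wired to a random anchor module with within-range
    confidences — topologically indistinguishable from members,
    distinguishable only by expression. Deterministic given the model
    (including its seed).
    """
    rng = np.random.default_rng(model.seed)
    truth = GroundTruth()
    net = WeightedNetwork()

    lo, hi = model.module_size_range
    sizes = [int(rng.integers(lo, hi + 1)) for _ in range(model.n_modules)]
    counter = 0
    prev: List[str] = []
    for mi, size in enumerate(sizes):
        shared: List[str] = []
        if model.overlap_fraction > 0 and prev:
            k = min(int(round(model.overlap_fraction * size)), len(prev) - 1)
            if k > 0:
                shared = list(rng.choice(prev, size=k, replace=False))
        fresh = []
        for _ in range(size - len(shared)):
            fresh.append(f"M{counter:03d}")
            counter += 1
        members = shared + fresh
        truth.modules.append(set(members))
        for v in members:
            truth.module_of.setdefault(v, mi)
            net.add_vertex(v)
        wlo, whi = model.within_weight_range
        order = list(rng.permutation(members))
        forced = set()
        for a, b in zip(order, order[1:]):  # spanning path keeps the block connected
            forced.add(frozenset((a, b)))
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i], members[j]
                pair = frozenset((a, b))
                if pair in forced or rng.random() < model.within_density:
                    if not net.has_edge(a, b):
                        w = float(rng.uniform(wlo, whi))
                        net.add_edge(a, b, w)
                        truth.within_edges.append((a, b))
        prev = members

    for i in range(model.n_background):
        v = f"B{i:03d}"
        truth.background.add(v)
        net.add_vertex(v)

    blo, bhi = model.background_weight_range
    vertices = net.vertices
    for i in range(len(vertices)):
        for j in range(i + 1, len(vertices)):
            a, b = vertices[i], vertices[j]
            same_module = any(a in m and b in m for m in truth.modules)
            if same_module or net.has_edge(a, b):
                continue
            if rng.random() < model.background_density:
                net.add_edge(a, b, float(rng.uniform(blo, bhi)))

    alo, ahi = model.attachment_weight_range
    a_counter = 0
    for mi, members in enumerate(truth.modules):
        core = sorted(members)
        k = len(core) // 2 + 1  # strict majority: always passes the join rule
        for _ in range(model.n_attachments_per_module):
            v = f"A{a_counter:03d}"
            a_counter += 1
            truth.attachments.add(v)
            truth.attachment_of[v] = mi
            net.add_vertex(v)
            for u in rng.choice(core, size=min(k, len(core)), replace=False):
                net.add_edge(v, str(u), float(rng.uniform(alo, ahi)))

    wlo, whi = model.within_weight_range
    for i in range(model.n_decoys):
        v = f"D{i:03d}"
        truth.decoys.add(v)
        net.add_vertex(v)
        anchor = int(rng.integers(0, model.n_modules))
        truth.module_of[v] = -anchor - 1  # negative marks "anti-module"
        members = sorted(truth.modules[anchor])
        k = min(model.decoy_edges_per_vertex, len(members))
        targets = rng.choice(members, size=k, replace=False)
        for u in targets:
            net.add_edge(v, str(u), float(rng.uniform(wlo, whi)))
            truth.decoy_edges.append((v, str(u)))
    return net, truth


def generate_expression(
    model: PlantedModel, truth: GroundTruth
) -> ExpressionMatrix:
    """Latent-profile-plus-noise expression for every network protein.

    Module members share their module's latent condition profile;
    attachments follow it at double the noise level (partially
    co-expressed periphery); decoy vertices get the negated latent of
    their anchor module; background genes are independent
    standard-normal profiles. Gaussian noise at
    the model's (derived) noise level is added everywhere. With
    ``profiled_fraction < 1`` a random subset of proteins is left
    unprofiled.
    """
    rng = np.random.default_rng(model.seed + 1)
    sd = model.derived_noise_sd
    latents = {
        mi: rng.normal(size=model.n_conditions) for mi in range(len(truth.modules))
    }
    profiles: Dict[str, np.ndarray] = {}
    for mi, members in enumerate(truth.modules):
        for v in sorted(members):
            if v not in profiles:
                base = latents[truth.module_of[v]]
                profiles[v] = base + rng.normal(scale=sd, size=model.n_conditions)
    for v in sorted(truth.attachments):
        base = latents[truth.attachment_of[v]]
        profiles[v] = base + rng.normal(scale=2 * sd, size=model.n_conditions)
    for v in sorted(truth.background):
        profiles[v] = rng.normal(size=model.n_conditions)
    for v in sorted(truth.decoys):
        anchor = -truth.module_of[v] - 1
        profiles[v] = -latents[anchor] + rng.normal(scale=sd, size=model.n_conditions)
    if model.profiled_fraction < 1.0:
        genes = sorted(profiles)
        keep = rng.random(len(genes)) < model.profiled_fraction
        profiles = {g: profiles[g] for g, k in zip(genes, keep) if k}
    return ExpressionMatrix(profiles)


def generate_ontology(
    truth: GroundTruth,
    dropout: float = 0.0,
    contamination: float = 0.0,
    annotate_background: bool = False,
    seed: int = 0,
) -> Tuple[str, str]:
    """Toy ontology + annotation texts mirroring the planted modules.

    Each module owns a two-level branch per aspect under the aspect
    root: a broad "process" term and a specific "core" leaf beneath it.
    Core members are annotated to the leaf, attachment vertices to the
    broad parent — the nested-coherence structure of hub-attachment
    modules, where the periphery is functionally related but less
    specifically annotated than the core. Each annotation is
    independently dropped with probability ``dropout``;
    ``contamination`` adds that fraction of random non-member proteins
    to each leaf. With ``annotate_background`` each background protein
    gets a private leaf per aspect, so background pairs share only the
    root (zero relevance similarity). Returns (OBO text, 3-column
    annotation text) that round-trip through the evaluation parsers.
    """
    rng = np.random.default_rng(seed)
    obo_lines = ["format-version: 1.2", "ontology: synthetic-planted-modules", ""]
    ann_lines: List[str] = []

    def term(term_id: str, name: str, aspect: str, parent: Optional[str]) -> None:
        obo_lines.extend(
            [
                "[Term]",
                f"id: {term_id}",
                f"name: {name}",
                f"namespace: {_NAMESPACES[aspect]}",
            ]
        )
        if parent:
            obo_lines.append(f"is_a: {parent}")
        obo_lines.append("")

    for aspect, root in _ROOTS.items():
        term(root, f"{_NAMESPACES[aspect]} root", aspect, None)

    all_proteins = sorted(
        {v for m in truth.modules for v in m}
        | truth.background
        | truth.decoys
        | truth.attachments
    )
    leaf_no = 10
    attach_by_module: Dict[int, List[str]] = {}
    for v in sorted(truth.attachments):
        attach_by_module.setdefault(truth.attachment_of[v], []).append(v)
    for mi, members in enumerate(truth.modules):
        for aspect in _ROOTS:
            parent = f"GO:{leaf_no:07d}"
            leaf = f"GO:{leaf_no + 1:07d}"
            leaf_no += 2
            term(parent, f"module {mi} {aspect} process", aspect, _ROOTS[aspect])
            term(leaf, f"module {mi} {aspect} core term", aspect, parent)
            annotated = [v for v in sorted(members) if rng.random() >= dropout]
            outsiders = [p for p in all_proteins if p not in members]
            n_cont = int(round(contamination * len(members)))
            if n_cont and outsiders:
                annotated += list(
                    rng.choice(outsiders, size=min(n_cont, len(outsiders)), replace=False)
                )
            for v in annotated:
                ann_lines.append(f"{v}\t{leaf}\t{_ASPECT_CODES[aspect]}")
            for v in attach_by_module.get(mi, []):
                if rng.random() >= dropout:
                    ann_lines.append(f"{v}\t{parent}\t{_ASPECT_CODES[aspect]}")
    if annotate_background:
        for v in sorted(truth.background):
            for aspect in _ROOTS:
                leaf = f"GO:{leaf_no:07d}"
                leaf_no += 1
                term(leaf, f"background {v} {aspect} term", aspect, _ROOTS[aspect])
                if rng.random() >= dropout:
                    ann_lines.append(f"{v}\t{leaf}\t{_ASPECT_CODES[aspect]}")
    return "\n".join(obo_lines) + "\n", "\n".join(ann_lines) + "\n"


def generate_localization(
    truth: GroundTruth, seed: int = 0, include_background: bool = True
) -> LocalizationData:
    """One location per planted module (attachments included); background
    pooled in its own."""
    locations: Dict[str, Set[str]] = {}
    for mi, members in enumerate(truth.modules):
        locations[f"compartment_{mi}"] = set(members) | {
            v for v in truth.attachments if truth.attachment_of[v] == mi
        }
    if include_background and truth.background:
        locations["background_pool"] = set(truth.background)
    return LocalizationData(locations)


def generate_gold(
    truth: GroundTruth,
    dropout: float = 0.0,
    contamination: float = 0.0,
    seed: int = 0,
) -> ComplexCatalogue:
    """Gold-standard catalogue from planted modules, optionally degraded.

    Each member survives with probability 1 - dropout (at least two are
    always kept so complexes stay meaningful); contamination adds that
    fraction of random outside proteins per complex.
    """
    rng = np.random.default_rng(seed)
    all_proteins = sorted(
        {v for m in truth.modules for v in m}
        | truth.background
        | truth.decoys
        | truth.attachments
    )
    complexes: Dict[str, Set[str]] = {}
    for mi, members in enumerate(truth.modules):
        kept = [v for v in sorted(members) if rng.random() >= dropout]
        if len(kept) < 2:
            kept = sorted(members)[:2]
        outsiders = [p for p in all_proteins if p not in members]
        n_cont = int(round(contamination * len(members)))
        if n_cont and outsiders:
            kept += list(
                rng.choice(outsiders, size=min(n_cont, len(outsiders)), replace=False)
            )
        complexes[f"complex_{mi}"] = set(kept)
    return ComplexCatalogue(complexes)


def write_dataset(model: PlantedModel, out_dir) -> Dict[str, str]:
    """Generate and write all five input files plus the planted truth.

    Emits ``ppi.tsv``, ``expression.tsv``, ``ontology.obo``,
    ``annotations.tsv``, ``localization.tsv``, ``gold.tsv`` and
    ``truth.tsv`` under ``out_dir``; returns the path map.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net, truth = generate_network(model)
    expr = generate_expression(model, truth)
    obo_text, ann_text = generate_ontology(truth, seed=model.seed + 2)
    loc = generate_localization(truth, seed=model.seed + 3)
    gold = generate_gold(truth, seed=model.seed + 4)

    paths: Dict[str, str] = {}

    def emit(name: str, text: str) -> None:
        path = out / name
        path.write_text(text, encoding="utf-8")
        paths[name] = str(path)

    emit(
        "ppi.tsv",
        "".join(f"{a}\t{b}\t{w:.6g}\n" for a, b, w in net.edges()),
    )
    emit(
        "expression.tsv",
        "".join(
            f"{g}\t" + "\t".join(f"{x:.6g}" for x in expr.profile(g)) + "\n"
            for g in expr.genes
        ),
    )
    emit("ontology.obo", obo_text)
    emit("annotations.tsv", ann_text)
    emit(
        "localization.tsv",
        "".join(
            f"{k}\t{p}\n" for k in sorted(loc.locations) for p in sorted(loc.locations[k])
        ),
    )
    emit(
        "gold.tsv",
        "".join(
            f"{cid}\t{p}\n"
            for cid in sorted(gold.complexes)
            for p in sorted(gold.complexes[cid])
        ),
    )
    emit(
        "truth.tsv",
        "".join(
            f"module_{mi}\t-\t{','.join(sorted(m))}\n"
            for mi, m in enumerate(truth.modules)
        ),
    )
    return paths
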