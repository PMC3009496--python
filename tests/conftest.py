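"""Shared fixtures: small hand-built networks and a synthetic dataset."""

import dataclasses

import pytest

from hunter.graph_io import ExpressionMatrix, WeightedNetwork
from hunter.simulate import (
    generate_expression,
    generate_network,
    generate_ontology,
    preset,
)


@pytest.fixture
def triangle() -> WeightedNetwork:
    return WeightedNetwork.from_edges(
        [("a", "b", 0.9), ("b", "c", 0.8), ("a", "c", 0.7)]
    )


@pytest.fixture
def two_blob_net() -> WeightedNetwork:
    """Two 4-cliques of strong edges joined by one weak bridge."""
    edges = []
    for blob in (["a", "b", "c", "d"], ["e", "f", "g", "h"]):
        for i in range(4):
            for j in range(i + 1, 4):
                edges.append((blob[i], blob[j], 0.95))
    edges.append(("d", "e", 0.5))
    return WeightedNetwork.from_edges(edges)


@pytest.fixture
def small_expr() -> ExpressionMatrix:
    return ExpressionMatrix(
        {
            "a": [1.0, 2.0, 3.0, 4.0],
            "b": [1.1, 2.1, 2.9, 4.2],
            "c": [4.0, 3.0, 2.0, 1.0],
            "d": [0.5, 0.4, 0.6, 0.5],
        }
    )


@pytest.fixture(scope="session")
def easy_dataset():
    """Easy-regime planted network with expression, generated once."""
    model = preset("easy", seed=11)
    net, truth = generate_network(model)
    expr = generate_expression(model, truth)
    return model, net, truth, expr


@pytest.fixture(scope="session")
def easy_corpus(easy_dataset, tmp_path_factory):
    """Annotation corpus mirroring the easy dataset's planted modules."""
    from hunter.evaluation import parse_annotations, parse_obo

    _, _, truth, _ = easy_dataset
    obo_text, ann_text = generate_ontology(truth, seed=12)
    d = tmp_path_factory.mktemp("corpus")
    (d / "ontology.obo").write_text(obo_text)
    (d / "annotations.tsv").write_text(ann_text)
    dag = parse_obo(str(d / "ontology.obo"))
    return parse_annotations(str(d / "annotations.tsv"), dag)
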