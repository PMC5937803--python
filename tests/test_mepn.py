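"""mEPN graph model: shape classification, GraphML I/O, validation, tissues."""

import numpy as np
import pytest

from steroflow.mepn import (
    GraphMLError,
    GraphValidationError,
    MepnGraph,
    NodeKind,
    classify_node,
    parse_graphml,
    tissue_subgraph,
    validate_graph,
    write_graphml,
)
from steroflow.synthetic import random_mepn_graph


@pytest.mark.parametrize(
    "shape, fill, kind",
    [
        ("hexagon", None, NodeKind.BIOCHEMICAL),
        ("roundrectangle", None, NodeKind.PROTEIN),
        ("parallelogram", None, NodeKind.GENE),
        ("ellipse", None, NodeKind.PROCESS),
        ("rectangle", "#000000", NodeKind.TOKEN_INPUT),
        ("rectangle", "#FFCC00", NodeKind.ANNOTATION),
        ("star", None, NodeKind.ANNOTATION),
        ("", None, NodeKind.ANNOTATION),
    ],
)
def test_classify_node(shape, fill, kind):
    assert classify_node(shape, fill) == kind


def test_documented_shapes_biject_onto_entity_kinds():
    mapped = {
        classify_node(s, "#000000" if s == "rectangle" else None)
        for s in ("hexagon", "roundrectangle", "parallelogram", "rectangle")
    }
    assert mapped == {
        NodeKind.BIOCHEMICAL,
        NodeKind.PROTEIN,
        NodeKind.GENE,
        NodeKind.TOKEN_INPUT,
    }


_PLAIN_DOC = """<?xml version="1.0"?>
<graphml xmlns="http://graphml.graphdrawing.org/xmlns">
  <key id="k0" for="node" attr.name="shape" attr.type="string"/>
  <key id="k1" for="node" attr.name="fill" attr.type="string"/>
  <key id="k2" for="node" attr.name="label" attr.type="string"/>
  <key id="k3" for="edge" attr.name="label" attr.type="string"/>
  <graph id="demo" edgedefault="directed">
    <node id="t1"><data key="k0">rectangle</data><data key="k1">#000000</data></node>
    <node id="enz"><data key="k0">roundrectangle</data><data key="k2">HSD17B</data></node>
    <node id="rxn"><data key="k0">ellipse</data></node>
    <edge source="t1" target="enz"><data key="k3">1-20,2;21-50,8</data></edge>
    <edge source="enz" target="rxn"/>
  </graph>
</graphml>
"""


def test_parse_plain_graphml():
    graph = parse_graphml(_PLAIN_DOC)
    assert len(graph.nodes) == 3 and len(graph.edges) == 2
    kinds = {n.id: n.kind for n in graph}
    assert kinds == {
        "t1": NodeKind.TOKEN_INPUT,
        "enz": NodeKind.PROTEIN,
        "rxn": NodeKind.PROCESS,
    }
    assert graph.nodes["enz"].label == "HSD17B"
    assert graph.edges[0].label == "1-20,2;21-50,8"


_YED_DOC = """<?xml version="1.0"?>
<graphml xmlns="http://graphml.graphdrawing.org/xmlns"
         xmlns:y="http://www.yworks.com/xml/graphml">
  <key id="d0" for="node" yfiles.type="nodegraphics"/>
  <graph id="yed" edgedefault="directed">
    <node id="n0"><data key="d0"><y:ShapeNode>
      <y:Geometry x="10.5" y="-3.25" width="60" height="30"/>
      <y:Fill color="#FFFFFF"/>
      <y:NodeLabel>testosterone</y:NodeLabel>
      <y:Shape type="hexagon"/>
    </y:ShapeNode></data></node>
    <node id="n1"><data key="d0"><y:ShapeNode>
      <y:Fill color="#000000"/>
      <y:Shape type="rectangle"/>
    </y:ShapeNode></data></node>
    <edge source="n1" target="n0"/>
  </graph>
</graphml>
"""


def test_parse_yed_dialect():
    graph = parse_graphml(_YED_DOC)
    assert graph.nodes["n0"].kind == NodeKind.BIOCHEMICAL
    assert graph.nodes["n0"].label == "testosterone"
    assert graph.nodes["n0"].position == (10.5, -3.25)
    assert graph.nodes["n1"].kind == NodeKind.TOKEN_INPUT


def test_parse_rejects_dangling_edge():
    doc = _PLAIN_DOC.replace('target="rxn"', 'target="n99"')
    with pytest.raises(GraphValidationError, match="n99"):
        parse_graphml(doc)


def test_parse_rejects_malformed_xml():
    with pytest.raises(GraphMLError, match="malformed"):
        parse_graphml("<graphml><unclosed>")


def test_write_empty_graph():
    text = write_graphml(MepnGraph(name="empty"))
    assert "<node" not in text
    assert parse_graphml(text) == MepnGraph(name="empty")


def test_write_preserves_url():
    graph = MepnGraph(name="g")
    graph.add_node(
        "s", NodeKind.BIOCHEMICAL, label="DHT",
        url="https://www.chemspider.com/Search.aspx?q=DHT",
    )
    text = write_graphml(graph)
    assert "chemspider" in text
    assert parse_graphml(text).nodes["s"].url == graph.nodes["s"].url


@pytest.mark.parametrize("seed", range(25))
def test_graphml_round_trip_random_graphs(seed):
    graph = random_mepn_graph(np.random.default_rng(seed))
    assert parse_graphml(write_graphml(graph)) == graph


def test_validate_flags_token_input_with_incoming_edge():
    graph = MepnGraph()
    graph.add_node("a", NodeKind.BIOCHEMICAL)
    graph.add_node("ti", NodeKind.TOKEN_INPUT)
    graph.add_edge("a", "ti")
    findings = validate_graph(graph)
    assert any(
        f.severity == "error" and f.subject == "ti" and "incoming" in f.message
        for f in findings
    )


def test_validate_reports_implicit_transition_as_info():
    graph = MepnGraph()
    graph.add_node("a", NodeKind.BIOCHEMICAL)
    graph.add_node("b", NodeKind.BIOCHEMICAL)
    graph.add_edge("a", "b")
    findings = validate_graph(graph)
    assert [f.severity for f in findings] == ["info"]
    assert "implicit transition" in findings[0].message


def test_validate_flags_dead_end_process():
    graph = MepnGraph()
    graph.add_node("s", NodeKind.BIOCHEMICAL)
    graph.add_node("p", NodeKind.PROCESS)
    graph.add_edge("s", "p")
    findings = validate_graph(graph)
    assert any(f.severity == "error" and f.subject == "p" for f in findings)


def test_self_loop_rejected_at_construction():
    graph = MepnGraph()
    graph.add_node("a", NodeKind.BIOCHEMICAL)
    with pytest.raises(GraphValidationError, match="self-loop"):
        graph.add_edge("a", "a")


class TestTissueSubgraph:
    def test_testis_branch_excludes_aldosterone(self, framework_graph):
        sub = tissue_subgraph(framework_graph, "testis")
        labels = {n.label for n in sub}
        assert "testosterone" in labels and "androstenedione" in labels
        assert "aldosterone" not in labels

    def test_glomerulosa_contains_aldosterone(self, framework_graph):
        sub = tissue_subgraph(framework_graph, "adrenal glomerulosa")
        labels = {n.label for n in sub}
        assert "aldosterone" in labels and "testosterone" not in labels

    def test_unknown_tissue_lists_known(self, framework_graph):
        with pytest.raises(KeyError, match="testis"):
            tissue_subgraph(framework_graph, "liver")

    def test_keeps_token_input_parents(self, leydig_graph):
        sub = tissue_subgraph(leydig_graph, "testis")
        assert any(n.kind == NodeKind.TOKEN_INPUT for n in sub)

    def test_original_graph_unchanged(self, framework_graph):
        before = (len(framework_graph.nodes), len(framework_graph.edges))
        tissue_subgraph(framework_graph, "testis")
        assert (len(framework_graph.nodes), len(framework_graph.edges)) == before

    def test_sparsely_tagged_tissue_gives_minimal_graph(self):
        graph = MepnGraph()
        graph.add_node("a", NodeKind.BIOCHEMICAL, tissues={"ovary"})
        graph.add_node("b", NodeKind.BIOCHEMICAL)
        graph.add_edge("a", "b")
        sub = tissue_subgraph(graph, "ovary")
        assert set(sub.nodes) == {"a"} and sub.edges == []
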