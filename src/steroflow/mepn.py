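"""Typed mEPN pathway graphs with GraphML read/write and validation.

The modified Edinburgh Pathway Notation draws small biochemicals (steroids) as
hexagons, proteins/enzymes as rounded rectangles, genes as parallelograms,
reaction/process events as small ellipses and token inputs — the hooks through
which a diagram is parameterised — as black rectangles.  This module keeps that
vocabulary as a typed, directed graph: node kinds are derived from (or written
back to) GraphML shape attributes, so diagrams round-trip through graph editors.

Two GraphML dialects are read: plain GraphML, where node attributes live in
``<data>`` elements keyed by attribute name (``kind``, ``shape``, ``label``,
``url``, ``fill``, ``x``, ``y``), and the yEd extension vocabulary, where shape,
fill, geometry and labels live in ``y:ShapeNode`` elements.  Plain GraphML with
the documented key set is emitted.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from lxml import etree

__all__ = [
    "NodeKind",
    "MepnNode",
    "MepnEdge",
    "MepnGraph",
    "Finding",
    "GraphMLError",
    "GraphValidationError",
    "classify_node",
    "shape_for_kind",
    "parse_graphml",
    "read_graphml",
    "write_graphml",
    "validate_graph",
    "tissue_subgraph",
    "findings_to_jsonl",
]

GRAPHML_NS = "http://graphml.graphdrawing.org/xmlns"
YED_NS = "http://www.yworks.com/xml/graphml"
_NSMAP = {"g": GRAPHML_NS, "y": YED_NS}


class GraphMLError(ValueError):
    """Malformed GraphML input (XML syntax or missing structure)."""


class GraphValidationError(ValueError):
    """A graph violates a structural invariant (e.g. dangling edge)."""


class NodeKind(str, enum.Enum):
    BIOCHEMICAL = "biochemical"
    PROTEIN = "protein"
    GENE = "gene"
    PROCESS = "process"
    TOKEN_INPUT = "token_input"
    ANNOTATION = "annotation"


#: kinds whose nodes hold tokens when the graph is compiled to a Petri net
PLACE_KINDS = frozenset({NodeKind.BIOCHEMICAL, NodeKind.PROTEIN})

_SHAPE_TO_KIND = {
    "hexagon": NodeKind.BIOCHEMICAL,
    "roundrectangle": NodeKind.PROTEIN,
    "rounded_rectangle": NodeKind.PROTEIN,
    "parallelogram": NodeKind.GENE,
    "ellipse": NodeKind.PROCESS,
}

_KIND_TO_SHAPE = {
    NodeKind.BIOCHEMICAL: "hexagon",
    NodeKind.PROTEIN: "roundrectangle",
    NodeKind.GENE: "parallelogram",
    NodeKind.PROCESS: "ellipse",
    NodeKind.TOKEN_INPUT: "rectangle",
    NodeKind.ANNOTATION: "rectangle",
}

_BLACK_FILLS = {"#000000", "black", "#000"}


def classify_node(shape: str, fill: str | None = None) -> NodeKind:
    """Map a GraphML shape token (plus fill colour) to a node kind.

    Hexagon -> biochemical, rounded rectangle -> protein, parallelogram ->
    gene, ellipse -> process, black-filled rectangle -> token input.  Any
    unknown shape (legends, tissue boxes, decorations) becomes an annotation
    node, which compilation ignores.
    """
    token = (shape or "").strip().lower()
    if token in _SHAPE_TO_KIND:
        return _SHAPE_TO_KIND[token]
    if token == "rectangle":
        if fill is not None and fill.strip().lower() in _BLACK_FILLS:
            return NodeKind.TOKEN_INPUT
        return NodeKind.ANNOTATION
    return NodeKind.ANNOTATION


def shape_for_kind(kind: NodeKind) -> str:
    return _KIND_TO_SHAPE[kind]


@dataclass
class MepnNode:
    id: str
    kind: NodeKind
    label: str = ""
    url: str | None = None
    shape: str | None = None
    position: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise GraphValidationError("node id must be non-empty")
        self.kind = NodeKind(self.kind)
        if self.shape is None:
            self.shape = shape_for_kind(self.kind)


@dataclass
class MepnEdge:
    source: str
    target: str
    label: str | None = None

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise GraphValidationError(f"self-loop on node {self.source!r}")


@dataclass
class MepnGraph:
    """A directed, typed mEPN pathway diagram."""

    name: str = ""
    nodes: dict[str, MepnNode] = field(default_factory=dict)
    edges: list[MepnEdge] = field(default_factory=list)
    tissue_tags: dict[str, set[str]] = field(default_factory=dict)

    # -- construction -----------------------------------------------------
    def add_node(
        self,
        id: str,
        kind: NodeKind | str,
        label: str = "",
        url: str | None = None,
        shape: str | None = None,
        position: tuple[float, float] | None = None,
        tissues: Iterable[str] = (),
    ) -> MepnNode:
        if id in self.nodes:
            raise GraphValidationError(f"duplicate node id {id!r}")
        node = MepnNode(id, NodeKind(kind), label, url, shape, position)
        self.nodes[id] = node
        tissues = set(tissues)
        if tissues:
            self.tissue_tags.setdefault(id, set()).update(tissues)
        return node

    def add_edge(self, source: str, target: str, label: str | None = None) -> MepnEdge:
        for endpoint in (source, target):
            if endpoint not in self.nodes:
                raise GraphValidationError(
                    f"edge {source!r}->{target!r} references missing node {endpoint!r}"
                )
        edge = MepnEdge(source, target, label)
        self.edges.append(edge)
        return edge

    def tag_tissue(self, node_id: str, *tissues: str) -> None:
        if node_id not in self.nodes:
            raise GraphValidationError(f"unknown node {node_id!r}")
        self.tissue_tags.setdefault(node_id, set()).update(tissues)

    # -- queries ----------------------------------------------------------
    def nodes_of_kind(self, kind: NodeKind) -> list[MepnNode]:
        return [n for n in self.nodes.values() if n.kind == kind]

    def predecessors(self, node_id: str) -> list[str]:
        return [e.source for e in self.edges if e.target == node_id]

    def successors(self, node_id: str) -> list[str]:
        return [e.target for e in self.edges if e.source == node_id]

    def in_degree(self, node_id: str) -> int:
        return sum(1 for e in self.edges if e.target == node_id)

    def out_degree(self, node_id: str) -> int:
        return sum(1 for e in self.edges if e.source == node_id)

    def known_tissues(self) -> set[str]:
        out: set[str] = set()
        for tags in self.tissue_tags.values():
            out |= tags
        return out

    def __iter__(self) -> Iterator[MepnNode]:
        return iter(self.nodes.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MepnGraph):
            return NotImplemented
        return (
            self.name == other.name
            and self.nodes == other.nodes
            and self.edges == other.edges
            and {k: v for k, v in self.tissue_tags.items() if v}
            == {k: v for k, v in other.tissue_tags.items() if v}
        )


# ---------------------------------------------------------------------------
# GraphML reading


def _qname(tag: str) -> str:
    return f"{{{GRAPHML_NS}}}{tag}"


def _collect_data(element: etree._Element, key_names: dict[str, str]) -> dict[str, str]:
    values: dict[str, str] = {}
    for data in element.findall(_qname("data")):
        name = key_names.get(data.get("key", ""), data.get("key", ""))
        if len(data) == 0:
            values[name] = data.text or ""
    return values


def _yed_shape_info(
    node_el: etree._Element,
) -> tuple[str | None, str | None, str | None, tuple[float, float] | None]:
    """Extract (shape, fill, label, position) from yEd extension elements."""
    shape = fill = label = None
    position = None
    for data in node_el.findall(_qname("data")):
        shape_el = data.find(f"{{{YED_NS}}}ShapeNode")
        if shape_el is None:
            generic = data.find(f"{{{YED_NS}}}GenericNode")
            if generic is None:
                continue
            shape_el = generic
        sh = shape_el.find(f"{{{YED_NS}}}Shape")
        if sh is not None:
            shape = sh.get("type")
        fl = shape_el.find(f"{{{YED_NS}}}Fill")
        if fl is not None:
            fill = fl.get("color")
        lab = shape_el.find(f"{{{YED_NS}}}NodeLabel")
        if lab is not None and lab.text:
            label = lab.text.strip()
        geom = shape_el.find(f"{{{YED_NS}}}Geometry")
        if geom is not None and geom.get("x") is not None:
            position = (float(geom.get("x")), float(geom.get("y", "0")))
    return shape, fill, label, position


def _yed_edge_label(edge_el: etree._Element) -> str | None:
    for data in edge_el.findall(_qname("data")):
        for holder in data:
            lab = holder.find(f"{{{YED_NS}}}EdgeLabel")
            if lab is not None and lab.text and lab.text.strip():
                return lab.text.strip()
    return None


def parse_graphml(document: str | bytes) -> MepnGraph:
    """Parse GraphML text (plain or yEd dialect) into a validated MepnGraph.

    Raises :class:`GraphMLError` on malformed XML (the message names the
    offending line) and :class:`GraphValidationError` when an edge references
    a node id that does not exist.
    """
    if isinstance(document, str):
        document = document.encode("utf-8")
    try:
        root = etree.fromstring(document)
    except etree.XMLSyntaxError as exc:
        raise GraphMLError(f"malformed GraphML: {exc}") from exc
    if etree.QName(root).localname != "graphml":
        raise GraphMLError(
            f"expected <graphml> document root, got <{etree.QName(root).localname}>"
        )

    key_names = {
        key.get("id", ""): key.get("attr.name", key.get("id", ""))
        for key in root.findall(_qname("key"))
    }

    graph_el = root.find(_qname("graph"))
    if graph_el is None:
        raise GraphMLError("document contains no <graph> element")

    graph = MepnGraph(name=graph_el.get("id", ""))
    for node_el in graph_el.findall(_qname("node")):
        node_id = node_el.get("id")
        if node_id is None:
            raise GraphMLError("node element without id")
        if node_id in graph.nodes:
            raise GraphValidationError(f"duplicate node id {node_id!r}")
        data = _collect_data(node_el, key_names)
        y_shape, y_fill, y_label, y_pos = _yed_shape_info(node_el)
        shape = data.get("shape") or y_shape
        fill = data.get("fill") or y_fill
        label = data.get("label") or y_label or ""
        url = data.get("url") or None
        if "kind" in data:
            try:
                kind = NodeKind(data["kind"])
            except ValueError as exc:
                raise GraphMLError(
                    f"node {node_id!r}: unknown kind {data['kind']!r}"
                ) from exc
        else:
            kind = classify_node(shape or "", fill)
        position = y_pos
        if "x" in data and "y" in data:
            position = (float(data["x"]), float(data["y"]))
        graph.nodes[node_id] = MepnNode(
            node_id,
            kind,
            label=label,
            url=url,
            shape=(shape or None),
            position=position,
        )
        tissues = data.get("tissues", "")
        if tissues:
            graph.tissue_tags[node_id] = set(t for t in tissues.split(";") if t)

    missing: list[str] = []
    for edge_el in graph_el.findall(_qname("edge")):
        source, target = edge_el.get("source"), edge_el.get("target")
        if source is None or target is None:
            raise GraphMLError("edge element without source/target")
        data = _collect_data(edge_el, key_names)
        label = data.get("label") or _yed_edge_label(edge_el)
        for endpoint in (source, target):
            if endpoint not in graph.nodes:
                missing.append(endpoint)
        if source in graph.nodes and target in graph.nodes:
            graph.edges.append(MepnEdge(source, target, label))
    if missing:
        raise GraphValidationError(
            "edges reference missing node ids: " + ", ".join(sorted(set(missing)))
        )
    return graph


def read_graphml(path: str | Path) -> MepnGraph:
    graph = parse_graphml(Path(path).read_bytes())
    if not graph.name:
        graph.name = Path(path).stem
    return graph


# ---------------------------------------------------------------------------
# GraphML writing

_NODE_KEYS = ("kind", "shape", "fill", "label", "url", "x", "y", "tissues")


def write_graphml(graph: MepnGraph) -> str:
    """Serialise a graph as plain GraphML with a documented key set.

    ``parse_graphml(write_graphml(g)) == g`` for any valid graph: kinds are
    written explicitly (as well as their shape mapping), so classification is
    never ambiguous on re-read.
    """
    root = etree.Element(_qname("graphml"), nsmap={None: GRAPHML_NS})
    key_ids: dict[tuple[str, str], str] = {}
    for i, name in enumerate(_NODE_KEYS):
        kid = f"d{i}"
        key_ids[("node", name)] = kid
        etree.SubElement(
            root, _qname("key"),
            id=kid, attrib={"for": "node", "attr.name": name, "attr.type": "string"},
        )
    key_ids[("edge", "label")] = "e0"
    etree.SubElement(
        root, _qname("key"),
        id="e0", attrib={"for": "edge", "attr.name": "label", "attr.type": "string"},
    )

    graph_attrib = {"edgedefault": "directed"}
    if graph.name:
        graph_attrib["id"] = graph.name
    graph_el = etree.SubElement(root, _qname("graph"), attrib=graph_attrib)

    def put(parent: etree._Element, domain: str, name: str, value: str) -> None:
        data = etree.SubElement(parent, _qname("data"), key=key_ids[(domain, name)])
        data.text = value

    for node in graph.nodes.values():
        node_el = etree.SubElement(graph_el, _qname("node"), id=node.id)
        put(node_el, "node", "kind", node.kind.value)
        put(node_el, "node", "shape", node.shape or shape_for_kind(node.kind))
        if node.kind == NodeKind.TOKEN_INPUT:
            put(node_el, "node", "fill", "#000000")
        if node.label:
            put(node_el, "node", "label", node.label)
        if node.url:
            put(node_el, "node", "url", node.url)
        if node.position is not None:
            put(node_el, "node", "x", repr(float(node.position[0])))
            put(node_el, "node", "y", repr(float(node.position[1])))
        tissues = graph.tissue_tags.get(node.id)
        if tissues:
            put(node_el, "node", "tissues", ";".join(sorted(tissues)))

    for i, edge in enumerate(graph.edges):
        edge_el = etree.SubElement(
            graph_el, _qname("edge"), id=f"e{i}", source=edge.source, target=edge.target
        )
        if edge.label:
            put(edge_el, "edge", "label", edge.label)

    return etree.tostring(root, pretty_print=True, encoding="unicode")


# ---------------------------------------------------------------------------
# Validation


@dataclass(frozen=True)
class Finding:
    severity: str  # "error" | "warning" | "info"
    subject: str   # node id or "source->target"
    message: str


def findings_to_jsonl(findings: Iterable[Finding]) -> str:
    return "\n".join(
        json.dumps(
            {"severity": f.severity, "subject": f.subject, "message": f.message}
        )
        for f in findings
    )


def validate_graph(graph: MepnGraph) -> list[Finding]:
    """Structural lint of an mEPN graph.

    Error findings are violations that make the graph unsimulatable (dangling
    edges, token inputs with incoming edges, process nodes missing substrates
    or products).  A direct entity-to-entity edge — the notation's shorthand
    for an uncharacterised event between two known molecules — is reported as
    an informational "implicit transition", never as an error.
    """
    findings: list[Finding] = []

    for edge in graph.edges:
        subject = f"{edge.source}->{edge.target}"
        for endpoint in (edge.source, edge.target):
            if endpoint not in graph.nodes:
                findings.append(
                    Finding("error", subject, f"edge references missing node {endpoint!r}")
                )
        if edge.source == edge.target:
            findings.append(Finding("error", subject, "self-loop"))

    for node in graph.nodes.values():
        if node.kind == NodeKind.TOKEN_INPUT:
            if graph.in_degree(node.id) > 0:
                findings.append(
                    Finding("error", node.id, "token input node has incoming edges")
                )
            if graph.out_degree(node.id) == 0:
                findings.append(
                    Finding("error", node.id, "token input node feeds nothing")
                )
        elif node.kind == NodeKind.PROCESS:
            pred_kinds = {
                graph.nodes[p].kind
                for p in graph.predecessors(node.id)
                if p in graph.nodes
            }
            succ_kinds = {
                graph.nodes[s].kind
                for s in graph.successors(node.id)
                if s in graph.nodes
            }
            if not pred_kinds & PLACE_KINDS:
                findings.append(
                    Finding("error", node.id, "process node has no entity input")
                )
            if not succ_kinds & PLACE_KINDS:
                findings.append(
                    Finding("error", node.id, "process node has no entity output")
                )

    for edge in graph.edges:
        if edge.source in graph.nodes and edge.target in graph.nodes:
            src, tgt = graph.nodes[edge.source], graph.nodes[edge.target]
            if src.kind in PLACE_KINDS and tgt.kind in PLACE_KINDS:
                findings.append(
                    Finding(
                        "info",
                        f"{edge.source}->{edge.target}",
                        "implicit transition (uncharacterised direct conversion)",
                    )
                )
            if src.kind == NodeKind.TOKEN_INPUT and edge.label:
                try:
                    from .schedule import parse_schedule

                    parse_schedule(edge.label)
                except Exception:
                    findings.append(
                        Finding(
                            "warning",
                            f"{edge.source}->{edge.target}",
                            f"edge label {edge.label!r} is not schedule notation",
                        )
                    )
    return findings


def tissue_subgraph(graph: MepnGraph, tissue: str) -> MepnGraph:
    """Induced subgraph of the nodes tagged with *tissue*.

    Token-input parents of retained nodes are kept so the subgraph stays
    parameterisable.  The original graph is not modified.
    """
    known = graph.known_tissues()
    if tissue not in known:
        raise KeyError(
            f"unknown tissue {tissue!r}; known tissues: {sorted(known)}"
        )
    keep = {nid for nid, tags in graph.tissue_tags.items() if tissue in tags}
    for edge in graph.edges:
        if (
            edge.target in keep
            and edge.source in graph.nodes
            and graph.nodes[edge.source].kind == NodeKind.TOKEN_INPUT
        ):
            keep.add(edge.source)

    sub = MepnGraph(name=f"{graph.name}[{tissue}]" if graph.name else tissue)
    for nid, node in graph.nodes.items():
        if nid in keep:
            sub.nodes[nid] = MepnNode(
                node.id, node.kind, node.label, node.url, node.shape, node.position
            )
            tags = graph.tissue_tags.get(nid)
            if tags:
                sub.tissue_tags[nid] = set(tags)
    for edge in graph.edges:
        if edge.source in keep and edge.target in keep:
            sub.edges.append(MepnEdge(edge.source, edge.target, edge.label))
    return sub
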