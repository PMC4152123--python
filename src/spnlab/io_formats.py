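"""Readers and writers for all interchange formats.

Supported formats
-----------------

* **CSV edge list** (RFC 4180, UTF-8). Required columns ``source,target``;
  optional ``directed`` (``directed``/``undirected``, default undirected),
  ``type`` (default ``physical``) and ``references`` (semicolon-separated
  citations in one cell). One edge per row; nodes are created on first
  mention; a row with an empty target declares an isolated node; duplicate
  rows collapse with reference merging.
* **Cytoscape-export JSON**: a document with an ``elements`` collection
  holding node entries (``data.id``) and edge entries (``data.source``,
  ``data.target``). Both the ``{"nodes": [...], "edges": [...]}`` object
  shape and the flat elements list are accepted. Unrecognised ``data`` fields
  are kept as string attributes.
* **Snoopy XML** (declared subset): ``nodeclass`` elements named ``Place``
  and ``Transition`` (with ``Name``, ``Marking`` and rate attributes) and the
  ``Edge`` edgeclass with ``Multiplicity``. Anything else is skipped with a
  logged warning.
* **Project JSON**: this package's own versioned, self-contained document for
  both graphs and Petri nets, covering nested graphs, coarse places, nested
  transitions, references and attributes. Serialization is canonical (sorted
  keys, two-space indent, trailing newline) so an unmodified document
  re-serializes byte-identically.

Every reader validates its result before returning; truncated or malformed
input raises a clean error, never a silent partial import.
"""

from __future__ import annotations

import csv
import io
import json
import logging

from lxml import etree

from .errors import (
    DanglingEdgeError,
    EmptyInputError,
    ParseError,
    SchemaError,
    UnsupportedVersionError,
    ValidationError,
)
from .graph_model import GraphEdge, GraphNode, InteractionGraph
from .petri_model import Arc, PetriNet, Place, Transition, net_validate

logger = logging.getLogger(__name__)

__all__ = [
    "PROJECT_FORMAT_VERSION",
    "ProjectDocument",
    "read_edge_csv",
    "write_edge_csv",
    "read_cytoscape_json",
    "read_snoopy",
    "read_project_json",
    "write_project_json",
    "graph_to_payload",
    "payload_to_graph",
    "net_to_payload",
    "payload_to_net",
]

PROJECT_FORMAT_VERSION = "1.0"

CSV_REQUIRED_COLUMNS = ("source", "target")
CSV_OPTIONAL_COLUMNS = ("directed", "type", "references")


# ---------------------------------------------------------------------------
# CSV edge lists
# ---------------------------------------------------------------------------

def read_edge_csv(text: str) -> InteractionGraph:
    """Parse a CSV edge list into an interaction graph.

    Raises :class:`EmptyInputError` on an empty document and
    :class:`SchemaError` (naming the columns or the line) on structural
    problems.
    """
    if not text.strip():
        raise EmptyInputError("empty CSV document")
    reader = csv.reader(io.StringIO(text))
    try:
        header = next(reader)
    except StopIteration:  # pragma: no cover - guarded by strip() above
        raise EmptyInputError("empty CSV document")
    columns = [c.strip().lower() for c in header]
    missing = [c for c in CSV_REQUIRED_COLUMNS if c not in columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    index = {c: columns.index(c) for c in columns}
    graph = InteractionGraph()
    n_required = max(index[c] for c in CSV_REQUIRED_COLUMNS) + 1
    for line_no, row in enumerate(reader, start=2):
        if not row or all(not cell.strip() for cell in row):
            continue
        if len(row) < n_required:
            raise SchemaError(
                f"line {line_no}: expected at least {n_required} columns, got {len(row)}"
            )
        source = row[index["source"]].strip()
        target = row[index["target"]].strip()
        if not source:
            raise SchemaError(f"line {line_no}: empty source")
        if not target:
            # node-only row: declares an isolated node
            if source not in graph.nodes:
                graph.add_node(GraphNode(id=source))
            continue
        directed = False
        if "directed" in index and len(row) > index["directed"]:
            cell = row[index["directed"]].strip().lower()
            if cell not in ("", "directed", "undirected"):
                raise SchemaError(
                    f"line {line_no}: directed column must be "
                    f"'directed' or 'undirected', got {cell!r}"
                )
            directed = cell == "directed"
        edge_type = "physical"
        if "type" in index and len(row) > index["type"] and row[index["type"]].strip():
            edge_type = row[index["type"]].strip()
        references: list[str] = []
        if "references" in index and len(row) > index["references"]:
            references = [
                r.strip() for r in row[index["references"]].split(";") if r.strip()
            ]
        for node_id in (source, target):
            if node_id not in graph.nodes:
                graph.add_node(GraphNode(id=node_id))
        graph.add_edge(
            GraphEdge(source, target, directed=directed, edge_type=edge_type,
                      references=references)
        )
    problems = graph.validate()
    if problems:  # pragma: no cover - construction enforces the invariants
        raise ValidationError("; ".join(problems))
    return graph


def write_edge_csv(graph: InteractionGraph) -> str:
    """Deterministic CSV export (rows sorted by source, target, type).

    Nested graphs cannot be expressed in a flat CSV; nodes carrying one are
    exported as plain nodes with a logged warning.
    """
    nested = [n.id for n in graph.nodes.values() if n.nested is not None]
    if nested:
        logger.warning(
            "CSV export is flat: dropping nested graphs of %d node(s): %s",
            len(nested), ", ".join(sorted(nested)),
        )
    out = io.StringIO()
    writer = csv.writer(out, lineterminator="\r\n")
    writer.writerow(["source", "target", "directed", "type", "references"])
    rows = []
    connected = set()
    for e in graph.edges:
        connected.update((e.source, e.target))
        rows.append([
            e.source,
            e.target,
            "directed" if e.directed else "undirected",
            e.edge_type,
            ";".join(e.references),
        ])
    # isolated nodes survive as node-only rows (empty target)
    for node_id in sorted(set(graph.nodes) - connected):
        rows.append([node_id, "", "", "", ""])
    rows.sort(key=lambda r: (r[0], r[1], r[3]))
    writer.writerows(rows)
    return out.getvalue()


# ---------------------------------------------------------------------------
# Cytoscape JSON
# ---------------------------------------------------------------------------

def read_cytoscape_json(text: str) -> InteractionGraph:
    """Parse a Cytoscape ``elements`` export into an interaction graph."""
    if not text.strip():
        raise EmptyInputError("empty Cytoscape document")
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError(f"not valid JSON: {exc}") from exc
    if not isinstance(doc, dict) or "elements" not in doc:
        raise SchemaError("missing 'elements' collection", path="/elements")
    elements = doc["elements"]
    if isinstance(elements, dict):
        node_entries = elements.get("nodes", [])
        edge_entries = elements.get("edges", [])
    elif isinstance(elements, list):
        node_entries = [e for e in elements if "source" not in e.get("data", {})]
        edge_entries = [e for e in elements if "source" in e.get("data", {})]
    else:
        raise SchemaError("'elements' must be an object or a list", path="/elements")
    graph = InteractionGraph(name=str(doc.get("name", "")))
    for k, entry in enumerate(node_entries):
        data = entry.get("data", {})
        node_id = data.get("id")
        if not node_id:
            raise SchemaError("node entry missing data.id", path=f"/elements/nodes/{k}")
        attributes = {
            key: str(value)
            for key, value in data.items()
            if key not in ("id", "name", "label", "entity_kind")
        }
        graph.add_node(GraphNode(
            id=str(node_id),
            label=str(data.get("name", data.get("label", ""))),
            entity_kind=str(data.get("entity_kind", "")),
            attributes=attributes,
        ))
    for k, entry in enumerate(edge_entries):
        data = entry.get("data", {})
        source, target = data.get("source"), data.get("target")
        if source is None or target is None:
            raise SchemaError(
                "edge entry missing data.source/data.target",
                path=f"/elements/edges/{k}",
            )
        for endpoint in (source, target):
            if str(endpoint) not in graph.nodes:
                raise DanglingEdgeError(
                    f"edge #{k} references unknown node {endpoint!r}"
                )
        references = data.get("references", [])
        if isinstance(references, str):
            references = [r for r in references.split(";") if r]
        attributes = {
            key: str(value)
            for key, value in data.items()
            if key not in ("id", "source", "target", "directed", "type",
                           "edge_type", "references")
        }
        graph.add_edge(GraphEdge(
            source=str(source),
            target=str(target),
            directed=bool(data.get("directed", False)),
            edge_type=str(data.get("edge_type", data.get("type", "physical"))),
            references=[str(r) for r in references],
            attributes=attributes,
        ))
    return graph


# ---------------------------------------------------------------------------
# Snoopy XML
# ---------------------------------------------------------------------------

_SNOOPY_PLACE_CLASSES = {"Place"}
_SNOOPY_TRANSITION_CLASSES = {"Transition", "Stochastic Transition"}
_SNOOPY_EDGE_CLASSES = {"Edge"}


def _snoopy_attribute(node, name: str) -> str | None:
    for attr in node.findall("attribute"):
        if attr.get("name") == name:
            return (attr.text or "").strip()
    return None


def read_snoopy(text: str) -> PetriNet:
    """Import the supported subset of a Snoopy Petri-net export.

    Places (with markings), transitions (with a numeric rate when one is
    present) and arcs (with multiplicities) are extracted; unsupported node
    and edge classes are skipped, each with a logged warning and a final
    summary count.
    """
    if not text.strip():
        raise ParseError("empty Snoopy document")
    try:
        root = etree.fromstring(text.encode("utf-8"))
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"not valid XML: {exc}") from exc
    net = PetriNet(name="snoopy-import")
    id_map: dict[str, str] = {}  # Snoopy numeric node id -> spnlab id
    skipped = 0
    found_any = False
    for nodeclass in root.iter("nodeclass"):
        cls = nodeclass.get("name", "")
        if cls in _SNOOPY_PLACE_CLASSES or cls in _SNOOPY_TRANSITION_CLASSES:
            found_any = True
            for node in nodeclass.findall("node"):
                raw_id = node.get("id")
                name = _snoopy_attribute(node, "Name") or (
                    ("P" if cls in _SNOOPY_PLACE_CLASSES else "T") + str(raw_id)
                )
                if cls in _SNOOPY_PLACE_CLASSES:
                    marking = _snoopy_attribute(node, "Marking")
                    net.add_place(Place(
                        id=name, label=name,
                        initial_tokens=int(marking) if marking else 0,
                    ))
                else:
                    rate_text = (
                        _snoopy_attribute(node, "Rate")
                        or _snoopy_attribute(node, "FunctionList")
                    )
                    try:
                        rate = float(rate_text) if rate_text else 1.0
                    except ValueError:
                        rate = 1.0  # symbolic rate function: default it
                    net.add_transition(Transition(id=name, label=name, rate_constant=rate))
                if raw_id is not None:
                    id_map[raw_id] = name
        else:
            count = len(nodeclass.findall("node"))
            if count:
                skipped += count
                logger.warning("skipping %d node(s) of unsupported class %r", count, cls)
    for edgeclass in root.iter("edgeclass"):
        cls = edgeclass.get("name", "")
        if cls in _SNOOPY_EDGE_CLASSES:
            for k, edge in enumerate(edgeclass.findall("edge")):
                src, tgt = edge.get("source"), edge.get("target")
                if src not in id_map or tgt not in id_map:
                    raise ParseError(f"edge #{k} references unknown node id")
                mult_text = _snoopy_attribute(edge, "Multiplicity")
                net.add_arc(id_map[src], id_map[tgt],
                            int(mult_text) if mult_text else 1)
        else:
            count = len(edgeclass.findall("edge"))
            if count:
                skipped += count
                logger.warning("skipping %d edge(s) of unsupported class %r", count, cls)
    if not found_any:
        raise ParseError("no recognizable Petri-net content in document")
    if skipped:
        logger.warning("Snoopy import skipped %d unsupported element(s) in total", skipped)
    problems = net_validate(net)
    if problems:
        raise ValidationError("imported net is invalid: " + "; ".join(problems))
    return net


# ---------------------------------------------------------------------------
# Project JSON
# ---------------------------------------------------------------------------

class ProjectDocument:
    """A saved project: a named graph or Petri net plus format metadata.

    Unknown top-level keys of a parsed document are preserved in ``extra`` and
    written back on serialization.
    """

    def __init__(self, payload, name: str = "", description: str = "",
                 extra: dict | None = None):
        if isinstance(payload, InteractionGraph):
            self.project_kind = "graph"
        elif isinstance(payload, PetriNet):
            self.project_kind = "petri_net"
        else:
            raise SchemaError(
                f"payload must be an InteractionGraph or PetriNet, "
                f"got {type(payload).__name__}"
            )
        self.payload = payload
        self.name = name or getattr(payload, "name", "")
        self.description = description or getattr(payload, "description", "")
        self.extra = dict(extra or {})


def graph_to_payload(graph: InteractionGraph) -> dict:
    return {
        "name": graph.name,
        "description": graph.description,
        "nodes": [
            {
                "id": n.id,
                "label": n.label,
                "entity_kind": n.entity_kind,
                "attributes": dict(sorted(n.attributes.items())),
                "nested": graph_to_payload(n.nested) if n.nested is not None else None,
            }
            for n in sorted(graph.nodes.values(), key=lambda n: n.id)
        ],
        "edges": sorted(
            (
                {
                    "source": e.source,
                    "target": e.target,
                    "directed": e.directed,
                    "edge_type": e.edge_type,
                    "references": list(e.references),
                    "attributes": dict(sorted(e.attributes.items())),
                }
                for e in graph.edges
            ),
            key=lambda d: (d["source"], d["target"], d["edge_type"], d["directed"]),
        ),
    }


def payload_to_graph(payload: dict, path: str = "/payload") -> InteractionGraph:
    if not isinstance(payload, dict):
        raise SchemaError("graph payload must be an object", path=path)
    graph = InteractionGraph(
        name=str(payload.get("name", "")),
        description=str(payload.get("description", "")),
    )
    for k, raw in enumerate(payload.get("nodes", [])):
        if not isinstance(raw, dict) or "id" not in raw:
            raise SchemaError("node must be an object with an id", path=f"{path}/nodes/{k}")
        nested = raw.get("nested")
        graph.add_node(GraphNode(
            id=raw["id"],
            label=str(raw.get("label", "")),
            entity_kind=str(raw.get("entity_kind", "")),
            attributes=dict(raw.get("attributes", {})),
            nested=payload_to_graph(nested, f"{path}/nodes/{k}/nested")
            if nested is not None else None,
        ))
    for k, raw in enumerate(payload.get("edges", [])):
        if not isinstance(raw, dict) or "source" not in raw or "target" not in raw:
            raise SchemaError(
                "edge must be an object with source and target",
                path=f"{path}/edges/{k}",
            )
        graph.add_edge(GraphEdge(
            source=raw["source"],
            target=raw["target"],
            directed=bool(raw.get("directed", False)),
            edge_type=str(raw.get("edge_type", "physical")),
            references=[str(r) for r in raw.get("references", [])],
            attributes=dict(raw.get("attributes", {})),
        ))
    return graph


def net_to_payload(net: PetriNet) -> dict:
    return {
        "name": net.name,
        "description": net.description,
        "places": [
            {
                "id": p.id,
                "label": p.label,
                "initial_tokens": p.initial_tokens,
                "contained": list(p.contained),
                "references": list(p.references),
            }
            for p in sorted(net.places.values(), key=lambda p: p.id)
        ],
        "transitions": [
            {
                "id": t.id,
                "label": t.label,
                "rate_constant": t.rate_constant,
                "references": list(t.references),
                "nested": net_to_payload(t.nested) if t.nested is not None else None,
            }
            for t in sorted(net.transitions.values(), key=lambda t: t.id)
        ],
        "arcs": sorted(
            (
                {"source": a.source, "target": a.target, "multiplicity": a.multiplicity}
                for a in net.arcs
            ),
            key=lambda d: (d["source"], d["target"]),
        ),
    }


def payload_to_net(payload: dict, path: str = "/payload") -> PetriNet:
    if not isinstance(payload, dict):
        raise SchemaError("net payload must be an object", path=path)
    net = PetriNet(
        name=str(payload.get("name", "")),
        description=str(payload.get("description", "")),
    )
    for k, raw in enumerate(payload.get("places", [])):
        if not isinstance(raw, dict) or "id" not in raw:
            raise SchemaError("place must be an object with an id", path=f"{path}/places/{k}")
        tokens = raw.get("initial_tokens", 0)
        if not isinstance(tokens, int) or isinstance(tokens, bool) or tokens < 0:
            raise SchemaError(
                "initial_tokens must be an integer >= 0",
                path=f"{path}/places/{k}/initial_tokens",
            )
        net.places[raw["id"]] = Place(
            id=raw["id"],
            label=str(raw.get("label", "")),
            initial_tokens=tokens,
            contained=[str(c) for c in raw.get("contained", [])],
            references=[str(r) for r in raw.get("references", [])],
        )
    for k, raw in enumerate(payload.get("transitions", [])):
        if not isinstance(raw, dict) or "id" not in raw:
            raise SchemaError(
                "transition must be an object with an id",
                path=f"{path}/transitions/{k}",
            )
        nested = raw.get("nested")
        net.transitions[raw["id"]] = Transition(
            id=raw["id"],
            label=str(raw.get("label", "")),
            rate_constant=float(raw.get("rate_constant", 1.0)),
            references=[str(r) for r in raw.get("references", [])],
            nested=payload_to_net(nested, f"{path}/transitions/{k}/nested")
            if nested is not None else None,
        )
    for k, raw in enumerate(payload.get("arcs", [])):
        if not isinstance(raw, dict) or "source" not in raw or "target" not in raw:
            raise SchemaError(
                "arc must be an object with source and target",
                path=f"{path}/arcs/{k}",
            )
        mult = raw.get("multiplicity", 1)
        if not isinstance(mult, int) or isinstance(mult, bool) or mult < 1:
            raise SchemaError(
                "multiplicity must be an integer >= 1",
                path=f"{path}/arcs/{k}/multiplicity",
            )
        net.arcs.append(Arc(raw["source"], raw["target"], mult))
    problems = net_validate(net)
    if problems:
        raise ValidationError("document decodes to an invalid net: " + "; ".join(problems))
    return net


def write_project_json(document: ProjectDocument) -> str:
    """Canonical serialization: sorted keys, 2-space indent, trailing newline."""
    if document.project_kind == "graph":
        payload = graph_to_payload(document.payload)
    else:
        payload = net_to_payload(document.payload)
    doc = dict(document.extra)
    doc.update({
        "format_version": PROJECT_FORMAT_VERSION,
        "project_kind": document.project_kind,
        "name": document.name,
        "description": document.description,
        "payload": payload,
    })
    return json.dumps(doc, indent=2, sort_keys=True, ensure_ascii=False) + "\n"


def read_project_json(text: str) -> ProjectDocument:
    if not text.strip():
        raise EmptyInputError("empty project document")
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError(f"not valid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise SchemaError("top level must be an object", path="/")
    version = doc.get("format_version")
    if not isinstance(version, str):
        raise SchemaError("missing or non-string format_version", path="/format_version")
    if version.split(".")[0] != PROJECT_FORMAT_VERSION.split(".")[0]:
        raise UnsupportedVersionError(
            f"format_version {version!r} not supported "
            f"(this library reads {PROJECT_FORMAT_VERSION})",
            path="/format_version",
        )
    kind = doc.get("project_kind")
    if kind not in ("graph", "petri_net"):
        raise SchemaError(
            f"project_kind must be 'graph' or 'petri_net', got {kind!r}",
            path="/project_kind",
        )
    if "payload" not in doc:
        raise SchemaError("missing payload", path="/payload")
    if kind == "graph":
        payload = payload_to_graph(doc["payload"])
    else:
        payload = payload_to_net(doc["payload"])
    extra = {
        k: v for k, v in doc.items()
        if k not in ("format_version", "project_kind", "name", "description", "payload")
    }
    return ProjectDocument(
        payload,
        name=str(doc.get("name", "")),
        description=str(doc.get("description", "")),
        extra=extra,
    )
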