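"""Serialization of weighted undirected networks.

Supported formats:

* GraphML (the graphml.graphdrawing.org schema subset with typed
  ``<key>``/``<data>`` attributes) — the toolkit's native format;
* R ``write.table``-dialect adjacency tables (tab-separated, quoted header
  of column names, each row = quoted row name + values);
* plain edge-list TSV.

Networks are held in memory as :class:`networkx.Graph` objects whose edges
carry a float ``weight`` attribute and whose nodes may carry arbitrary
string attributes.  Writers are deterministic: nodes and edges are emitted
in sorted order, so writing the same network twice yields identical bytes.
Weights are printed with Python's shortest round-trip ``repr`` so reads
recover them exactly at double precision.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from lxml import etree

from .errors import InvalidDataError, NetworkFormatError

logger = logging.getLogger(__name__)

GRAPHML_NS = "http://graphml.graphdrawing.org/xmlns"

__all__ = [
    "AnnotationTable",
    "read_graphml",
    "write_graphml",
    "read_adjacency_table",
    "write_adjacency_table",
    "export_edge_list",
    "read_edge_list",
    "read_annotation_table",
    "attach_annotations",
    "validate_network",
]


def validate_network(g: nx.Graph) -> nx.Graph:
    """Check the undirected-network invariants: no self-loops, finite
    nonnegative weights."""
    if g.is_directed():
        raise InvalidDataError("network must be undirected")
    for u, v, data in g.edges(data=True):
        if u == v:
            raise InvalidDataError(f"self-loop on node {u!r}")
        w = data.get("weight", 1.0)
        if not np.isfinite(w) or w < 0:
            raise InvalidDataError(f"edge {u!r}-{v!r} has invalid weight {w!r}")
    return g


def _canonical_edges(g: nx.Graph):
    """Edges as sorted (u, v, weight) triples with u < v, in lexicographic order."""
    out = []
    for u, v, data in g.edges(data=True):
        a, b = sorted((str(u), str(v)))
        out.append((a, b, float(data.get("weight", 1.0))))
    out.sort()
    return out


# ---------------------------------------------------------------------------
# GraphML
# ---------------------------------------------------------------------------

def write_graphml(g: nx.Graph, path) -> None:
    """Write a network as GraphML with ``edgedefault="undirected"``.

    Edge weights go to a double-typed key named ``weight``; every other
    node/edge attribute is emitted as a string-typed key.  Output is
    byte-stable for a given network.
    """
    validate_network(g)
    nsmap = {None: GRAPHML_NS}
    root = etree.Element(f"{{{GRAPHML_NS}}}graphml", nsmap=nsmap)

    node_attr_names = sorted({k for _, d in g.nodes(data=True) for k in d})
    edge_attr_names = sorted(
        {k for _, _, d in g.edges(data=True) for k in d if k != "weight"}
    )
    key_ids: dict[tuple[str, str], str] = {}
    counter = 0

    def declare(domain: str, name: str, attr_type: str) -> str:
        nonlocal counter
        kid = f"d{counter}"
        counter += 1
        el = etree.SubElement(root, f"{{{GRAPHML_NS}}}key", id=kid)
        el.set("for", domain)
        el.set("attr.name", name)
        el.set("attr.type", attr_type)
        key_ids[(domain, name)] = kid
        return kid

    weight_key = declare("edge", "weight", "double")
    for name in node_attr_names:
        declare("node", name, "string")
    for name in edge_attr_names:
        declare("edge", name, "string")

    graph_el = etree.SubElement(
        root, f"{{{GRAPHML_NS}}}graph", id="G", edgedefault="undirected"
    )
    for node in sorted(g.nodes, key=str):
        n_el = etree.SubElement(graph_el, f"{{{GRAPHML_NS}}}node", id=str(node))
        attrs = g.nodes[node]
        for name in sorted(attrs):
            d_el = etree.SubElement(
                n_el, f"{{{GRAPHML_NS}}}data", key=key_ids[("node", name)]
            )
            d_el.text = str(attrs[name])
    for u, v, w in _canonical_edges(g):
        e_el = etree.SubElement(
            graph_el, f"{{{GRAPHML_NS}}}edge", source=u, target=v
        )
        d_el = etree.SubElement(e_el, f"{{{GRAPHML_NS}}}data", key=weight_key)
        d_el.text = repr(w)
        extra = g.edges[u, v]
        for name in sorted(k for k in extra if k != "weight"):
            x_el = etree.SubElement(
                e_el, f"{{{GRAPHML_NS}}}data", key=key_ids[("edge", name)]
            )
            x_el.text = str(extra[name])

    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True)


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def read_graphml(path) -> nx.Graph:
    """Parse a GraphML file into an undirected weighted network.

    The edge-weight key is the one whose ``attr.name`` is ``weight``
    (case-insensitive) with type double, else the first double-typed edge
    key in document order; edges without weight data default to 1.0 (or the
    key's declared ``<default>``).  All other keys are preserved as string
    node/edge attributes.  Directed files are folded to undirected, keeping
    the maximum weight when both directions of a pair occur.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise NetworkFormatError(f"malformed GraphML XML: {exc}") from exc
    root = tree.getroot()
    if _local(root.tag) != "graphml":
        raise NetworkFormatError("root element is not <graphml>")

    keys: dict[str, dict] = {}
    weight_key_id = None
    first_double_edge_key = None
    for el in root:
        if _local(el.tag) != "key":
            continue
        kid = el.get("id")
        info = {
            "for": el.get("for", "all"),
            "name": el.get("attr.name", kid),
            "type": el.get("attr.type", "string"),
            "default": None,
        }
        for child in el:
            if _local(child.tag) == "default":
                info["default"] = child.text
        keys[kid] = info
        if info["for"] in ("edge", "all") and info["type"] in ("double", "float"):
            if info["name"].lower() == "weight" and weight_key_id is None:
                weight_key_id = kid
            if first_double_edge_key is None:
                first_double_edge_key = kid
    if weight_key_id is None:
        weight_key_id = first_double_edge_key

    graph_el = next((el for el in root if _local(el.tag) == "graph"), None)
    if graph_el is None:
        raise NetworkFormatError("no <graph> element found")

    g = nx.Graph()
    for el in graph_el:
        if _local(el.tag) != "node":
            continue
        nid = el.get("id")
        attrs = {}
        for d in el:
            if _local(d.tag) != "data":
                continue
            kid = d.get("key")
            if kid == weight_key_id:
                continue
            name = keys.get(kid, {}).get("name", kid)
            attrs[name] = d.text or ""
        g.add_node(nid, **attrs)

    default_weight = 1.0
    if weight_key_id is not None and keys[weight_key_id]["default"] is not None:
        default_weight = float(keys[weight_key_id]["default"])

    for el in graph_el:
        if _local(el.tag) != "edge":
            continue
        u, v = el.get("source"), el.get("target")
        if u not in g or v not in g:
            missing = u if u not in g else v
            raise NetworkFormatError(f"edge endpoint {missing!r} is not a declared node")
        if u == v:
            logger.warning("dropping self-loop on node %r", u)
            continue
        weight = default_weight
        attrs = {}
        for d in el:
            if _local(d.tag) != "data":
                continue
            kid = d.get("key")
            if kid == weight_key_id:
                weight = float(d.text)
            else:
                name = keys.get(kid, {}).get("name", kid)
                attrs[name] = d.text or ""
        if g.has_edge(u, v):  # directed pair folded to undirected: keep max
            weight = max(weight, g.edges[u, v]["weight"])
        g.add_edge(u, v, weight=weight, **attrs)
    return validate_network(g)


# ---------------------------------------------------------------------------
# R-dialect adjacency tables
# ---------------------------------------------------------------------------

def write_adjacency_table(g: nx.Graph, path) -> None:
    """Write the full symmetric adjacency matrix in the R ``write.table``
    dialect: tab-separated, quoted header of column names, each row a
    quoted row name followed by the weights."""
    validate_network(g)
    ids = sorted(map(str, g.nodes))
    index = {n: i for i, n in enumerate(ids)}
    m = np.zeros((len(ids), len(ids)))
    for u, v, w in _canonical_edges(g):
        m[index[u], index[v]] = m[index[v], index[u]] = w
    with open(path, "w") as fh:
        fh.write("\t".join(f'"{c}"' for c in ids) + "\n")
        for i, rid in enumerate(ids):
            fh.write(f'"{rid}"\t' + "\t".join(repr(float(x)) for x in m[i]) + "\n")


def read_adjacency_table(path) -> nx.Graph:
    """Read a labeled square adjacency matrix (quoted or unquoted R-style
    names accepted); strictly positive entries become edges.

    The matrix must be symmetric to 1e-9; an asymmetric matrix is
    symmetrized entrywise by the maximum, with a warning.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    except Exception as exc:
        raise NetworkFormatError(f"cannot parse adjacency table: {exc}") from exc
    if df.shape[0] != df.shape[1]:
        raise NetworkFormatError(
            f"adjacency table must be square, got {df.shape[0]}x{df.shape[1]}"
        )
    rows = [str(i) for i in df.index]
    cols = [str(c) for c in df.columns]
    if rows != cols:
        raise NetworkFormatError("row labels differ from column labels")
    m = df.to_numpy(dtype=float)
    if not np.allclose(m, m.T, atol=1e-9):
        warnings.warn(
            "adjacency table is asymmetric; symmetrizing entrywise by max",
            stacklevel=2,
        )
        m = np.maximum(m, m.T)
    g = nx.Graph()
    g.add_nodes_from(rows)
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            if m[i, j] > 0:
                g.add_edge(rows[i], rows[j], weight=float(m[i, j]))
    return validate_network(g)


# ---------------------------------------------------------------------------
# edge lists
# ---------------------------------------------------------------------------

def export_edge_list(g: nx.Graph, path) -> None:
    """TSV of source / target / weight, lexicographically sorted.

    Lossless for topology and weights; node attributes are not written, and
    isolated nodes do not appear.
    """
    validate_network(g)
    with open(path, "w") as fh:
        fh.write("source\ttarget\tweight\n")
        for u, v, w in _canonical_edges(g):
            fh.write(f"{u}\t{v}\t{repr(w)}\n")


def read_edge_list(path) -> nx.Graph:
    g = nx.Graph()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["source", "target", "weight"]:
            raise NetworkFormatError("edge list must start with source/target/weight header")
        for line in fh:
            if not line.strip():
                continue
            u, v, w = line.rstrip("\n").split("\t")[:3]
            g.add_edge(u, v, weight=float(w))
    return validate_network(g)


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

@dataclass
class AnnotationTable:
    """Local annotation table: probeset id -> named attribute values
    (gene symbol, Entrez, Ensembl, ... as provided)."""

    rows: dict[str, dict[str, str]]

    def __post_init__(self) -> None:
        for pid, attrs in self.rows.items():
            if not pid:
                raise NetworkFormatError("empty probeset id in annotation table")


def read_annotation_table(path) -> AnnotationTable:
    """Read a TSV whose first column is the probeset id and remaining
    columns are attributes.  Duplicate probeset rows are a format error."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    id_col = df.columns[0]
    if df[id_col].duplicated().any():
        dup = df[id_col][df[id_col].duplicated()].iloc[0]
        raise NetworkFormatError(f"duplicate probeset id {dup!r} in annotation table")
    rows = {
        str(rec[id_col]): {c: str(rec[c]) for c in df.columns[1:]}
        for rec in df.to_dict("records")
    }
    return AnnotationTable(rows=rows)


def attach_annotations(g: nx.Graph, table: AnnotationTable) -> tuple[nx.Graph, int]:
    """Merge annotation attributes into matching nodes.

    Returns the annotated network and the number of nodes that matched a
    table row; unmatched nodes (and table rows without a node) are left
    untouched.
    """
    out = g.copy()
    matched = 0
    for pid, attrs in table.rows.items():
        if pid in out:
            out.nodes[pid].update(attrs)
            matched += 1
    logger.info("annotations matched %d of %d nodes", matched, out.number_of_nodes())
    return out, matched


def guess_read(path) -> nx.Graph:
    """Dispatch on file extension: .graphml -> GraphML, .edges/.edgelist TSV
    -> edge list, anything else -> adjacency table."""
    p = str(path)
    if p.endswith(".graphml"):
        return read_graphml(p)
    if p.endswith((".edges", ".edges.tsv", ".edgelist")):
        return read_edge_list(p)
    return read_adjacency_table(p)
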