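"""Read and write networks in Cytoscape JSON, edge-list, GraphML, and a
native pickled-graph format.

The edge-list dialect: whitespace- or tab-delimited; ``#`` starts a
comment; two tokens are an edge, three tokens add a float weight, and a
single token declares an isolated node (needed so edge lists round-trip
graphs with isolated nodes).

The native format (``.gpickle``) is a pickled networkx graph and is
documented as non-portable across library versions.
"""

from __future__ import annotations

import json
import pickle
from pathlib import Path

import networkx as nx

from .network import Network, NetworkValidationError

__all__ = ["read_network", "write_network", "FormatError"]

_EXT_FMT = {
    ".cyjs": "cyjs",
    ".graphml": "graphml",
    ".gpickle": "native",
    ".pkl": "native",
    ".edgelist": "edgelist",
    ".tsv": "edgelist",
    ".csv": "edgelist",
    ".txt": "edgelist",
}


class FormatError(ValueError):
    """Unparseable input; the message names the first offending record."""


def _sniff(path: Path) -> str:
    try:
        head = path.read_bytes()[:256]
    except OSError as e:
        raise FormatError(f"cannot read {path}: {e}") from e
    stripped = head.lstrip()
    if stripped.startswith(b"{"):
        return "cyjs"
    if stripped.startswith(b"<"):
        return "graphml"
    if head.startswith(b"\x80"):  # pickle protocol marker
        return "native"
    return "edgelist"


def _resolve_fmt(path: Path, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    if path.suffix.lower() == ".json":
        return "cyjs"
    return _EXT_FMT.get(path.suffix.lower()) or _sniff(path)


# ----------------------------------------------------------------------
# readers


def _read_edgelist(path: Path) -> Network:
    nodes: set[str] = set()
    edges: list[tuple] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tok = line.split()
        if len(tok) == 1:
            nodes.add(tok[0])
        elif len(tok) == 2:
            nodes.update(tok)
            edges.append((tok[0], tok[1]))
        elif len(tok) == 3:
            try:
                w = float(tok[2])
            except ValueError as e:
                raise FormatError(
                    f"{path}:{lineno}: bad weight {tok[2]!r} in line {raw!r}"
                ) from e
            nodes.update(tok[:2])
            edges.append((tok[0], tok[1], w))
        else:
            raise FormatError(f"{path}:{lineno}: expected 1-3 fields, got {raw!r}")
    if not nodes:
        raise FormatError(f"{path}: empty edge list")
    return Network.build(nodes, edges)


def _read_cyjs(path: Path) -> Network:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"{path}: invalid JSON at line {e.lineno}: {e.msg}") from e
    elements = doc.get("elements", doc)
    if isinstance(elements, list):  # flat elements array dialect
        node_els = [e for e in elements if "source" not in e.get("data", {})]
        edge_els = [e for e in elements if "source" in e.get("data", {})]
    else:
        node_els = elements.get("nodes", [])
        edge_els = elements.get("edges", [])
    if not node_els:
        raise FormatError(f"{path}: no nodes in Cytoscape JSON document")

    nodes, coords, labels = [], {}, {}
    for el in node_els:
        data = el.get("data", {})
        if "id" not in data:
            raise FormatError(f"{path}: node element without data.id: {el!r}")
        nid = str(data["id"])
        nodes.append(nid)
        if "position" in el and el["position"] is not None:
            pos = el["position"]
            coords[nid] = (float(pos["x"]), float(pos["y"]))
        if "name" in data:
            labels[nid] = str(data["name"])
    edges = []
    for el in edge_els:
        data = el.get("data", {})
        if "source" not in data or "target" not in data:
            raise FormatError(f"{path}: edge element without source/target: {el!r}")
        e = (str(data["source"]), str(data["target"]))
        if "weight" in data:
            e = (*e, float(data["weight"]))
        edges.append(e)
    use_coords = coords if len(coords) == len(set(nodes)) else None
    return Network.build(nodes, edges, use_coords, labels or None)


def _read_graphml(path: Path) -> Network:
    try:
        g = nx.read_graphml(path)
    except Exception as e:  # lxml/expat raise various types
        raise FormatError(f"{path}: invalid GraphML: {e}") from e
    return Network.from_networkx(g)


def _read_native(path: Path) -> Network:
    with open(path, "rb") as fh:
        obj = pickle.load(fh)
    if isinstance(obj, Network):
        return obj
    if isinstance(obj, (nx.Graph, nx.DiGraph, nx.MultiGraph, nx.MultiDiGraph)):
        return Network.from_networkx(obj)
    raise FormatError(f"{path}: pickled object is not a graph ({type(obj).__name__})")


def read_network(path, fmt: str = "auto") -> Network:
    """Read a network file into a canonical :class:`Network`.

    ``fmt`` is one of ``cyjs``, ``edgelist``, ``graphml``, ``native`` or
    ``auto`` (extension, then content sniffing). Directed inputs are
    symmetrized; isolated nodes are retained.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _resolve_fmt(path, fmt)
    readers = {
        "cyjs": _read_cyjs,
        "edgelist": _read_edgelist,
        "graphml": _read_graphml,
        "native": _read_native,
    }
    if fmt not in readers:
        raise ValueError(f"unknown network format {fmt!r}")
    return readers[fmt](path)


# ----------------------------------------------------------------------
# writers


def _write_edgelist(net: Network, path: Path) -> None:
    lines = []
    touched = set()
    for (u, v), w in sorted(net.edges.items()):
        touched.update((u, v))
        lines.append(f"{u}\t{v}" if w == 1.0 else f"{u}\t{v}\t{w!r}")
    for v in net.nodes:
        if v not in touched:
            lines.append(v)
    path.write_text("\n".join(lines) + "\n")


def _write_cyjs(net: Network, path: Path) -> None:
    node_els = []
    for v in net.nodes:
        el: dict = {"data": {"id": v}}
        if net.labels and v in net.labels:
            el["data"]["name"] = net.labels[v]
        if net.coords:
            x, y = net.coords[v]
            el["position"] = {"x": x, "y": y}
        node_els.append(el)
    edge_els = [
        {"data": {"source": u, "target": v, "weight": w}}
        for (u, v), w in sorted(net.edges.items())
    ]
    doc = {"elements": {"nodes": node_els, "edges": edge_els}}
    path.write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def _write_graphml(net: Network, path: Path) -> None:
    nx.write_graphml(net.to_networkx(), path)


def _write_native(net: Network, path: Path) -> None:
    with open(path, "wb") as fh:
        pickle.dump(net, fh)


def write_network(net: Network, path, fmt: str = "auto") -> None:
    """Write ``net`` so that ``read_network(path, fmt)`` round-trips the
    node set, edge set, weights, and (for cyjs/graphml/native) coords."""
    path = Path(path)
    fmt = _resolve_fmt(path, fmt)
    writers = {
        "cyjs": _write_cyjs,
        "edgelist": _write_edgelist,
        "graphml": _write_graphml,
        "native": _write_native,
    }
    if fmt not in writers:
        raise ValueError(f"unsupported write format {fmt!r}")
    writers[fmt](net, path)
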