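"""Readers and writers for neuron tracings and specimen metadata.

Two plain-text morphology formats are supported:

* SWC — the standard 7-column interchange format (id, type, x, y, z,
  radius, parent), one node per line, ``#`` comments;
* Amira SpatialGraph ASCII — the export format of interactive tracing in
  Amira: VERTEX / EDGE / POINT sections where each edge carries a polyline
  of intermediate points.  Only the ASCII dialect is read; binary files
  are rejected with a clear message.

Multi-point soma contours are collapsed to their centroid on read, since
every metric centres on a single soma point.  Specimen identity (cohort,
region, hemisphere, layer, index) is recovered from filenames through a
configurable ordered-token convention, defaulting to
``COHORT_REGION_HEMI_LAYER_INDEX`` (e.g. ``AD06_CA1_L_L1_003.swc``).
"""

from __future__ import annotations

import io
import logging
import os
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO

import numpy as np
import pandas as pd

from .errors import MetadataError, ParseError, StructureError
from .model import (
    DEFAULT_COHORTS,
    DEFAULT_REGIONS,
    DENDRITE,
    SOMA,
    UNDEFINED,
    NeuronNode,
    NeuronTree,
    Point3,
    SpecimenMeta,
    require_valid,
    validate_tree,
)

logger = logging.getLogger(__name__)

SWC_SOMA = 1
SWC_BASAL_DENDRITE = 3
_KIND_TO_SWC = {SOMA: SWC_SOMA, DENDRITE: SWC_BASAL_DENDRITE, UNDEFINED: 0}
DEFAULT_RADIUS_UM = 1.0  # written when a node has no radius


def _as_text_stream(source: str | os.PathLike | TextIO) -> tuple[TextIO, bool]:
    if isinstance(source, (str, os.PathLike)):
        return open(source, "r"), True
    return source, False


# ---------------------------------------------------------------------------
# SWC
# ---------------------------------------------------------------------------

def read_swc(source: str | os.PathLike | TextIO,
             metadata: SpecimenMeta | None = None) -> NeuronTree:
    """Parse an SWC stream or file into a :class:`NeuronTree`.

    SWC type 1 maps to soma, every other type to dendrite.  A contiguous
    cluster of soma records rooted at the file's root is collapsed to its
    centroid.  Raises :class:`ParseError` with a line number on malformed
    lines and :class:`StructureError` on multiple roots or dangling
    parents.
    """
    stream, close = _as_text_stream(source)
    records: dict[int, tuple[int, float, float, float, float, int]] = {}
    try:
        for lineno, raw in enumerate(stream, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise ParseError(f"expected 7 columns, got {len(parts)}", lineno)
            try:
                nid = int(parts[0])
                type_code = int(parts[1])
                x, y, z, radius = (float(v) for v in parts[2:6])
                parent = int(parts[6])
            except ValueError as exc:
                raise ParseError(f"unparsable field ({exc})", lineno) from None
            if nid <= 0:
                raise ParseError(f"non-positive node id {nid}", lineno)
            if nid in records:
                raise ParseError(f"duplicate node id {nid}", lineno)
            records[nid] = (type_code, x, y, z, radius, parent)
    finally:
        if close:
            stream.close()

    if not records:
        raise ParseError("no records in SWC input")

    roots = [nid for nid, rec in records.items() if rec[5] == -1]
    if len(roots) != 1:
        raise StructureError(
            f"expected exactly one root record (parent -1), found {len(roots)}"
        )
    for nid, rec in records.items():
        if rec[5] != -1 and rec[5] not in records:
            raise StructureError(f"node {nid} references missing parent {rec[5]}")

    return _assemble_tree(records, roots[0], metadata)


def _assemble_tree(records, root_id: int,
                   metadata: SpecimenMeta | None) -> NeuronTree:
    """Collapse the soma cluster and build the tree."""
    children: dict[int, list[int]] = {nid: [] for nid in records}
    for nid, rec in records.items():
        if rec[5] != -1:
            children[rec[5]].append(nid)

    # soma cluster: root plus type-1 records reachable from it through
    # type-1 records only
    cluster = {root_id}
    if records[root_id][0] == SWC_SOMA:
        stack = [root_id]
        while stack:
            cur = stack.pop()
            for ch in children[cur]:
                if records[ch][0] == SWC_SOMA and ch not in cluster:
                    cluster.add(ch)
                    stack.append(ch)
    else:
        logger.warning("root record %d has SWC type %d; treating it as the soma",
                       root_id, records[root_id][0])
    if len(cluster) > 1:
        logger.warning("collapsing %d-point soma contour to its centroid", len(cluster))

    cluster_pos = np.array([[records[c][1], records[c][2], records[c][3]]
                            for c in cluster])
    centroid = Point3.of(cluster_pos.mean(axis=0))
    radius = float(np.mean([records[c][4] for c in cluster]))

    nodes = [NeuronNode(id=root_id, position=centroid, radius=radius,
                        kind=SOMA, parent_id=None)]
    for nid, rec in records.items():
        if nid in cluster:
            continue
        parent = root_id if rec[5] in cluster else rec[5]
        nodes.append(NeuronNode(
            id=nid,
            position=Point3(rec[1], rec[2], rec[3]),
            radius=rec[4],
            kind=DENDRITE,
            parent_id=parent,
        ))
    tree = NeuronTree(nodes, soma_id=root_id, metadata=metadata)
    violations = validate_tree(tree)
    if violations:
        raise StructureError("; ".join(violations))
    return tree


def write_swc(tree: NeuronTree, sink: str | os.PathLike | TextIO) -> None:
    """Write a valid tree as SWC, parents before children, ids relabelled
    1..N in traversal order.  Unset radii are written as 1.0."""
    require_valid(tree)
    children = tree.children_map()
    lines = ["# id type x y z radius parent"]
    new_id: dict[int, int] = {}
    stack = [tree.soma_id]
    while stack:
        nid = stack.pop()
        node = tree.nodes[nid]
        new_id[nid] = len(new_id) + 1
        parent = new_id[node.parent_id] if node.parent_id is not None else -1
        radius = node.radius if node.radius is not None else DEFAULT_RADIUS_UM
        p = node.position
        # repr() gives the shortest exactly round-tripping decimal form
        lines.append(
            f"{new_id[nid]} {_KIND_TO_SWC.get(node.kind, 0)} "
            f"{p.x!r} {p.y!r} {p.z!r} {radius!r} {parent}"
        )
        stack.extend(reversed(children[nid]))
    text = "\n".join(lines) + "\n"
    if isinstance(sink, (str, os.PathLike)):
        Path(sink).write_text(text)
    else:
        sink.write(text)


# ---------------------------------------------------------------------------
# Amira SpatialGraph ASCII
# ---------------------------------------------------------------------------

_AMIRA_FIELDS = {
    "VertexCoordinates": "vertices",
    "EdgeConnectivity": "connectivity",
    "NumEdgePoints": "num_points",
    "EdgePointCoordinates": "points",
}


def read_amira_spatialgraph(source: str | os.PathLike | TextIO,
                            soma_vertex: int | None = None,
                            metadata: SpecimenMeta | None = None) -> NeuronTree:
    """Parse an ASCII Amira SpatialGraph into a rooted tree.

    Edges' interior points become chain nodes; consecutive duplicate
    coordinates (edge point lists commonly repeat their endpoint vertices)
    are merged.  The root is vertex 0 unless ``soma_vertex`` designates
    another vertex.  Binary AmiraMesh files raise :class:`ParseError`;
    a disconnected graph raises :class:`StructureError` listing components.
    """
    stream, close = _as_text_stream(source)
    try:
        text = stream.read()
    finally:
        if close:
            stream.close()

    header = text.splitlines()[0] if text else ""
    if "AmiraMesh" not in header:
        raise ParseError("not an AmiraMesh file (missing header)", 1)
    if "ASCII" not in header:
        dialect = "binary" if "BINARY" in header.upper() else "unknown"
        raise ParseError(
            f"unsupported AmiraMesh dialect ({dialect}); only '3D ASCII' is readable", 1
        )

    marker_of: dict[str, str] = {}
    for name, key in _AMIRA_FIELDS.items():
        m = re.search(rf"\b{name}\b[^@]*@(\d+)", text)
        if m:
            marker_of[key] = m.group(1)
    missing = [k for k in _AMIRA_FIELDS.values() if k not in marker_of]
    if missing:
        raise ParseError(f"SpatialGraph sections missing: {', '.join(sorted(missing))}")

    # data blocks: "@k" on its own line, then whitespace-separated numbers
    blocks: dict[str, list[float]] = {}
    current: str | None = None
    for line in text.splitlines():
        stripped = line.strip()
        m = re.fullmatch(r"@(\d+)", stripped)
        if m:
            current = m.group(1)
            blocks[current] = []
            continue
        if current is not None and stripped and not stripped.startswith("#"):
            try:
                blocks[current].extend(float(v) for v in stripped.split())
            except ValueError:
                current = None  # left the data section (e.g. trailing metadata)

    def block(key: str) -> np.ndarray:
        marker = marker_of[key]
        if marker not in blocks:
            raise ParseError(f"data block @{marker} ({key}) not found")
        return np.asarray(blocks[marker], dtype=float)

    vertices = block("vertices").reshape(-1, 3)
    connectivity = block("connectivity").astype(int).reshape(-1, 2)
    num_points = block("num_points").astype(int)
    points = block("points").reshape(-1, 3)
    if len(num_points) != len(connectivity):
        raise ParseError("NumEdgePoints length does not match EdgeConnectivity")
    if num_points.sum() != len(points):
        raise ParseError("EdgePointCoordinates length does not match NumEdgePoints")

    root_vertex = soma_vertex if soma_vertex is not None else 0
    if not (0 <= root_vertex < len(vertices)):
        raise ParseError(f"soma vertex {root_vertex} out of range")

    # per-edge point slices
    offsets = np.concatenate([[0], np.cumsum(num_points)])
    adjacency: dict[int, list[int]] = {v: [] for v in range(len(vertices))}
    for e, (u, v) in enumerate(connectivity):
        adjacency[int(u)].append(e)
        adjacency[int(v)].append(e)

    nodes: list[NeuronNode] = [NeuronNode(
        id=1, position=Point3.of(vertices[root_vertex]), kind=SOMA, parent_id=None)]
    vertex_node: dict[int, int] = {root_vertex: 1}
    visited_edges: set[int] = set()
    stack = [root_vertex]
    while stack:
        u = stack.pop()
        for e in adjacency[u]:
            if e in visited_edges:
                continue
            visited_edges.add(e)
            eu, ev = (int(c) for c in connectivity[e])
            v = ev if eu == u else eu
            plist = points[offsets[e]:offsets[e + 1]]
            if len(plist) and eu != u:
                plist = plist[::-1]
            cur_id = vertex_node[u]
            cur_pos = nodes[cur_id - 1].position
            chain = list(plist) + [vertices[v]]
            for p in chain:
                pt = Point3.of(p)
                if pt == cur_pos:
                    continue
                nodes.append(NeuronNode(id=len(nodes) + 1, position=pt,
                                        kind=DENDRITE, parent_id=cur_id))
                cur_id = len(nodes)
                cur_pos = pt
            if v not in vertex_node:
                vertex_node[v] = cur_id
                stack.append(v)
            elif v != u and vertex_node[v] != cur_id:
                raise StructureError(
                    f"graph contains a cycle through vertices {u} and {v}"
                )

    unreached = sorted(set(range(len(vertices))) - set(vertex_node))
    if unreached:
        raise StructureError(
            f"disconnected SpatialGraph: {len(unreached)} vertex/vertices "
            f"unreachable from root {root_vertex}: {unreached}"
        )
    tree = NeuronTree(nodes, soma_id=1, metadata=metadata)
    violations = validate_tree(tree)
    if violations:
        raise StructureError("; ".join(violations))
    return tree


def write_amira_spatialgraph(tree: NeuronTree, sink: str | os.PathLike | TextIO) -> None:
    """Write a tree as a minimal ASCII SpatialGraph: branch points, the soma
    and leaves become vertices; chains between them become edge point lists
    (endpoints repeated, as Amira exports do)."""
    require_valid(tree)
    children = tree.children_map()
    is_vertex = {nid: (nid == tree.soma_id or len(chs) != 1)
                 for nid, chs in children.items()}
    vertex_ids = [nid for nid in _preorder(tree, children) if is_vertex[nid]]
    vertex_index = {nid: i for i, nid in enumerate(vertex_ids)}

    edges: list[tuple[int, int, list[Point3]]] = []
    for start in vertex_ids:
        for ch in children[start]:
            chain = [tree.nodes[start].position]
            cur = ch
            while not is_vertex[cur]:
                chain.append(tree.nodes[cur].position)
                cur = children[cur][0]
            chain.append(tree.nodes[cur].position)
            edges.append((vertex_index[start], vertex_index[cur], chain))

    out = io.StringIO()
    out.write("# AmiraMesh 3D ASCII 2.0\n\n")
    out.write(f"define VERTEX {len(vertex_ids)}\n")
    out.write(f"define EDGE {len(edges)}\n")
    out.write(f"define POINT {sum(len(c) for _, _, c in edges)}\n\n")
    out.write('Parameters {\n    ContentType "HxSpatialGraph"\n}\n\n')
    out.write("VERTEX { float[3] VertexCoordinates } @1\n")
    out.write("EDGE { int[2] EdgeConnectivity } @2\n")
    out.write("EDGE { int NumEdgePoints } @3\n")
    out.write("POINT { float[3] EdgePointCoordinates } @4\n\n")
    out.write("@1\n")
    for nid in vertex_ids:
        p = tree.nodes[nid].position
        out.write(f"{p.x!r} {p.y!r} {p.z!r}\n")
    out.write("\n@2\n")
    for u, v, _ in edges:
        out.write(f"{u} {v}\n")
    out.write("\n@3\n")
    for _, _, chain in edges:
        out.write(f"{len(chain)}\n")
    out.write("\n@4\n")
    for _, _, chain in edges:
        for p in chain:
            out.write(f"{p.x!r} {p.y!r} {p.z!r}\n")
    text = out.getvalue()
    if isinstance(sink, (str, os.PathLike)):
        Path(sink).write_text(text)
    else:
        sink.write(text)


def _preorder(tree: NeuronTree, children: dict[int, list[int]]) -> list[int]:
    order, stack = [], [tree.soma_id]
    while stack:
        nid = stack.pop()
        order.append(nid)
        stack.extend(reversed(children[nid]))
    return order


# ---------------------------------------------------------------------------
# Filename metadata
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NamingConvention:
    """Ordered-token filename convention for specimen metadata.

    The default reads ``AD06_CA1_L_L1_003.swc`` as cohort AD06, region CA1,
    left hemisphere, layer L1, neuron 3.  Token order, separator and the
    controlled vocabularies are all configurable.
    """

    tokens: tuple[str, ...] = ("cohort", "region", "hemisphere", "layer", "index")
    separator: str = "_"
    cohorts: tuple[str, ...] = DEFAULT_COHORTS
    regions: tuple[str, ...] = DEFAULT_REGIONS
    hemispheres: tuple[str, ...] = ("L", "R", "unknown")

    def format_name(self, meta: SpecimenMeta, extension: str = ".swc") -> str:
        values = {
            "cohort": meta.cohort,
            "region": meta.region,
            "hemisphere": meta.hemisphere,
            "layer": meta.layer or "L0",
            "index": f"{meta.neuron_index:03d}",
        }
        return self.separator.join(values[t] for t in self.tokens) + extension


DEFAULT_NAMING = NamingConvention()


def parse_specimen_metadata(filename: str | os.PathLike,
                            convention: NamingConvention = DEFAULT_NAMING) -> SpecimenMeta:
    """Recover :class:`SpecimenMeta` from a filename; unknown cohort/region
    tokens are an error, never silently accepted."""
    stem = Path(filename).stem
    parts = stem.split(convention.separator)
    if len(parts) != len(convention.tokens):
        raise MetadataError(
            f"filename {Path(filename).name!r} does not match the expected "
            f"pattern {convention.separator.join(convention.tokens).upper()}"
        )
    fields = dict(zip(convention.tokens, parts))
    if fields["cohort"] not in convention.cohorts:
        raise MetadataError(
            f"unknown cohort {fields['cohort']!r}; expected one of {convention.cohorts}"
        )
    if fields["region"] not in convention.regions:
        raise MetadataError(
            f"unknown region {fields['region']!r}; expected one of {convention.regions}"
        )
    hemi = fields.get("hemisphere", "unknown")
    if hemi not in convention.hemispheres:
        raise MetadataError(
            f"unknown hemisphere {hemi!r}; expected one of {convention.hemispheres}"
        )
    try:
        index = int(fields.get("index", "0"))
    except ValueError:
        raise MetadataError(f"neuron index {fields['index']!r} is not an integer") from None
    return SpecimenMeta(cohort=fields["cohort"], region=fields["region"],
                        hemisphere=hemi, layer=fields.get("layer", ""),
                        neuron_index=index)


# ---------------------------------------------------------------------------
# Metadata tables
# ---------------------------------------------------------------------------

METADATA_COLUMNS = ["cohort", "region", "hemisphere", "layer", "index", "path"]


def write_metadata_csv(entries: Iterable[tuple[SpecimenMeta, str]],
                       path: str | os.PathLike) -> None:
    rows = [
        {"cohort": m.cohort, "region": m.region, "hemisphere": m.hemisphere,
         "layer": m.layer, "index": m.neuron_index, "path": p}
        for m, p in entries
    ]
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(path, index=False)


def read_metadata_csv(path: str | os.PathLike) -> list[tuple[SpecimenMeta, str]]:
    df = pd.read_csv(path, dtype={"layer": str})
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise MetadataError(f"metadata CSV missing columns: {sorted(missing)}")
    return [
        (SpecimenMeta(cohort=str(r["cohort"]), region=str(r["region"]),
                      hemisphere=str(r["hemisphere"]),
                      layer="" if pd.isna(r["layer"]) else str(r["layer"]),
                      neuron_index=int(r["index"])), str(r["path"]))
        for r in df.to_dict("records")
    ]
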