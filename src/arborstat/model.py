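"""Rooted-tree representation of a traced neuron.

A reconstructed neuron is a rooted tree of 3D points: the soma (cell body)
is the single root, and dendrites extend from it as chains of tracing
nodes.  All geometry is in micrometres.  Every metric in the package
(dendritic length, terminal count, spatial volume, Sholl profile) is
computed from this skeleton representation; node radii are carried through
I/O but ignored by the metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np

from .errors import StructureError

logger = logging.getLogger(__name__)

#: Controlled vocabularies for specimen metadata.  AD06/AD12 are the 6- and
#: 12-month-old AD-model cohorts; WT is a wild-type reference cohort.
DEFAULT_COHORTS = ("AD06", "AD12", "WT")
#: Prefrontal cortex, primary motor cortex, entorhinal cortex, hippocampal CA1.
DEFAULT_REGIONS = ("PFC", "PMC", "EC", "CA1")

SOMA = "soma"
DENDRITE = "dendrite"
UNDEFINED = "undefined"
_KINDS = (SOMA, DENDRITE, UNDEFINED)


class Point3(NamedTuple):
    """A 3D point in µm."""

    x: float
    y: float
    z: float

    def to_array(self) -> np.ndarray:
        return np.array(self, dtype=float)

    @staticmethod
    def of(xyz: Iterable[float]) -> "Point3":
        x, y, z = xyz
        return Point3(float(x), float(y), float(z))


@dataclass(frozen=True)
class SpecimenMeta:
    """Identity of one traced neuron: cohort, brain region, hemisphere,
    cortical layer label and running neuron index."""

    cohort: str
    region: str
    hemisphere: str = "unknown"  # {L, R, unknown}
    layer: str = ""
    neuron_index: int = 0


@dataclass
class NeuronNode:
    """One tracing point.  ``parent_id is None`` marks the root (soma)."""

    id: int
    position: Point3
    radius: float | None = None
    kind: str = DENDRITE
    parent_id: int | None = None


class Segment(NamedTuple):
    """A straight parent->child edge; the unit of length summation and of
    sphere-crossing tests."""

    a: Point3
    b: Point3
    child_is_terminal: bool

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.subtract(self.b, self.a)))


class NeuronTree:
    """A validated-on-demand rooted tree of :class:`NeuronNode`.

    Nodes are stored by id; ``soma_id`` names the root.  Structural
    invariants (single root, acyclic, connected, ids unique) are checked by
    :func:`validate_tree`, which reports violations rather than raising.
    """

    def __init__(self, nodes: Iterable[NeuronNode], soma_id: int | None = None,
                 metadata: SpecimenMeta | None = None):
        self.nodes: dict[int, NeuronNode] = {}
        for node in nodes:
            if node.id in self.nodes:
                # keep both so validate_tree can report; later one wins lookup
                logger.warning("duplicate node id %d", node.id)
            self.nodes[node.id] = node
        if soma_id is None:
            roots = [n.id for n in self.nodes.values() if n.parent_id is None]
            soma_id = roots[0] if roots else next(iter(self.nodes), 0)
        self.soma_id = soma_id
        self.metadata = metadata
        self._arrays: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None
        # trees are treated as immutable after construction; a successful
        # validation is cached so metric calls do not re-walk the ancestry
        self._validated = False

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_arrays(cls, positions: np.ndarray, parents: np.ndarray,
                    metadata: SpecimenMeta | None = None) -> "NeuronTree":
        """Build a tree from an (N, 3) position array and an (N,) parent-index
        array (-1 for the root; indices are 0-based row numbers).  Node ids
        are assigned 1..N; the root gets kind soma."""
        positions = np.asarray(positions, dtype=float)
        parents = np.asarray(parents, dtype=int)
        nodes = [
            NeuronNode(
                id=i + 1,
                position=Point3.of(positions[i]),
                kind=SOMA if parents[i] < 0 else DENDRITE,
                parent_id=None if parents[i] < 0 else int(parents[i]) + 1,
            )
            for i in range(len(parents))
        ]
        root = int(np.nonzero(parents < 0)[0][0]) + 1 if len(parents) else None
        return cls(nodes, soma_id=root, metadata=metadata)

    def with_metadata(self, metadata: SpecimenMeta) -> "NeuronTree":
        t = NeuronTree.__new__(NeuronTree)
        t.nodes = self.nodes
        t.soma_id = self.soma_id
        t.metadata = metadata
        t._arrays = self._arrays
        t._validated = self._validated
        return t

    # -- basic queries --------------------------------------------------------

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def soma(self) -> NeuronNode:
        return self.nodes[self.soma_id]

    def children_map(self) -> dict[int, list[int]]:
        ch: dict[int, list[int]] = {nid: [] for nid in self.nodes}
        for node in self.nodes.values():
            if node.parent_id is not None and node.parent_id in ch:
                ch[node.parent_id].append(node.id)
        return ch

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (ids (N,), positions (N, 3), parent_index (N,)) with the
        parent given as a row index, -1 for the root.  Cached."""
        if self._arrays is None:
            ids = np.fromiter(self.nodes.keys(), dtype=int, count=len(self.nodes))
            pos = np.array([self.nodes[i].position for i in ids], dtype=float)
            index_of = {int(i): k for k, i in enumerate(ids)}
            par = np.array(
                [index_of.get(self.nodes[i].parent_id, -1)
                 if self.nodes[i].parent_id is not None else -1
                 for i in ids],
                dtype=int,
            )
            self._arrays = (ids, pos, par)
        return self._arrays


def validate_tree(tree: NeuronTree) -> list[str]:
    """Check all structural invariants; return a list of human-readable
    violation descriptions (empty iff the tree is valid).  Diagnostic only:
    never raises on a bad structure."""
    violations: list[str] = []
    if not tree.nodes:
        return ["empty tree: no nodes"]

    roots = [n for n in tree.nodes.values() if n.parent_id is None]
    if len(roots) == 0:
        violations.append("no root: every node has a parent_id")
    elif len(roots) > 1:
        violations.append(
            "multiple roots: nodes "
            + ", ".join(str(n.id) for n in roots)
            + " all have parent_id = none"
        )
    for node in tree.nodes.values():
        if node.parent_id is not None and node.parent_id not in tree.nodes:
            violations.append(
                f"dangling parent: node {node.id} refers to missing node "
                f"{node.parent_id}"
            )
        if node.parent_id == node.id:
            violations.append(f"cycle: node {node.id} is its own parent")
        if node.kind not in _KINDS:
            violations.append(f"unknown kind {node.kind!r} on node {node.id}")
        if node.radius is not None and node.radius < 0:
            violations.append(f"negative radius on node {node.id}")
        if not all(np.isfinite(node.position)):
            violations.append(f"non-finite coordinates on node {node.id}")

    if tree.soma_id not in tree.nodes:
        violations.append(f"soma_id {tree.soma_id} names no node")
    else:
        soma = tree.nodes[tree.soma_id]
        if soma.parent_id is not None:
            violations.append(f"soma node {soma.id} has a parent")
        if soma.kind != SOMA:
            violations.append(f"root node {soma.id} has kind {soma.kind!r}, not soma")

    # connectivity / acyclicity.  Fast path: pointer-doubling on the parent
    # index array — in an acyclic single-rooted tree every ancestry chain
    # terminates (-1) within ceil(log2 N) doublings.  Only when that fails do
    # we walk node by node to name the offenders.
    n = len(tree.nodes)
    if not violations:
        _, _, anc = tree.as_arrays()
        anc = anc.copy()
        for _ in range(max(1, n).bit_length() + 1):
            live = anc >= 0
            if not live.any():
                break
            anc[live] = np.where(anc[live] >= 0, anc[anc[live]], -1)
        if not (anc >= 0).any():
            return violations
    reported_cycle: set[int] = set()
    for node in tree.nodes.values():
        cur, steps = node, 0
        while cur.parent_id is not None and cur.parent_id in tree.nodes:
            cur = tree.nodes[cur.parent_id]
            steps += 1
            if steps > n:
                if node.id not in reported_cycle and node.parent_id != node.id:
                    violations.append(f"cycle: ancestry of node {node.id} never ends")
                    reported_cycle.add(node.id)
                break
        else:
            if cur.id != tree.soma_id and cur.parent_id is None and len(roots) == 1:
                violations.append(
                    f"disconnected: node {node.id} does not reach soma {tree.soma_id}"
                )
    return violations


def require_valid(tree: NeuronTree) -> None:
    """Raise :class:`StructureError` listing violations, if any."""
    if tree._validated:
        return
    violations = validate_tree(tree)
    if violations:
        raise StructureError("; ".join(violations))
    tree._validated = True


def extract_segments(tree: NeuronTree) -> list[Segment]:
    """One :class:`Segment` per parent->child pair, in arbitrary order.

    Zero-length pairs (duplicated tracing points) are dropped with a logged
    warning; they contribute to no metric.  ``child_is_terminal`` marks
    segments whose child has no children.
    """
    require_valid(tree)
    children = tree.children_map()
    segments: list[Segment] = []
    dropped = 0
    for node in tree.nodes.values():
        if node.parent_id is None:
            continue
        a = tree.nodes[node.parent_id].position
        b = node.position
        if a == b:
            dropped += 1
            continue
        segments.append(Segment(a, b, not children[node.id]))
    if dropped:
        logger.warning("dropped %d zero-length segment(s)", dropped)
    return segments


def segment_arrays(tree: NeuronTree) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised companion to :func:`extract_segments`: returns
    (a (S, 3), b (S, 3), child_is_terminal (S,)) with zero-length pairs
    dropped.  Assumes the tree is valid (callers on the hot path check once)."""
    ids, pos, par = tree.as_arrays()
    child = par >= 0
    a = pos[par[child]]
    b = pos[child]
    keep = np.any(a != b, axis=1)
    has_child = np.zeros(len(ids), dtype=bool)
    has_child[par[child]] = True
    terminal = ~has_child[child]
    return a[keep], b[keep], terminal[keep]
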