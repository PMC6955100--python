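"""Per-neuron scalar morphometrics.

Three descriptors of dendritic complexity:

* total dendritic length  L  — sum of Euclidean lengths of all dendritic
  segments (µm);
* terminal count          T  — number of last-order (leaf) dendrites;
* spatial volume          V  — volume of the region the arbor occupies
  (µm³), either the axis-aligned bounding box (default) or the cube of the
  longest extent (``mode="cube"``).

The bounding-box reading is the default because reported neuron volumes
differ across regions in a way a single cubed extent would not capture;
whichever mode produced a number is always recorded alongside it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model import NeuronTree, SpecimenMeta, require_valid, segment_arrays

logger = logging.getLogger(__name__)

VOLUME_MODES = ("box", "cube")


@dataclass(frozen=True)
class MorphometrySummary:
    length_um: float
    terminal_count: int
    spatial_volume_um3: float
    node_count: int
    volume_mode: str = "box"
    meta: SpecimenMeta | None = None


def total_dendritic_length(tree: NeuronTree) -> float:
    """Sum of the lengths of all dendritic branches, in µm.  0 for a
    soma-only tree."""
    require_valid(tree)
    a, b, _ = segment_arrays(tree)
    if len(a) == 0:
        return 0.0
    return float(np.linalg.norm(b - a, axis=1).sum())


def terminal_count(tree: NeuronTree) -> int:
    """Number of branches of the last stage: leaf nodes with no children.
    The soma is excluded even when it is childless (soma-only tree -> 0,
    with a warning)."""
    require_valid(tree)
    ids, _, par = tree.as_arrays()
    if len(ids) == 1:
        logger.warning("terminal_count on soma-only tree defined as 0")
        return 0
    has_child = np.zeros(len(ids), dtype=bool)
    has_child[par[par >= 0]] = True
    leaves = ~has_child
    leaves[par < 0] = False  # exclude soma
    return int(leaves.sum())


def spatial_volume(tree: NeuronTree, mode: str = "box") -> float:
    """Volume of the smallest accommodating region, in µm³.

    ``mode="box"``: product of the coordinate ranges (axis-aligned bounding
    box; 0 for degenerate coplanar/collinear trees).  ``mode="cube"``: the
    longest coordinate extent cubed (a literal smallest enclosing
    axis-aligned cube)."""
    if mode not in VOLUME_MODES:
        raise ValueError(f"unknown volume mode {mode!r}; expected one of {VOLUME_MODES}")
    require_valid(tree)
    _, pos, _ = tree.as_arrays()
    extents = pos.max(axis=0) - pos.min(axis=0)
    if mode == "cube":
        return float(extents.max() ** 3)
    return float(np.prod(extents))


def summarize(tree: NeuronTree, volume_mode: str = "box") -> MorphometrySummary:
    """All three metrics, computed in one pass over the tree's arrays."""
    if volume_mode not in VOLUME_MODES:
        raise ValueError(f"unknown volume mode {volume_mode!r}")
    require_valid(tree)
    ids, pos, par = tree.as_arrays()
    a, b, _ = segment_arrays(tree)
    length = float(np.linalg.norm(b - a, axis=1).sum()) if len(a) else 0.0
    has_child = np.zeros(len(ids), dtype=bool)
    has_child[par[par >= 0]] = True
    leaves = ~has_child
    leaves[par < 0] = False
    extents = pos.max(axis=0) - pos.min(axis=0)
    volume = float(extents.max() ** 3) if volume_mode == "cube" else float(np.prod(extents))
    return MorphometrySummary(
        length_um=length,
        terminal_count=int(leaves.sum()),
        spatial_volume_um3=volume,
        node_count=len(ids),
        volume_mode=volume_mode,
        meta=tree.metadata,
    )
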