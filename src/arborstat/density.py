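"""Stereological neuron-density estimation from marker centroids.

Neurons are counted inside cubic counting blocks placed by a systematic
random scheme: blocks of edge 300 µm repeat at equally spaced intervals
(default 3 mm) along the longest axis of the target region, starting from
a uniformly random (seeded) offset.  Marker centroids — one per manually
identified large cell — are assigned to blocks with a half-open convention
(origin ≤ coordinate < origin + edge on every axis), so a centroid on a
face shared by two adjacent blocks is counted exactly once.  The density
estimate is total count over total block volume; the random start makes it
unbiased for a homogeneous point field.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .model import Point3

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegionExtent:
    """Axis-aligned spatial extent of one brain region, in µm."""

    origin: Point3
    size: tuple[float, float, float]
    region_label: str = ""

    def __post_init__(self):
        if any(s <= 0 for s in self.size):
            raise ConfigurationError(f"region extents must be > 0, got {self.size}")

    @property
    def volume_um3(self) -> float:
        return float(np.prod(self.size))


@dataclass(frozen=True)
class SamplingScheme:
    """Systematic random counting-block layout: ``n_blocks`` cubes of edge
    ``block_edge_um`` every ``spacing_um`` along the region's long axis."""

    block_edge_um: float = 300.0
    n_blocks: int = 5
    spacing_um: float = 3000.0
    random_start: bool = True

    def __post_init__(self):
        if self.block_edge_um <= 0:
            raise ConfigurationError("block_edge_um must be > 0")
        if self.n_blocks < 1:
            raise ConfigurationError("n_blocks must be >= 1")
        if self.spacing_um < self.block_edge_um:
            raise ConfigurationError("spacing_um must be >= block_edge_um")


@dataclass(frozen=True)
class CountingBlock:
    origin: Point3
    edge: float
    marker_count: int = 0


def place_counting_blocks(extent: RegionExtent, scheme: SamplingScheme,
                          seed: int | np.random.Generator = 0) -> list[CountingBlock]:
    """Place blocks along the region's longest axis.

    If the axis cannot accommodate ``n_blocks`` at the requested spacing the
    spacing shrinks, with a warning.  The starting offset is uniform on the
    available slack (capped at one spacing interval) when ``random_start``;
    otherwise blocks start flush at the region origin.  Raises
    :class:`ConfigurationError` when the extent cannot contain one block.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    edge = scheme.block_edge_um
    if any(s < edge for s in extent.size):
        raise ConfigurationError(
            f"region extent {extent.size} cannot contain a {edge} µm block"
        )
    axis = int(np.argmax(extent.size))
    length = extent.size[axis]
    spacing = scheme.spacing_um
    span = (scheme.n_blocks - 1) * spacing + edge
    if span > length:
        if scheme.n_blocks > 1:
            spacing = (length - edge) / (scheme.n_blocks - 1)
            logger.warning(
                "region long axis (%.0f µm) too short for %d blocks at %.0f µm "
                "spacing; spacing shrunk to %.0f µm",
                length, scheme.n_blocks, scheme.spacing_um, spacing)
        span = (scheme.n_blocks - 1) * spacing + edge
    slack = length - span
    offset = float(rng.uniform(0.0, min(spacing, slack))) if (
        scheme.random_start and slack > 0) else 0.0

    # cross axes: blocks centred in the region
    base = list(extent.origin)
    for ax in range(3):
        if ax != axis:
            base[ax] = extent.origin[ax] + (extent.size[ax] - edge) / 2.0
    blocks = []
    for i in range(scheme.n_blocks):
        origin = list(base)
        origin[axis] = extent.origin[axis] + offset + i * spacing
        blocks.append(CountingBlock(origin=Point3.of(origin), edge=edge))
    return blocks


def count_markers(blocks: list[CountingBlock],
                  centroids: list[Point3] | np.ndarray) -> tuple[list[CountingBlock], float]:
    """Assign centroids to blocks (half-open per axis) and return the blocks
    with counts filled in, plus the density estimate in markers / µm³."""
    pts = np.asarray(centroids, dtype=float).reshape(-1, 3)
    counted = []
    total = 0
    for blk in blocks:
        o = np.asarray(blk.origin, dtype=float)
        if len(pts):
            inside = np.all((pts >= o) & (pts < o + blk.edge), axis=1)
            n = int(inside.sum())
        else:
            n = 0
        counted.append(CountingBlock(origin=blk.origin, edge=blk.edge, marker_count=n))
        total += n
    volume = sum(b.edge ** 3 for b in blocks)
    density = total / volume if volume > 0 else 0.0
    return counted, density


def estimate_density(extent: RegionExtent, centroids, scheme: SamplingScheme,
                     seed: int | np.random.Generator = 0) -> tuple[list[CountingBlock], float]:
    """Place blocks and count in one call."""
    blocks = place_counting_blocks(extent, scheme, seed)
    return count_markers(blocks, centroids)


def read_centroids_csv(path) -> np.ndarray:
    """Read a marker-centroid table (columns x_um, y_um, z_um; extra columns
    such as a label are ignored) into an (N, 3) array."""
    df = pd.read_csv(path)
    required = ["x_um", "y_um", "z_um"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigurationError(f"centroid CSV missing columns: {missing}")
    return df[required].to_numpy(dtype=float)


def block_report(blocks: list[CountingBlock], region: str = "") -> pd.DataFrame:
    """Per-block count table: region, block_index, origin, count."""
    return pd.DataFrame([
        {"region": region, "block_index": i,
         "origin_x": b.origin.x, "origin_y": b.origin.y, "origin_z": b.origin.z,
         "count": b.marker_count}
        for i, b in enumerate(blocks)
    ])
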