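"""3D Sholl analysis.

Concentric spheres of radius Δr, 2Δr, ... are centred on the soma, and the
number of transversal crossings between the dendritic skeleton and each
sphere is counted exactly:  for every straight segment p(t) = a + t(b - a),
t ∈ [0, 1), the roots of |p(t)|² = r² are found in closed form and a root
is counted when the squared distance changes sign there (discriminant > 0).
The half-open parameter interval attributes a tracing node lying exactly on
a sphere to exactly one of its two adjoining segments, so it is never
double-counted.  A tangential touch (discriminant = 0, or a segment whose
closest approach equals r) is a measure-zero event and counts 0 unless
``tangency_counts`` is set.

The shell spacing defaults to 30 µm.  Spheres (not planar circles) are
used throughout: the reconstructions are three-dimensional, so crossings
are counted in 3D.

:func:`sholl_profile_sampled` is a deliberately naive dense-sampling
cross-check (walk each segment in tiny steps, count sign changes of
|p| - r); it shares no geometry code with the exact path and exists to
validate it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .model import NeuronTree, Point3, Segment, SpecimenMeta, require_valid, segment_arrays

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ShollConfig:
    """Shell layout.  ``max_radius_um=None`` means data-driven: the smallest
    multiple of ``step_um`` that reaches the neuron's most distant node."""

    step_um: float = 30.0
    max_radius_um: float | None = None
    tangency_counts: bool = False

    def __post_init__(self):
        if self.step_um <= 0:
            raise ValueError("step_um must be > 0")
        if self.max_radius_um is not None and self.max_radius_um < self.step_um:
            raise ValueError("max_radius_um must be >= step_um")


@dataclass(frozen=True)
class ShollProfile:
    """Intersection counts N(r) on shells r = Δr, 2Δr, ... for one neuron."""

    radii_um: tuple[float, ...]
    intersections: tuple[int, ...]
    meta: SpecimenMeta | None = None

    def __post_init__(self):
        if len(self.radii_um) != len(self.intersections):
            raise ValueError("radii_um and intersections must have equal length")

    @property
    def step_um(self) -> float:
        return self.radii_um[0] if self.radii_um else 0.0

    def padded(self, radii: tuple[float, ...]) -> "ShollProfile":
        """Re-express on a longer shell grid, padding with zero counts."""
        if radii[: len(self.radii_um)] != self.radii_um:
            raise ValueError("target grid does not extend this profile's grid")
        counts = self.intersections + (0,) * (len(radii) - len(self.intersections))
        return ShollProfile(radii, counts, self.meta)


def _crossing_matrix(a: np.ndarray, b: np.ndarray, center: np.ndarray,
                     radii: np.ndarray, tangency_counts: bool = False) -> np.ndarray:
    """Exact transversal crossing counts for S segments x R shells.

    Solves A t² + B t + C_r = 0 per (segment, shell) with
    A = |d|², B = 2 f·d, C_r = |f|² - r², d = b - a, f = a - center,
    and counts roots in [0, 1) with positive discriminant.
    """
    d = b - a
    f = a - center
    A = np.einsum("ij,ij->i", d, d)[:, None]          # (S, 1)
    B = 2.0 * np.einsum("ij,ij->i", d, f)[:, None]
    C = np.einsum("ij,ij->i", f, f)[:, None] - radii[None, :] ** 2  # (S, R)
    disc = B * B - 4.0 * A * C
    counts = np.zeros(disc.shape, dtype=np.int64)
    transversal = disc > 0
    if tangency_counts:
        transversal |= disc == 0
    if not transversal.any():
        return counts
    sq = np.sqrt(np.where(disc > 0, disc, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (-B - sq) / (2.0 * A)
        t2 = (-B + sq) / (2.0 * A)
    in_range1 = (t1 >= 0.0) & (t1 < 1.0) & transversal
    in_range2 = (t2 >= 0.0) & (t2 < 1.0) & transversal & (disc > 0)
    counts += in_range1.astype(np.int64) + in_range2.astype(np.int64)
    return counts


def segment_sphere_crossings(seg: Segment, center: Point3, r: float,
                             tangency_counts: bool = False) -> int:
    """Number of transversal crossings (0, 1 or 2) of one segment with the
    sphere of radius ``r`` about ``center``.  A degenerate segment (a = b)
    contributes 0, with a warning."""
    if r <= 0:
        raise ValueError("sphere radius must be > 0")
    a = np.asarray(seg.a, dtype=float)
    b = np.asarray(seg.b, dtype=float)
    if np.array_equal(a, b):
        logger.warning("degenerate segment at %s contributes no crossings", seg.a)
        return 0
    counts = _crossing_matrix(a[None, :], b[None, :], np.asarray(center, dtype=float),
                              np.array([r], dtype=float), tangency_counts)
    return int(counts[0, 0])


def shell_radii(max_distance: float, config: ShollConfig) -> np.ndarray:
    """The shell grid for a neuron whose farthest node sits at
    ``max_distance`` from the soma."""
    if config.max_radius_um is not None:
        rmax = config.max_radius_um
    else:
        n = int(np.ceil(max_distance / config.step_um)) if max_distance > 0 else 0
        rmax = n * config.step_um
    n_shells = int(round(rmax / config.step_um))
    return config.step_um * np.arange(1, n_shells + 1)


def sholl_profile(tree: NeuronTree, config: ShollConfig | None = None) -> ShollProfile:
    """Exact Sholl profile of one neuron, centred on its soma."""
    config = config or ShollConfig()
    require_valid(tree)
    center = np.asarray(tree.soma.position, dtype=float)
    _, pos, _ = tree.as_arrays()
    max_distance = float(np.linalg.norm(pos - center, axis=1).max())
    radii = shell_radii(max_distance, config)
    if len(radii) == 0:
        return ShollProfile((), (), tree.metadata)
    a, b, _ = segment_arrays(tree)
    if len(a) == 0:
        counts = np.zeros(len(radii), dtype=np.int64)
    else:
        counts = _crossing_matrix(a, b, center, radii, config.tangency_counts).sum(axis=0)
    return ShollProfile(tuple(float(r) for r in radii),
                        tuple(int(c) for c in counts), tree.metadata)


def sholl_profile_sampled(tree: NeuronTree, config: ShollConfig | None = None,
                          sample_um: float = 0.01) -> ShollProfile:
    """Brute-force profile by dense sampling: each segment is sampled every
    ``sample_um`` micrometres and, per shell, sign changes of |p| - r along
    the sampled path are counted.  Independent of the closed-form path;
    intended as a validation oracle, not for routine use."""
    config = config or ShollConfig()
    require_valid(tree)
    center = np.asarray(tree.soma.position, dtype=float)
    _, pos, _ = tree.as_arrays()
    max_distance = float(np.linalg.norm(pos - center, axis=1).max())
    radii = shell_radii(max_distance, config)
    if len(radii) == 0:
        return ShollProfile((), (), tree.metadata)
    a, b, _ = segment_arrays(tree)
    counts = np.zeros(len(radii), dtype=np.int64)
    for ai, bi in zip(a, b):
        seg_len = float(np.linalg.norm(bi - ai))
        # sample t in [0, 1): include t=0, exclude t=1 (half-open convention)
        n = max(int(np.ceil(seg_len / sample_um)), 2)
        t = np.arange(n) / n
        pts = ai[None, :] + t[:, None] * (bi - ai)[None, :]
        dist = np.linalg.norm(pts - center, axis=1)
        # also evaluate the endpoint to close the last sub-interval
        dist = np.append(dist, np.linalg.norm(bi - center))
        for k, r in enumerate(radii):
            s = np.sign(dist - r)
            counts[k] += int(np.sum(s[:-1] * s[1:] < 0))
    return ShollProfile(tuple(float(r) for r in radii),
                        tuple(int(c) for c in counts), tree.metadata)


def aggregate_range(profile: ShollProfile, lo_um: float, hi_um: float) -> int:
    """Sum of intersection counts over shells with lo ≤ r ≤ hi.  Bounds not
    on the shell grid are snapped outward (lo down, hi up) with a warning;
    an empty range returns 0 with a warning."""
    if lo_um > hi_um:
        raise ValueError("lo_um must be <= hi_um")
    step = profile.step_um
    if step > 0:
        lo_snap = np.floor(lo_um / step) * step
        hi_snap = np.ceil(hi_um / step) * step
        if lo_snap != lo_um or hi_snap != hi_um:
            warnings.warn(
                f"range [{lo_um}, {hi_um}] snapped outward to "
                f"[{lo_snap}, {hi_snap}] (shell step {step})",
                stacklevel=2,
            )
        lo_um, hi_um = lo_snap, hi_snap
    total = sum(c for r, c in zip(profile.radii_um, profile.intersections)
                if lo_um <= r <= hi_um)
    if not any(lo_um <= r <= hi_um for r in profile.radii_um):
        warnings.warn(f"no shells in range [{lo_um}, {hi_um}]", stacklevel=2)
    return int(total)


def common_grid(profiles: list[ShollProfile]) -> tuple[float, ...]:
    """Longest shell grid across profiles; all profiles must share a step."""
    steps = {p.step_um for p in profiles if p.radii_um}
    if len(steps) > 1:
        raise ValueError(f"profiles mix shell steps: {sorted(steps)}")
    longest: tuple[float, ...] = ()
    for p in profiles:
        if len(p.radii_um) > len(longest):
            longest = p.radii_um
    return longest
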