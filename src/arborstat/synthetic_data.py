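"""Seeded stochastic generator of neuron trees and two-group cohorts.

The generator emulates the structure of Golgi-stained pyramidal-neuron
tracings: from a single soma, ``n_stems`` primary dendrites grow outward
as straight polyline branches whose lengths are gamma-distributed; at each
branch end the dendrite bifurcates with probability ``branch_prob`` until
a branch-order cap, daughter directions being the parent direction
perturbed by a random rotation within ``angle_spread_deg``.

Default parameters are chosen so a baseline neuron resembles the traced
cohorts this pipeline targets: total dendritic length around 700 µm with a
between-neuron coefficient of variation near 0.3, about 12 terminal
dendrites, a spatial volume of a few 10⁶ µm³ and an arbor radius of one
to two hundred µm.  Two kinds of
between-group effects can be planted: global multipliers on the mean
branch length or branching probability (overall complexity shifts), and a
proximal-twig mechanism — extra short terminal branches sprouted near the
soma — which raises Sholl counts only in a chosen radial window, the
signature of a near-soma density increase.

Reproducibility: one master seed is split into independent per-neuron
streams by counter (``numpy`` ``SeedSequence``), so a cohort is identical
regardless of generation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigurationError
from .density import RegionExtent
from .model import NeuronTree, SpecimenMeta

_TWIG_LENGTH_FRACTION = 0.5  # proximal twigs are half a mean branch long


@dataclass(frozen=True)
class GrowthParams:
    """Stochastic growth rule for one neuron."""

    n_stems: int = 10
    mean_branch_len_um: float = 41.0
    branch_len_cv: float = 0.30
    branch_prob: float = 0.25
    max_order: int = 3
    angle_spread_deg: float = 40.0
    step_um: float = 5.0
    # planted proximal effect: probability of sprouting one extra short
    # terminal twig at a branch end lying inside the radial window
    proximal_twig_prob: float = 0.0
    proximal_window_um: tuple[float, float] = (0.0, 90.0)

    def __post_init__(self):
        if not (0.0 <= self.branch_prob <= 1.0):
            raise ConfigurationError("branch_prob must lie in [0, 1]")
        if not (0.0 <= self.proximal_twig_prob <= 1.0):
            raise ConfigurationError("proximal_twig_prob must lie in [0, 1]")
        if self.max_order < 1:
            raise ConfigurationError("max_order must be >= 1")
        if min(self.mean_branch_len_um, self.step_um) <= 0:
            raise ConfigurationError("lengths must be > 0")
        if self.n_stems < 1:
            raise ConfigurationError("n_stems must be >= 1")
        if self.branch_len_cv < 0:
            raise ConfigurationError("branch_len_cv must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """A labelled cohort with optional planted effects relative to baseline
    parameters: multiplicative shifts of mean branch length and branching
    probability, plus the proximal-twig density effect."""

    label: str
    n_neurons: int = 60
    params: GrowthParams = GrowthParams()
    length_multiplier: float = 1.0
    branch_prob_multiplier: float = 1.0
    proximal_twig_prob: float = 0.0
    region: str = "CA1"
    hemisphere: str = "L"

    def __post_init__(self):
        if self.n_neurons < 1:
            raise ConfigurationError("n_neurons must be >= 1")
        if min(self.length_multiplier, self.branch_prob_multiplier) <= 0:
            raise ConfigurationError("effect multipliers must be > 0")

    def effective_params(self) -> GrowthParams:
        return replace(
            self.params,
            mean_branch_len_um=self.params.mean_branch_len_um * self.length_multiplier,
            branch_prob=min(1.0, self.params.branch_prob * self.branch_prob_multiplier),
            proximal_twig_prob=min(1.0, self.params.proximal_twig_prob
                                   + self.proximal_twig_prob),
        )


def _cross(u, v) -> np.ndarray:
    # scalar 3-vector cross product; np.cross has large overhead at size 3
    return np.array([u[1] * v[2] - u[2] * v[1],
                     u[2] * v[0] - u[0] * v[2],
                     u[0] * v[1] - u[1] * v[0]])


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / math.sqrt(v[0] * v[0] + v[1] * v[1] + v[2] * v[2])


def _perturb(direction: np.ndarray, spread_deg: float,
             rng: np.random.Generator) -> np.ndarray:
    """Rotate ``direction`` by a polar angle uniform on [0, spread] about a
    random axis perpendicular to it (Rodrigues rotation; the axis-parallel
    term vanishes because the axis is orthogonal to the direction)."""
    if spread_deg <= 0:
        return direction
    theta = math.radians(rng.uniform(0.0, spread_deg))
    axis = _cross(direction, _random_unit(rng))
    norm = math.sqrt(axis @ axis)
    if norm < 1e-12:  # helper parallel to direction; retry deterministically
        axis = _cross(direction, np.roll(direction, 1))
        norm = math.sqrt(axis @ axis)
    axis /= norm
    return (direction * math.cos(theta) + _cross(axis, direction) * math.sin(theta))


def _branch_length(params: GrowthParams, rng: np.random.Generator) -> float:
    mean, cv = params.mean_branch_len_um, params.branch_len_cv
    if cv == 0:
        return mean
    shape = 1.0 / cv**2
    return float(rng.gamma(shape, mean / shape))


def grow_neuron(params: GrowthParams,
                seed: int | np.random.Generator = 0,
                metadata: SpecimenMeta | None = None) -> NeuronTree:
    """Grow one neuron from the origin.  Deterministic under the seed."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    positions: list[np.ndarray] = [np.zeros(3)]
    parents: list[int] = [-1]

    def add_branch(start_index: int, direction: np.ndarray, length: float) -> int:
        """Append a straight polyline of ~step_um-spaced nodes; return the
        index of its last node."""
        start = positions[start_index]
        n_steps = max(1, int(round(length / params.step_um)))
        step = length / n_steps
        base = len(positions)
        pts = start + np.arange(1, n_steps + 1)[:, None] * (direction * step)
        positions.extend(pts)
        parents.append(start_index)
        parents.extend(range(base, base + n_steps - 1))
        return base + n_steps - 1

    # (attach node index, direction, order) — grown depth-first; the stack
    # order is deterministic under the seed
    stack: list[tuple[int, np.ndarray, int]] = [
        (0, _random_unit(rng), 1) for _ in range(params.n_stems)
    ]
    while stack:
        attach, direction, order = stack.pop()
        end = add_branch(attach, direction, _branch_length(params, rng))
        if order < params.max_order and rng.random() < params.branch_prob:
            stack.append((end, _perturb(direction, params.angle_spread_deg, rng), order + 1))
            stack.append((end, _perturb(direction, params.angle_spread_deg, rng), order + 1))
        if params.proximal_twig_prob > 0:
            lo, hi = params.proximal_window_um
            radial = float(np.linalg.norm(positions[end]))
            if lo <= radial <= hi and rng.random() < params.proximal_twig_prob:
                twig_dir = _perturb(direction, 90.0, rng)
                twig_len = _TWIG_LENGTH_FRACTION * _branch_length(params, rng)
                add_branch(end, twig_dir, max(twig_len, params.step_um))

    return NeuronTree.from_arrays(np.array(positions), np.array(parents, dtype=int),
                                  metadata=metadata)


def expected_total_length(params: GrowthParams) -> float:
    """Closed-form expectation of total dendritic length under the growth
    rule (without proximal twigs): each stem spawns an expected
    Σ_{k=1..max_order} (2·branch_prob)^(k−1) branches of expected length
    ``mean_branch_len_um``."""
    q = 2.0 * params.branch_prob
    branches_per_stem = sum(q**k for k in range(params.max_order))
    return params.n_stems * branches_per_stem * params.mean_branch_len_um


def expected_terminal_count(params: GrowthParams) -> float:
    """Expected number of terminal dendrites (without twigs): T(max) = 1,
    T(k) = (1−p) + 2p·T(k+1), summed over stems."""
    p = params.branch_prob
    t = 1.0
    for _ in range(params.max_order - 1):
        t = (1.0 - p) + 2.0 * p * t
    return params.n_stems * t


def generate_cohort(spec: CohortSpec,
                    seed: int = 0) -> list[tuple[NeuronTree, SpecimenMeta]]:
    """Generate ``spec.n_neurons`` trees with per-neuron metadata.  Each
    neuron uses an independent child stream of the master seed, indexed by
    its position, so cohorts are reproducible."""
    params = spec.effective_params()
    children = np.random.SeedSequence(seed).spawn(spec.n_neurons)
    out = []
    for i, child in enumerate(children):
        meta = SpecimenMeta(cohort=spec.label, region=spec.region,
                            hemisphere=spec.hemisphere, layer="L0",
                            neuron_index=i + 1)
        tree = grow_neuron(params, np.random.default_rng(child), metadata=meta)
        out.append((tree, meta))
    return out


def generate_centroid_field(extent: RegionExtent, intensity_per_um3: float,
                            seed: int | np.random.Generator = 0) -> np.ndarray:
    """Homogeneous Poisson point sample over the extent: the marker field a
    perfectly uniform region of neuron somata would produce."""
    if intensity_per_um3 < 0:
        raise ConfigurationError("intensity must be >= 0")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n = rng.poisson(intensity_per_um3 * extent.volume_um3)
    origin = np.asarray(extent.origin, dtype=float)
    size = np.asarray(extent.size, dtype=float)
    return origin + rng.uniform(size=(n, 3)) * size
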