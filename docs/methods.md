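# Methods

## Neuron model

A reconstructed neuron is a rooted tree: one soma node (the root) and
dendritic nodes connected by straight segments, coordinates in µm. This
matches how interactive tracing tools export morphology — the soma is
located first and dendrites are extended from it — and it is the minimal
substrate for every metric here. Multi-point soma contours found in SWC
files are collapsed to their centroid, because all downstream geometry
(in particular the Sholl centre) needs a single soma point. Node radii
are read and written but ignored by all metrics: the measured quantities
are skeleton properties. Duplicate consecutive tracing points (zero-length
segments) are dropped with a logged warning; they carry no length and
cross no sphere.

Validation is diagnostic rather than exception-driven: `validate_tree`
returns a list of named violations (multiple roots, cycles, dangling
parents, disconnection, bad kinds/radii/coordinates) and metric
entry-points refuse invalid trees. Internally, connectivity is checked by
pointer-doubling over the parent-index array (O(N log N)); the node-by-node
walk that names offenders runs only when something is actually wrong. A
tree that validates once is marked clean and not re-checked, so
metric-heavy simulation loops do not pay for repeated validation; trees
are treated as immutable after construction.

## Scalar morphometrics

* **Dendritic length** — sum of Euclidean segment lengths. Soma-only
  trees measure 0.
* **Terminal count** — leaves of the tree, soma excluded (an isolated
  soma has 0 terminals, with a warning). Branch order is centripetal
  (stems are order 1), but only leaf status is needed.
* **Spatial volume** — the "smallest volume accommodating the neuron" has
  two defensible readings, and both are implemented: the axis-aligned
  bounding-box product Δx·Δy·Δz (default `box`), and the literal smallest
  enclosing axis-aligned cube, max-extent³ (`cube`). Box volume is the
  default because real cohort volumes differ in all three extents; every
  report records which mode produced the number. Box volume is not
  rotation-invariant — a test documents this limitation explicitly rather
  than hiding it.

## Exact 3D Sholl analysis

Shells are spheres (the reconstructions are 3D), spaced Δr = 30 µm by
default, centred on the soma. The profile extends to the smallest
multiple of Δr reaching the most distant node, unless a fixed maximum is
configured; group comparisons zero-pad profiles to a common grid (a shell
beyond a neuron's extent genuinely has zero crossings).

Crossing counting is closed-form. For a segment p(t) = a + t(b−a) and
shell radius r, the roots of |p(t)|² = r² come from one quadratic;
a root counts when (i) it lies in the half-open interval t ∈ [0, 1) and
(ii) the discriminant is strictly positive (a transversal crossing). The
half-open convention attributes a tracing node lying exactly on a shell
to exactly one of its two adjoining segments, so polyline subdivision
never double-counts. Tangential touches count 0 by default — they are
measure-zero events and the convention keeps the exact counter consistent
with any sign-change definition of "crossing"; `tangency_counts=True` is
available for the other convention.

The independent cross-check, `sholl_profile_sampled`, walks each segment
in 0.01 µm steps and counts sign changes of |p|−r. It shares no geometry
code with the exact path, and equality between the two on hundreds of
random arbors is one of the package's acceptance properties.

Range statistics (e.g. "more crossings between 150 and 450 µm") first sum
each neuron's counts over the shells in range, then test one number per
neuron; bounds off the shell grid snap outward with a warning.

## Group statistics

Groups are reported as mean ± SEM (sd with n−1 denominator over √n);
n ≥ 2 is required, and per-metric n is always recorded because usable
neurons can differ between metrics. Differences use a two-sided
two-sample *t*-test at α = 0.05. Student's pooled-variance variant is the
default — when a study says only "t-test", pooled is the historical
default of common statistics software — with Welch selectable, and every
report names the variant. Degenerate zero-variance samples follow the
limiting convention (equal means → t = 0, p = 1; unequal → ±∞, p = 0).
The t statistics and p-values are delegated to scipy; first-principles
formulas serve as oracles in the test suite.

Per-shell Sholl testing performs one uncorrected test per radius —
mirroring common practice in the field — but emits a multiplicity
warning, and a Holm correction (statsmodels) is available by flag. Range
tests avoid shell pseudo-replication by construction (one aggregate per
neuron). Neurons are the unit of analysis; per-animal clustering is not
modelled (see limitations).

## Stereological density estimation

Counting blocks (default: five 300 × 300 × 300 µm³ cubes at 3 mm
intervals) are laid along the region's longest axis starting at a
seeded uniformly random offset within the available slack (capped at one
spacing interval); cross-axes are centred. If the region is too short for
the requested spacing, spacing shrinks with a warning; a region smaller
than one block is a configuration error. Markers are assigned half-open
(origin ≤ x < origin + edge per axis), so a centroid on a face shared by
adjacent blocks counts exactly once, in the higher block. Density is
total count over total block volume; the random start makes the
estimator unbiased for a homogeneous field, which the acceptance suite
verifies by Monte-Carlo against generated Poisson intensities.
Large-vs-small cell discrimination is perceptual and happens upstream;
this module consumes pre-classified centroid lists.

## Synthetic cohorts

The generator emulates the *structure* of traced pyramidal-neuron data,
not its biophysics: from the soma, `n_stems` straight polyline branches
(nodes `step_um` apart) grow in random directions; branch lengths are
gamma-distributed (positive and right-skewed, with `branch_len_cv`
setting the shape); each branch end bifurcates with `branch_prob` until
`max_order`; daughter directions are the parent direction rotated by a
polar angle uniform on [0, `angle_spread_deg`] about a random
perpendicular axis. One master seed is split into per-neuron child
streams by counter, so cohorts reproduce independently of generation
order.

Defaults (10 stems, mean branch 41 µm at CV 0.30, branch probability
0.25, order cap 3, 40° spread, 5 µm steps) were chosen once to make a
baseline cohort resemble Golgi-cohort morphometry: mean dendritic length
≈ 700 µm, ≈ 13 terminal dendrites, box volume of order 10⁶ µm³, arbor
radius 100–150 µm, and a between-neuron length CV of ≈ 0.26 — at the low
end of the dispersion seen in real per-region cohorts, a deliberate
choice so that moderate (20%) planted effects are recoverable at
n = 60/group, which is the regime the pipeline is designed to resolve.

Planted effects:

* `length_multiplier` / `branch_prob_multiplier` scale the corresponding
  parameter globally (overall complexity shifts);
* `proximal_twig_prob` sprouts an extra short terminal twig (half a
  branch-length draw) at branch ends inside `proximal_window_um`
  (default 0–90 µm; the validation scenario uses 0–60 µm). Because a twig
  from radius r adds crossings only on shells in (r, r + twig length],
  the effect stays confined to proximal shells — the signature of a
  near-soma density increase with more terminals.

What the generator does **not** emulate: apical/basal dichotomy, tropism
toward the pia, tortuous branch paths (branches are straight between
bifurcations), spines, tracing noise, truncation at block faces, or
per-animal clustering. Passing tests therefore demonstrate that the
*measurement and inference machinery* is correct and calibrated on data
with known ground truth — not that real cohorts will show any particular
effect.

## Numerical and design choices

* Exact Sholl roots use the standard quadratic with a strict
  discriminant-positivity test; no epsilon tolerances are introduced, so
  exact-arithmetic ties (a node exactly on a shell) resolve by the
  half-open rule rather than by fuzz.
* SWC output writes coordinates via `repr`, the shortest exactly
  round-tripping decimal form, so metrics survive a write/read cycle
  bit-for-bit; records are ordered parent-before-child with ids
  relabelled 1..N; unset radii are written as 1.0.
* The Amira reader consumes only the ASCII SpatialGraph dialect and
  rejects binary files by name; edge point lists that repeat their
  endpoint vertices are merged; the root is the first vertex unless a
  soma vertex is designated (`soma_vertex`).
* Filename metadata uses a configurable ordered-token convention
  (default `COHORT_REGION_HEMI_LAYER_INDEX`); unknown cohort/region
  tokens are errors, never guesses.
* Simulation problem sizes in the validation suite (200 oracle trees,
  1000 null replicates, 50 effect replicates, 100 density replicates at
  n = 60 neurons/group) were sized to give stable Monte-Carlo estimates
  at interactive runtimes on a single CPU.

## Known limitations

* Box volume is axis-frame dependent; the cube mode shares this.
* Per-neuron inference ignores animal-level correlation; with few
  animals per cohort, p-values are anti-conservative for animal-level
  claims.
* Uncorrected per-shell Sholl tests inflate family-wise error across
  shells (hence the warning and Holm flag).
* Binary Amira files, Neurolucida formats and HDF5 morphology containers
  are out of scope.
* The growth model is a test harness, not a biophysical model of
  dendritic development.
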