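# arborstat

Morphometry, 3D Sholl analysis and two-group statistics for traced neuron
arbors — with a seeded synthetic-cohort generator for validation.

`arborstat` is aimed at quantitative comparisons of dendritic complexity
between cohorts of reconstructed neurons, such as pyramidal neurons traced
from Golgi-stained mouse brains at different disease stages (e.g. 6- vs
12-month-old Alzheimer's-model animals, across prefrontal cortex, primary
motor cortex, entorhinal cortex and hippocampal CA1). It ingests standard
SWC files or ASCII Amira SpatialGraph exports, computes per-neuron
descriptors, compares cohorts, and additionally estimates regional neuron
density from manually placed soma markers by stereological counting
blocks.

## What it computes

For each neuron, modelled as a rooted tree with the soma at the root:

* **Total dendritic length** `L = Σ_e ‖e‖` — the sum of Euclidean lengths
  of all dendritic segments (µm).
* **Terminal-dendrite count** `T` — the number of last-order (leaf)
  branches.
* **Spatial volume** `V` (µm³) — the axis-aligned bounding box of the
  arbor (default), or the cube of the longest extent (`mode="cube"`); the
  mode used is always recorded.
* **3D Sholl profile** `N(r)` for shells `r = Δr, 2Δr, …` (default
  Δr = 30 µm): the exact number of transversal crossings between the
  skeleton and the sphere of radius `r` centred on the soma, obtained by
  solving `|a + t(b − a)|² = r²` per segment on the half-open interval
  `t ∈ [0, 1)` so shared nodes are never double-counted.

Cohorts are summarised as mean ± SEM (`SEM = s/√n`) and compared with
two-sided two-sample *t*-tests at α = 0.05 (Student's pooled test by
default, Welch selectable) — per metric, per Sholl shell, and per radial
range (per-neuron sums over the range, avoiding shell pseudo-replication).

Neuron density is estimated from marker centroids with `n` cubic counting
blocks (default five 300 µm blocks every 3 mm) placed systematically with
a random start along the region's long axis; markers are binned half-open
so shared faces count once, and density = total count / total block
volume.

The `synthetic_data` module grows stochastic neuron cohorts (gamma branch
lengths, Bernoulli bifurcation up to an order cap, perturbed directions)
with plantable between-group effects — global shifts of branch length or
branching probability, and a proximal-twig effect that raises Sholl
counts only near the soma.

## Worked example

Simulate two 60-neuron cohorts with a planted 20% dendritic-length
difference and compare them:

```python
from arborstat import CohortSpec, compare_metric, generate_cohort

ad06 = [t for t, _ in generate_cohort(CohortSpec(label="AD06", length_multiplier=1.2), seed=7)]
ad12 = [t for t, _ in generate_cohort(CohortSpec(label="AD12"), seed=8)]
c = compare_metric(ad06, ad12, "length", label_a="AD06", label_b="AD12")
print(f"{c.metric}: {c.summary_a.mean:.1f} ± {c.summary_a.sem:.1f} (n={c.summary_a.n}) vs "
      f"{c.summary_b.mean:.1f} ± {c.summary_b.sem:.1f} (n={c.summary_b.n}); "
      f"t = {c.test.t_statistic:.2f}, p = {c.test.p_value:.4f}")
```

prints

```
length: 839.8 ± 29.0 (n=60) vs 737.0 ± 23.4 (n=60); t = 2.76, p = 0.0068
```

i.e. the AD06-like cohort's mean dendritic length (839.8 µm) exceeds the
baseline cohort's (737.0 µm) and the pooled *t*-test flags the planted
difference as significant (p < 0.05, positive t = planted direction).

The same workflow from the shell, via the cohort-spec files in
`examples/`:

```
arborstat simulate --spec examples/ad06.cfg --spec examples/ad12.cfg --out cohorts --seed 7
arborstat analyze --input cohorts --metadata cohorts/metadata.csv --range 150:450 --out report --seed 7
```

`report/` then contains `metrics.csv` (one row per neuron), `sholl.csv`
(long-format profiles), `comparisons.csv`/`.json` (means ± SEM, t, df, p
per metric, shell and range) and `manifest.json` (config echo, versions,
seed, skipped-file log). `arborstat density` estimates markers/µm³ from a
centroid CSV.

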