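"""End-to-end orchestration: ingest tracings, compute metrics and Sholl
profiles, compare cohorts, write reports.

The analysis is metadata-driven: each neuron's cohort/region comes from a
metadata CSV or from its filename (never from directory position).  Within
every region holding at least two cohorts, all cohort pairs are compared
on the three scalar morphometrics and shell-by-shell on Sholl profiles
(plus any configured radial ranges).  Outputs are plain CSV/JSON plus a
manifest echoing the configuration, the seed, library versions, and a
per-file account of anything skipped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ArborstatError, ConfigurationError
from .io_formats import (
    DEFAULT_NAMING,
    NamingConvention,
    parse_specimen_metadata,
    read_amira_spatialgraph,
    read_metadata_csv,
    read_swc,
    write_metadata_csv,
    write_swc,
)
from .model import NeuronTree, SpecimenMeta
from .morphometry import summarize
from .group_stats import compare_metric, compare_sholl, comparisons_table, METRICS
from .sholl import ShollConfig, sholl_profile
from .synthetic_data import CohortSpec, GrowthParams, generate_cohort

logger = logging.getLogger(__name__)

_FORMAT_EXT = {"swc": ".swc", "amira": ".am"}


@dataclass(frozen=True)
class AnalysisConfig:
    input_dir: str
    out_dir: str
    file_format: str = "swc"
    metadata_csv: str | None = None
    naming: NamingConvention = DEFAULT_NAMING
    sholl: ShollConfig = field(default_factory=ShollConfig)
    sholl_ranges: tuple[tuple[float, float], ...] = ()
    alpha: float = 0.05
    t_variant: str = "student"
    volume_mode: str = "box"
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.file_format not in _FORMAT_EXT:
            raise ConfigurationError(
                f"unknown format {self.file_format!r}; expected swc or amira")


def _load_inputs(config: AnalysisConfig):
    """Yield (tree, meta) for every readable input; collect skip reasons."""
    reader = read_swc if config.file_format == "swc" else read_amira_spatialgraph
    entries: list[tuple[SpecimenMeta | None, Path]] = []
    if config.metadata_csv:
        base = Path(config.metadata_csv).parent
        for meta, rel in read_metadata_csv(config.metadata_csv):
            p = Path(rel)
            entries.append((meta, p if p.is_absolute() else base / p))
    else:
        ext = _FORMAT_EXT[config.file_format]
        for p in sorted(Path(config.input_dir).glob(f"*{ext}")):
            entries.append((None, p))

    loaded: list[tuple[NeuronTree, SpecimenMeta]] = []
    skipped: dict[str, str] = {}
    for meta, path in entries:
        try:
            if meta is None:
                meta = parse_specimen_metadata(path, config.naming)
            tree = reader(path, metadata=meta)
            loaded.append((tree, meta))
        except (ArborstatError, OSError) as exc:
            logger.warning("skipping %s: %s", path, exc)
            skipped[str(path)] = str(exc)
    return loaded, skipped


def run_analysis(config: AnalysisConfig) -> dict:
    """Run the full analysis; returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    loaded, skipped = _load_inputs(config)
    if not loaded:
        raise ConfigurationError(
            f"no parsable neurons found in {config.input_dir!r}")

    metric_rows, sholl_rows = [], []
    profiles: dict[tuple[str, str], list] = {}
    trees: dict[tuple[str, str], list[NeuronTree]] = {}
    for tree, meta in loaded:
        s = summarize(tree, volume_mode=config.volume_mode)
        metric_rows.append({
            "cohort": meta.cohort, "region": meta.region,
            "hemisphere": meta.hemisphere, "neuron_index": meta.neuron_index,
            "length_um": s.length_um, "terminal_count": s.terminal_count,
            "spatial_volume_um3": s.spatial_volume_um3,
            "node_count": s.node_count,
        })
        prof = sholl_profile(tree, config.sholl)
        for r, c in zip(prof.radii_um, prof.intersections):
            sholl_rows.append({
                "cohort": meta.cohort, "region": meta.region,
                "neuron_index": meta.neuron_index,
                "radius_um": r, "intersections": c,
            })
        key = (meta.region, meta.cohort)
        profiles.setdefault(key, []).append(prof)
        trees.setdefault(key, []).append(tree)

    metrics_df = pd.DataFrame(metric_rows).sort_values(
        ["region", "cohort", "neuron_index"], kind="stable")
    metrics_df.to_csv(out / "metrics.csv", index=False)
    pd.DataFrame(sholl_rows).to_csv(out / "sholl.csv", index=False)

    comparisons = []
    regions = sorted({r for r, _ in trees})
    for region in regions:
        cohorts = sorted({c for r, c in trees if r == region})
        if len(cohorts) < 2:
            logger.warning("region %s has a single cohort; comparisons skipped", region)
            continue
        for ca, cb in combinations(cohorts, 2):
            for metric in METRICS:
                cmp_ = compare_metric(
                    trees[(region, ca)], trees[(region, cb)], metric,
                    label_a=ca, label_b=cb, variant=config.t_variant,
                    alpha=config.alpha, volume_mode=config.volume_mode)
                comparisons.append((region, cmp_))
            shell_cmps = compare_sholl(
                profiles[(region, ca)], profiles[(region, cb)],
                mode="per_shell", label_a=ca, label_b=cb,
                variant=config.t_variant, alpha=config.alpha)
            comparisons.extend((region, c) for c in shell_cmps)
            if config.sholl_ranges:
                range_cmps = compare_sholl(
                    profiles[(region, ca)], profiles[(region, cb)],
                    mode="range", ranges=config.sholl_ranges,
                    label_a=ca, label_b=cb,
                    variant=config.t_variant, alpha=config.alpha)
                comparisons.extend((region, c) for c in range_cmps)

    cmp_df = comparisons_table([c for _, c in comparisons])
    cmp_df.insert(0, "region", [r for r, _ in comparisons])
    cmp_df.to_csv(out / "comparisons.csv", index=False)
    (out / "comparisons.json").write_text(
        cmp_df.to_json(orient="records", indent=2))

    manifest = {
        "arborstat_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config": {
            "input_dir": str(config.input_dir),
            "file_format": config.file_format,
            "metadata_csv": config.metadata_csv,
            "sholl_step_um": config.sholl.step_um,
            "sholl_ranges": list(map(list, config.sholl_ranges)),
            "alpha": config.alpha,
            "t_variant": config.t_variant,
            "volume_mode": config.volume_mode,
        },
        "n_neurons": len(loaded),
        "n_skipped": len(skipped),
        "skipped": skipped,
        "regions": regions,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


# ---------------------------------------------------------------------------
# Simulation entry point
# ---------------------------------------------------------------------------

_SPEC_FIELDS = {f: float for f in (
    "mean_branch_len_um", "branch_len_cv", "branch_prob", "angle_spread_deg",
    "step_um")}
_SPEC_FIELDS.update({"n_stems": int, "max_order": int})
_COHORT_FIELDS = {
    "label": str, "n_neurons": int, "length_multiplier": float,
    "branch_prob_multiplier": float, "proximal_twig_prob": float,
    "region": str, "hemisphere": str,
}


def load_cohort_spec(path: str | Path) -> CohortSpec:
    """Read a flat key=value cohort-spec file ('#' comments allowed)."""
    values: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigurationError(f"{path}:{lineno}: expected key = value")
        key, _, value = line.partition("=")
        values[key.strip()] = value.strip()

    growth_kwargs, cohort_kwargs = {}, {}
    for key, value in values.items():
        try:
            if key in _SPEC_FIELDS:
                growth_kwargs[key] = _SPEC_FIELDS[key](value)
            elif key in _COHORT_FIELDS:
                cohort_kwargs[key] = _COHORT_FIELDS[key](value)
            else:
                raise ConfigurationError(f"{path}: unknown field {key!r}")
        except ValueError:
            raise ConfigurationError(
                f"{path}: field {key!r} has invalid value {value!r}") from None
    if "label" not in cohort_kwargs:
        raise ConfigurationError(f"{path}: cohort spec needs a 'label' field")
    return CohortSpec(params=GrowthParams(**growth_kwargs), **cohort_kwargs)


def run_simulation(specs: list[CohortSpec], out_dir: str | Path, seed: int = 0,
                   naming: NamingConvention = DEFAULT_NAMING) -> dict:
    """Generate each cohort into an SWC directory plus a metadata CSV; echo
    the generator parameters next to the output."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for k, spec in enumerate(specs):
        cohort_dir = out / spec.label
        cohort_dir.mkdir(exist_ok=True)
        for tree, meta in generate_cohort(spec, seed=seed + k):
            name = naming.format_name(meta)
            write_swc(tree, cohort_dir / name)
            entries.append((meta, str(Path(spec.label) / name)))
        (cohort_dir / "params.json").write_text(json.dumps({
            "seed": seed + k, **asdict(spec)}, indent=2, default=str))
    write_metadata_csv(entries, out / "metadata.csv")
    return {"n_cohorts": len(specs), "n_neurons": len(entries),
            "metadata_csv": str(out / "metadata.csv")}
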