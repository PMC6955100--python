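"""Two-group comparison of morphometrics and Sholl profiles.

All summaries follow the mean ± SEM convention (SEM = sd/√n with the n−1
denominator), group differences are assessed with a two-sided two-sample
t-test at α = 0.05 — Student's pooled-variance test by default, Welch's
test selectable — and per-metric sample sizes are always recorded.

Per-shell Sholl testing performs one test per radius with no multiplicity
correction by default (many shells means many comparisons; a Holm
correction is available by flag).  Range-level Sholl tests first sum each
neuron's counts over the radial range and then test one value per neuron,
which avoids pseudo-replicating shells.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import SampleSizeError
from .model import NeuronTree
from . import morphometry
from .sholl import ShollConfig, ShollProfile, aggregate_range, common_grid, sholl_profile

DEFAULT_ALPHA = 0.05
T_VARIANTS = ("student", "welch")

#: metric name -> per-tree extractor
METRICS: dict[str, Callable[[NeuronTree], float]] = {
    "length": morphometry.total_dendritic_length,
    "terminal_count": lambda t: float(morphometry.terminal_count(t)),
    "spatial_volume": morphometry.spatial_volume,
}


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    sem: float


@dataclass(frozen=True)
class TestResult:
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    significant: bool
    alpha: float = DEFAULT_ALPHA
    variant: str = "student"


@dataclass(frozen=True)
class GroupComparison:
    metric: str
    summary_a: GroupSummary
    summary_b: GroupSummary
    test: TestResult


def summarize_group(values: Sequence[float], label: str = "") -> GroupSummary:
    """Mean and SEM (sd/√n, ddof=1) of one group; requires n ≥ 2."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise SampleSizeError(
            f"group {label!r} has n = {arr.size}; at least 2 observations needed"
        )
    return GroupSummary(label=label, n=int(arr.size), mean=float(arr.mean()),
                        sem=float(arr.std(ddof=1) / math.sqrt(arr.size)))


def two_sample_t(xs: Sequence[float], ys: Sequence[float],
                 variant: str = "student", alpha: float = DEFAULT_ALPHA) -> TestResult:
    """Two-sided two-sample t-test.

    ``student`` pools variances (df = n₁ + n₂ − 2); ``welch`` uses the
    Satterthwaite df.  Degenerate zero-variance samples follow the limiting
    convention: equal means → t = 0, p = 1; unequal means → infinite t,
    p = 0 (significant).
    """
    if variant not in T_VARIANTS:
        raise ValueError(f"unknown t-test variant {variant!r}")
    xs = np.asarray(list(xs), dtype=float)
    ys = np.asarray(list(ys), dtype=float)
    if xs.size < 2 or ys.size < 2:
        raise SampleSizeError("both samples need n >= 2 for a t-test")
    if xs.std() == 0.0 and ys.std() == 0.0:
        if xs.mean() == ys.mean():
            t, p = 0.0, 1.0
        else:
            t = math.inf if xs.mean() > ys.mean() else -math.inf
            p = 0.0
        df = xs.size + ys.size - 2
        return TestResult(t, float(df), p, p < alpha, alpha, variant)
    res = sps.ttest_ind(xs, ys, equal_var=(variant == "student"))
    df = float(res.df)
    return TestResult(float(res.statistic), df, float(res.pvalue),
                      bool(res.pvalue < alpha), alpha, variant)


def compare_groups(values_a: Sequence[float], values_b: Sequence[float],
                   metric: str, label_a: str = "A", label_b: str = "B",
                   variant: str = "student", alpha: float = DEFAULT_ALPHA) -> GroupComparison:
    return GroupComparison(
        metric=metric,
        summary_a=summarize_group(values_a, label_a),
        summary_b=summarize_group(values_b, label_b),
        test=two_sample_t(values_a, values_b, variant=variant, alpha=alpha),
    )


def compare_metric(trees_a: Sequence[NeuronTree], trees_b: Sequence[NeuronTree],
                   metric: str | Callable[[NeuronTree], float],
                   label_a: str = "A", label_b: str = "B",
                   variant: str = "student", alpha: float = DEFAULT_ALPHA,
                   volume_mode: str = "box") -> GroupComparison:
    """Extract one scalar metric per neuron from each cohort, then compare."""
    if callable(metric):
        extractor, name = metric, getattr(metric, "__name__", "custom")
    else:
        if metric not in METRICS:
            raise ValueError(f"unknown metric {metric!r}; expected one of {sorted(METRICS)}")
        name = metric
        if metric == "spatial_volume":
            extractor = lambda t: morphometry.spatial_volume(t, mode=volume_mode)
        else:
            extractor = METRICS[metric]
    va = [extractor(t) for t in trees_a]
    vb = [extractor(t) for t in trees_b]
    return compare_groups(va, vb, name, label_a, label_b, variant, alpha)


def _holm(pvalues: list[float], alpha: float) -> list[bool]:
    from statsmodels.stats.multitest import multipletests
    reject, *_ = multipletests(pvalues, alpha=alpha, method="holm")
    return list(reject)


def compare_sholl(profiles_a: Sequence[ShollProfile], profiles_b: Sequence[ShollProfile],
                  mode: str = "per_shell",
                  ranges: Sequence[tuple[float, float]] | None = None,
                  label_a: str = "A", label_b: str = "B",
                  variant: str = "student", alpha: float = DEFAULT_ALPHA,
                  holm: bool = False) -> list[GroupComparison]:
    """Compare two cohorts of Sholl profiles.

    ``per_shell``: one t-test per radius on the zero-padded common shell
    grid (metric names ``sholl_shell@r``).  ``range``: per-neuron sums over
    each requested radial range, one test per range
    (``sholl_range@lo-hi``).  No multiplicity correction unless ``holm``.
    """
    if mode not in ("per_shell", "range"):
        raise ValueError(f"unknown mode {mode!r}")
    profiles = list(profiles_a) + list(profiles_b)
    grid = common_grid(profiles)
    comparisons: list[GroupComparison] = []
    if mode == "per_shell":
        mat_a = np.array([p.padded(grid).intersections for p in profiles_a], dtype=float)
        mat_b = np.array([p.padded(grid).intersections for p in profiles_b], dtype=float)
        for k, r in enumerate(grid):
            comparisons.append(compare_groups(
                mat_a[:, k], mat_b[:, k], f"sholl_shell@{r:g}",
                label_a, label_b, variant, alpha))
    else:
        if not ranges:
            raise ValueError("range mode requires at least one (lo, hi) range")
        for lo, hi in ranges:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # snap warnings handled per profile
                va = [aggregate_range(p, lo, hi) for p in profiles_a]
                vb = [aggregate_range(p, lo, hi) for p in profiles_b]
            comparisons.append(compare_groups(
                va, vb, f"sholl_range@{lo:g}-{hi:g}",
                label_a, label_b, variant, alpha))
    if len(comparisons) > 1 and not holm:
        warnings.warn(
            f"{len(comparisons)} uncorrected comparisons; consider holm=True",
            stacklevel=2)
    if holm:
        rejects = _holm([c.test.p_value for c in comparisons], alpha)
        comparisons = [
            GroupComparison(c.metric, c.summary_a, c.summary_b,
                            TestResult(c.test.t_statistic, c.test.degrees_of_freedom,
                                       c.test.p_value, rej, alpha, c.test.variant))
            for c, rej in zip(comparisons, rejects)
        ]
    return comparisons


def sholl_profiles(trees: Iterable[NeuronTree],
                   config: ShollConfig | None = None) -> list[ShollProfile]:
    cfg = config or ShollConfig()
    return [sholl_profile(t, cfg) for t in trees]


def comparisons_table(comparisons: Iterable[GroupComparison]) -> pd.DataFrame:
    """Flatten comparisons into the report schema."""
    rows = []
    for c in comparisons:
        rows.append({
            "metric": c.metric,
            "group_a": c.summary_a.label, "n_a": c.summary_a.n,
            "mean_a": c.summary_a.mean, "sem_a": c.summary_a.sem,
            "group_b": c.summary_b.label, "n_b": c.summary_b.n,
            "mean_b": c.summary_b.mean, "sem_b": c.summary_b.sem,
            "t": c.test.t_statistic, "df": c.test.degrees_of_freedom,
            "p": c.test.p_value, "significant": c.test.significant,
            "variant": c.test.variant,
        })
    return pd.DataFrame(rows)
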