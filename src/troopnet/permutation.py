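"""Resampling nulls for class-level metric comparison.

``selective_node_permutation`` enumerates every fixed-size subset of a
class and records the subset means, producing the simulated metric
distribution used to compare age classes.  ``bootstrap_class_means``
resamples class members with replacement.  Note that comparing two
subset-mean distributions with a rank-sum test is anti-conservative
(the subset means are heavily correlated); a warning is logged and the
result is best read descriptively.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .knockout import n_combinations
from .stats_results import TestResult

__all__ = [
    "MetricDistribution",
    "selective_node_permutation",
    "compare_class_distributions",
    "bootstrap_class_means",
]

logger = logging.getLogger(__name__)

REFERENCE_CLASS_SIZE = 10  # the subset-of-5 design assumes 10-member classes


@dataclass
class MetricDistribution:
    """Distribution of subset-mean metric values for one class."""

    class_label: str
    values: np.ndarray
    subset_size: int
    exhaustive: bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(self.values.mean())


def selective_node_permutation(
    metric_values: Mapping[str, float],
    class_ids: Sequence[str],
    subset_size: int = 5,
    class_label: str = "",
) -> MetricDistribution:
    """Means of the metric over every size-``subset_size`` subset of a class."""
    class_ids = list(class_ids)
    missing = [i for i in class_ids if i not in metric_values]
    if missing:
        raise ValueError(f"metric missing for class members: {missing}")
    if subset_size > len(class_ids):
        raise ValueError(
            f"subset_size {subset_size} exceeds class size {len(class_ids)}"
        )
    if len(class_ids) != REFERENCE_CLASS_SIZE:
        logger.warning(
            "selective node permutation on a class of %d members "
            "(the subset-of-%d design assumes %d)",
            len(class_ids), subset_size, REFERENCE_CLASS_SIZE,
        )
    vals = np.array([float(metric_values[i]) for i in class_ids])
    means = [vals[list(idx)].mean() for idx in combinations(range(len(vals)), subset_size)]
    dist = MetricDistribution(
        class_label=class_label or "class",
        values=np.array(means),
        subset_size=subset_size,
        exhaustive=True,
    )
    assert len(dist) == n_combinations(len(class_ids), subset_size)
    return dist


def compare_class_distributions(
    dist_a: MetricDistribution,
    dist_b: MetricDistribution,
) -> TestResult:
    """Two-sided Wilcoxon rank-sum comparison of two simulated distributions.

    Also reports a Shapiro-Wilk normality p-value for each distribution in
    ``notes`` (most simulated subset-mean distributions are non-normal).
    If both distributions are the same constant the comparison is
    degenerate and p = 1 is reported with a flag.
    """
    a, b = dist_a.values, dist_b.values
    if len(a) == 0 or len(b) == 0:
        raise ValueError("distributions must be non-empty")
    notes: dict[str, object] = {
        "class_a": dist_a.class_label,
        "class_b": dist_b.class_label,
        "n_a": len(a),
        "n_b": len(b),
        "anticonservative": True,
    }
    for name, vals in (("shapiro_p_a", a), ("shapiro_p_b", b)):
        if len(vals) >= 3 and np.ptp(vals) > 0:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                notes[name] = float(stats.shapiro(vals).pvalue)
        else:
            notes[name] = None
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        notes["degenerate"] = True
        return TestResult("wilcoxon_rank_sum", 0.0, None, 1.0, notes)
    stat, p = stats.ranksums(a, b)
    return TestResult("wilcoxon_rank_sum", float(stat), None, float(p), notes)


def bootstrap_class_means(
    metric_values: Mapping[str, float],
    class_ids: Sequence[str],
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """``n_boot`` bootstrap means of a class's metric values.

    Each resample draws ``len(class_ids)`` members with replacement.
    Deterministic given ``seed``.
    """
    class_ids = list(class_ids)
    if len(class_ids) < 2:
        raise ValueError("bootstrap requires at least 2 class members")
    missing = [i for i in class_ids if i not in metric_values]
    if missing:
        raise ValueError(f"metric missing for class members: {missing}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vals = np.array([float(metric_values[i]) for i in class_ids])
    idx = rng.integers(0, len(vals), size=(n_boot, len(vals)))
    return vals[idx].mean(axis=1)
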