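"""Statistical tests used by the analysis pipeline.

Standard tests (Kruskal-Wallis, Mann-Whitney, Welch t, Levene,
Shapiro-Wilk) wrap :mod:`scipy.stats` and return a uniform
:class:`TestResult`.  The Scheirer-Ray-Hare rank-based factorial test and
the slope-equality comparison are implemented here directly.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy import stats as sps
from scipy.stats import rankdata

from .stats_results import TestResult

__all__ = [
    "TestResult",
    "kruskal_wallis",
    "scheirer_ray_hare",
    "mann_whitney",
    "compare_slopes",
    "t_test_bootstrap",
    "variance_diagnostics",
]


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Tie-corrected Kruskal-Wallis H test across ``k`` groups (df = k - 1)."""
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis requires at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrays):
        if g.size == 0:
            raise ValueError(f"group {i} is empty")
    df = len(arrays) - 1
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return TestResult("kruskal_wallis", 0.0, df, 1.0, {"degenerate": True})
    stat, p = sps.kruskal(*arrays)
    return TestResult("kruskal_wallis", float(stat), df, float(p),
                      {"n_groups": len(arrays), "n_total": pooled.size})


def _effect_ss(ranks: np.ndarray, labels: np.ndarray) -> float:
    """Between-level sum of squares of ranks for one factor/cell labelling."""
    grand = ranks.mean()
    ss = 0.0
    for lev in np.unique(labels):
        r = ranks[labels == lev]
        ss += r.size * (r.mean() - grand) ** 2
    return ss


def scheirer_ray_hare(
    values: Sequence[float],
    factor_a: Sequence,
    factor_b: Sequence,
) -> dict[str, TestResult]:
    """Scheirer-Ray-Hare rank-based two-way factorial test.

    All values are ranked jointly (midranks for ties); sums of squares of
    the ranks are computed for each main effect and the interaction, and
    each effect's H = SS_effect / MS_total is referred to a chi-square
    distribution with the effect's df, where MS_total is the variance of
    all ranks (denominator N - 1).  Returns results keyed ``"A"``,
    ``"B"`` and ``"interaction"``.
    """
    values = np.asarray(values, dtype=float)
    factor_a = np.asarray(factor_a)
    factor_b = np.asarray(factor_b)
    if not (len(values) == len(factor_a) == len(factor_b)):
        raise ValueError("values and factors must have equal length")
    levels_a = np.unique(factor_a)
    levels_b = np.unique(factor_b)
    if len(levels_a) < 2 and len(levels_b) < 2:
        raise ValueError("at least one factor must have 2 or more levels")
    # complete layout: every combination of levels observed
    cells = {(a, b) for a, b in zip(factor_a, factor_b)}
    for a in levels_a:
        for b in levels_b:
            if (a, b) not in cells:
                raise ValueError(f"incomplete layout: no observations in cell ({a}, {b})")

    ranks = rankdata(values)
    n = ranks.size
    ms_total = ranks.var(ddof=1)
    df_a = len(levels_a) - 1
    df_b = len(levels_b) - 1
    df_ab = df_a * df_b

    if ms_total == 0:  # all values tied: nothing to test
        h_a = h_b = h_ab = 0.0
    else:
        ss_a = _effect_ss(ranks, factor_a)
        ss_b = _effect_ss(ranks, factor_b)
        cell_labels = np.array([f"{a}\x00{b}" for a, b in zip(factor_a, factor_b)])
        ss_cells = _effect_ss(ranks, cell_labels)
        ss_ab = max(ss_cells - ss_a - ss_b, 0.0)
        h_a = ss_a / ms_total
        h_b = ss_b / ms_total
        h_ab = ss_ab / ms_total

    def result(name: str, h: float, df: int) -> TestResult:
        if df == 0:
            return TestResult(f"scheirer_ray_hare[{name}]", 0.0, 0, 1.0,
                              {"degenerate": True})
        p = 1.0 if ms_total == 0 else float(sps.chi2.sf(h, df))
        return TestResult(f"scheirer_ray_hare[{name}]", float(h), df, p,
                          {"n_total": int(n)})

    return {
        "A": result("A", h_a, df_a),
        "B": result("B", h_b, df_b),
        "interaction": result("AxB", h_ab, df_ab),
    }


def mann_whitney(group_a: Sequence[float], group_b: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test (exact for small tie-free samples)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return TestResult(
        "mann_whitney_u",
        float(res.statistic),
        None,
        float(res.pvalue),
        {"n_a": int(a.size), "n_b": int(b.size)},
    )


def compare_slopes(
    series_a: Sequence[tuple[float, float]],
    series_b: Sequence[tuple[float, float]],
) -> TestResult:
    """Test equality of the least-squares slopes of two (step, mean) series.

    Fits the stacked model ``y ~ step + series + step:series`` and reports
    the F statistic of the interaction term with df (1, n_a + n_b - 4).
    The per-series slopes and their difference are returned in ``notes``.
    Note this df convention follows from the stacked regression itself.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != 2 or b.shape[1] != 2:
        raise ValueError("series must be sequences of (step, mean) pairs")
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each series needs at least 3 points")
    x = np.concatenate([a[:, 0], b[:, 0]])
    y = np.concatenate([a[:, 1], b[:, 1]])
    g = np.concatenate([np.zeros(len(a)), np.ones(len(b))])
    X = np.column_stack([np.ones_like(x), x, g, x * g])
    n, k = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < k:
        raise ValueError("design matrix is rank deficient (degenerate step grid)")
    resid = y - X @ beta
    df_resid = n - k
    sse = float(resid @ resid)
    slope_a = float(beta[1])
    slope_diff = float(beta[3])
    notes = {
        "slope_a": slope_a,
        "slope_b": slope_a + slope_diff,
        "slope_difference": slope_diff,
    }
    scale = max(1.0, float(y @ y))
    if sse <= 1e-24 * scale:  # noiseless fit
        if abs(slope_diff) <= 1e-12 * max(1.0, abs(slope_a)):
            return TestResult("slope_comparison_f", 0.0, (1, df_resid), 1.0,
                              {**notes, "degenerate": True})
        tiny = float(np.finfo(float).tiny)
        return TestResult("slope_comparison_f", math.inf, (1, df_resid), tiny,
                          {**notes, "noiseless": True})
    mse = sse / df_resid
    xtx_inv = np.linalg.inv(X.T @ X)
    se = math.sqrt(mse * xtx_inv[3, 3])
    f_stat = (slope_diff / se) ** 2
    p = float(sps.f.sf(f_stat, 1, df_resid))
    return TestResult("slope_comparison_f", float(f_stat), (1, df_resid), p, notes)


def t_test_bootstrap(boot_a: Sequence[float], boot_b: Sequence[float]) -> TestResult:
    """Welch two-sample t test on two bootstrap-mean distributions.

    Testing bootstrap distributions directly is anti-conservative (their
    size is the resampling budget, not the sample size); flagged in notes.
    """
    a = np.asarray(boot_a, dtype=float)
    b = np.asarray(boot_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sequence needs at least 2 values")
    notes: dict[str, object] = {"n_a": int(a.size), "n_b": int(b.size),
                                "anticonservative": True}
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        notes["degenerate"] = True
        if a.mean() == b.mean():
            return TestResult("welch_t", 0.0, float(a.size + b.size - 2), 1.0, notes)
        return TestResult("welch_t", math.inf, float(a.size + b.size - 2),
                          float(np.finfo(float).tiny), notes)
    res = sps.ttest_ind(a, b, equal_var=False)
    return TestResult("welch_t", float(res.statistic), float(res.df),
                      float(res.pvalue), notes)


def variance_diagnostics(
    groups: Sequence[Sequence[float]],
) -> dict[str, object]:
    """Levene (median-centred) plus per-group Shapiro-Wilk diagnostics.

    Used to decide whether to route the analysis to nonparametric tests.
    Groups too small or constant get ``None`` in place of a Shapiro
    result; Levene is ``None`` when fewer than two usable groups exist.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    shapiro_results: list[TestResult | None] = []
    for g in arrays:
        if g.size < 3 or np.ptp(g) == 0:
            shapiro_results.append(None)
        else:
            res = sps.shapiro(g)
            shapiro_results.append(
                TestResult("shapiro_wilk", float(res.statistic), None,
                           float(res.pvalue), {"n": int(g.size)})
            )
    levene_result: TestResult | None = None
    usable = [g for g in arrays if g.size >= 2]
    if len(usable) >= 2 and np.ptp(np.concatenate(usable)) > 0:
        res = sps.levene(*usable, center="median")
        k = len(usable)
        n_tot = sum(g.size for g in usable)
        levene_result = TestResult("levene", float(res.statistic),
                                   (k - 1, n_tot - k), float(res.pvalue),
                                   {"center": "median"})
    return {"levene": levene_result, "shapiro": shapiro_results}
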