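"""Stepwise node-removal (knockout) simulation engine.

Three removal schemes are provided: exhaustive targeted removal of a
fixed class of nodes, random control removals with an exhaustive
fallback when the subset space is smaller than the iteration budget
(avoiding pseudoreplication), and class-effect removals that track
per-age-sex-class mean betweenness and clustering while one class is
progressively deleted.  Removal means node deletion with all incident
edges; remaining edge weights are hourly rates per dyad and are not
re-normalized.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data_model import SocialNetwork
from .metrics import (
    global_metrics,
    weighted_betweenness,
    weighted_local_clustering,
)

__all__ = [
    "n_combinations",
    "KnockoutTrajectory",
    "targeted_knockout",
    "random_knockout",
    "class_effect_knockout",
    "betweenness_rank_table",
    "MIN_SURVIVING_NODES",
]

logger = logging.getLogger(__name__)

#: smallest network on which the global metrics remain defined
MIN_SURVIVING_NODES = 3


def n_combinations(n: int, r: int) -> int:
    """Exact n! / (r!(n-r)!)."""
    if n < 0 or r < 0:
        raise ValueError(f"n and r must be non-negative (got n={n}, r={r})")
    if r > n:
        raise ValueError(f"r must not exceed n (got n={n}, r={r})")
    return math.comb(n, r)


@dataclass
class KnockoutTrajectory:
    """Per-step, per-replicate metric values under a removal scheme.

    ``records`` is a long table with columns ``step``, ``replicate``,
    ``removed`` (semicolon-joined ids) plus one column per metric.
    """

    scheme: str
    records: pd.DataFrame
    exhaustive_steps: tuple[int, ...] = ()

    @property
    def metric_names(self) -> list[str]:
        return [c for c in self.records.columns if c not in ("step", "replicate", "removed")]

    def replicates_at(self, step: int) -> int:
        return int((self.records["step"] == step).sum())

    def values_at(self, step: int, metric: str) -> np.ndarray:
        return self.records.loc[self.records["step"] == step, metric].to_numpy()

    def summary(self) -> pd.DataFrame:
        """Mean, standard error (SD/sqrt(replicates)) and count per step/metric."""
        long = self.to_long()
        grouped = long.groupby(["step", "metric"])["value"]
        out = grouped.agg(
            mean="mean",
            se=lambda v: v.std(ddof=1) / math.sqrt(len(v)) if len(v) > 1 else 0.0,
            n_replicates="size",
        ).reset_index()
        out.insert(0, "scheme", self.scheme)
        return out

    def to_long(self) -> pd.DataFrame:
        long = self.records.melt(
            id_vars=["step", "replicate", "removed"],
            var_name="metric",
            value_name="value",
        )
        long.insert(0, "scheme", self.scheme)
        return long


MetricFunc = Callable[[SocialNetwork], Mapping[str, float]]


def _default_metric_func(triplet_value: str = "arithmetic_mean") -> MetricFunc:
    def f(net: SocialNetwork) -> Mapping[str, float]:
        return global_metrics(net, triplet_value).as_dict()

    return f


def _evaluate_subsets(
    network: SocialNetwork,
    subsets_by_step: Mapping[int, Sequence[tuple[str, ...]]],
    metric_func: MetricFunc,
    scheme: str,
    exhaustive_steps: Iterable[int] = (),
    include_intact: bool = True,
) -> KnockoutTrajectory:
    rows: list[dict] = []
    if include_intact:
        rows.append(
            {"step": 0, "replicate": 0, "removed": "", **metric_func(network)}
        )
    for step in sorted(subsets_by_step):
        for rep, subset in enumerate(subsets_by_step[step]):
            reduced = network.without_nodes(subset)
            rows.append(
                {
                    "step": step,
                    "replicate": rep,
                    "removed": ";".join(sorted(subset)),
                    **metric_func(reduced),
                }
            )
    return KnockoutTrajectory(
        scheme=scheme,
        records=pd.DataFrame(rows),
        exhaustive_steps=tuple(sorted(exhaustive_steps)),
    )


def targeted_knockout(
    network: SocialNetwork,
    target_ids: Iterable[str],
    r_max: int | None = None,
    metric_func: MetricFunc | None = None,
    scheme: str = "targeted",
    include_intact: bool = True,
) -> KnockoutTrajectory:
    """Exhaustive stepwise removal of ``target_ids``.

    At each step r in 1..r_max every size-r subset of the targets is
    removed from a fresh copy of the network and the metrics recomputed,
    giving C(|targets|, r) replicates per step.  Steps that would leave
    fewer than :data:`MIN_SURVIVING_NODES` nodes are skipped with a
    warning.
    """
    targets = sorted(set(target_ids))
    missing = set(targets) - set(network.nodes)
    if missing:
        raise ValueError(f"target ids not in network: {sorted(missing)}")
    if r_max is None:
        r_max = len(targets)
    if not 1 <= r_max <= len(targets):
        raise ValueError(f"r_max must be in 1..{len(targets)}, got {r_max}")
    metric_func = metric_func or _default_metric_func()

    subsets_by_step: dict[int, list[tuple[str, ...]]] = {}
    steps_done = []
    for r in range(1, r_max + 1):
        if network.n_nodes - r < MIN_SURVIVING_NODES:
            logger.warning(
                "skipping step %d of scheme %r: fewer than %d nodes would survive",
                r, scheme, MIN_SURVIVING_NODES,
            )
            continue
        subsets_by_step[r] = list(combinations(targets, r))
        steps_done.append(r)
        logger.info("scheme %r step %d: %d exhaustive subsets",
                    scheme, r, len(subsets_by_step[r]))
    return _evaluate_subsets(
        network, subsets_by_step, metric_func, scheme,
        exhaustive_steps=steps_done, include_intact=include_intact,
    )


def _draw_subsets(
    pool: Sequence[str],
    r: int,
    n_iterations: int,
    rng: np.random.Generator,
    exhaustive_if_fewer: bool,
) -> tuple[list[tuple[str, ...]], bool]:
    """Subsets for one step: all of them, or ``n_iterations`` random draws.

    ``exhaustive_if_fewer`` selects strict ``C(n,r) < n_iterations``
    (random control convention) vs ``C(n,r) <= n_iterations`` (class-effect
    convention) as the fallback trigger.
    """
    n_comb = n_combinations(len(pool), r)
    exhaustive = n_comb < n_iterations if exhaustive_if_fewer else n_comb <= n_iterations
    if exhaustive:
        return list(combinations(sorted(pool), r)), True
    subsets = [
        tuple(sorted(rng.choice(pool, size=r, replace=False)))
        for _ in range(n_iterations)
    ]
    return subsets, False


def random_knockout(
    network: SocialNetwork,
    r_max: int,
    n_iterations: int = 500,
    seed: int | np.random.Generator | None = None,
    metric_func: MetricFunc | None = None,
    scheme: str = "random",
    include_intact: bool = True,
) -> KnockoutTrajectory:
    """Random control removals: ``n_iterations`` uniform subsets per step.

    Whenever C(n, r) < ``n_iterations`` all subsets are enumerated instead
    (no pseudoreplication).  Deterministic given ``seed``.
    """
    n = network.n_nodes
    if not 1 <= r_max <= n - MIN_SURVIVING_NODES:
        raise ValueError(
            f"r_max must leave at least {MIN_SURVIVING_NODES} nodes "
            f"(valid range 1..{n - MIN_SURVIVING_NODES}, got {r_max})"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    metric_func = metric_func or _default_metric_func()
    pool = sorted(network.nodes)
    subsets_by_step = {}
    exhaustive_steps = []
    for r in range(1, r_max + 1):
        subsets, exhaustive = _draw_subsets(pool, r, n_iterations, rng,
                                            exhaustive_if_fewer=True)
        subsets_by_step[r] = subsets
        if exhaustive:
            exhaustive_steps.append(r)
        logger.info("scheme %r step %d: %d %s subsets", scheme, r, len(subsets),
                    "exhaustive" if exhaustive else "random")
    return _evaluate_subsets(
        network, subsets_by_step, metric_func, scheme,
        exhaustive_steps=exhaustive_steps, include_intact=include_intact,
    )


def class_effect_knockout(
    network: SocialNetwork,
    removal_ids: Iterable[str],
    class_map: Mapping[str, str],
    tracked_classes: Sequence[str] = ("adult_male", "adult_female", "subadult_female"),
    r_max: int | None = None,
    n_iterations: int = 50,
    seed: int | np.random.Generator | None = None,
    alpha: float = 0.5,
    triplet_value: str = "arithmetic_mean",
    include_intact: bool = True,
) -> KnockoutTrajectory:
    """Track per-class mean betweenness and clustering while removing a class.

    At each step r, ``n_iterations`` random size-r subsets of
    ``removal_ids`` are deleted (all subsets when C(n, r) <=
    ``n_iterations``); for each replicate the mean weighted betweenness
    and mean local clustering of the surviving members of every tracked
    class are recorded as ``betweenness[<class>]`` / ``clustering[<class>]``.
    Empty classes yield NaN.
    """
    removal = sorted(set(removal_ids))
    missing = set(removal) - set(network.nodes)
    if missing:
        raise ValueError(f"removal ids not in network: {sorted(missing)}")
    unmapped = set(network.nodes) - set(removal) - set(class_map)
    if unmapped:
        raise ValueError(f"nodes missing from class_map: {sorted(unmapped)}")
    if r_max is None:
        r_max = len(removal)
    if not 1 <= r_max <= len(removal):
        raise ValueError(f"r_max must be in 1..{len(removal)}, got {r_max}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    def metric_func(net: SocialNetwork) -> dict[str, float]:
        btw = weighted_betweenness(net, alpha=alpha)
        clu = weighted_local_clustering(net, triplet_value)
        out = {}
        for cls in tracked_classes:
            members = [v for v in net.nodes if class_map.get(v) == cls]
            if members:
                out[f"betweenness[{cls}]"] = float(btw[members].mean())
                clu_vals = clu[members].dropna()
                out[f"clustering[{cls}]"] = (
                    float(clu_vals.mean()) if len(clu_vals) else math.nan
                )
            else:
                out[f"betweenness[{cls}]"] = math.nan
                out[f"clustering[{cls}]"] = math.nan
        return out

    subsets_by_step = {}
    exhaustive_steps = []
    for r in range(1, r_max + 1):
        if network.n_nodes - r < MIN_SURVIVING_NODES:
            logger.warning("skipping class-effect step %d: too few survivors", r)
            continue
        subsets, exhaustive = _draw_subsets(removal, r, n_iterations, rng,
                                            exhaustive_if_fewer=False)
        subsets_by_step[r] = subsets
        if exhaustive:
            exhaustive_steps.append(r)
    return _evaluate_subsets(
        network, subsets_by_step, metric_func, "class_effect",
        exhaustive_steps=exhaustive_steps, include_intact=include_intact,
    )


def betweenness_rank_table(
    network_full: SocialNetwork,
    network_reduced: SocialNetwork,
    alpha: float = 0.5,
    top_n: int = 5,
) -> pd.DataFrame:
    """Betweenness ranks of shared individuals with and without the others.

    Rank 1 is the most central individual; ties share the midrank.  The
    returned frame (one row per individual present in both networks) has
    columns ``rank_full``, ``rank_reduced``, ``rank_change`` (positive =
    more central after removal) and ``age_sex``; the identities of the
    ``top_n`` most central individuals in each network are stored in
    ``df.attrs["top_full"]`` and ``df.attrs["top_reduced"]``.
    """
    shared = [v for v in network_full.nodes if v in set(network_reduced.nodes)]
    if not shared:
        raise ValueError("networks share no nodes")
    btw_full = weighted_betweenness(network_full, alpha=alpha)
    btw_red = weighted_betweenness(network_reduced, alpha=alpha)

    def ranks(series: pd.Series) -> pd.Series:
        return pd.Series(rankdata(-series.to_numpy(), method="average"),
                         index=series.index)

    rank_full_all = ranks(btw_full)
    rank_red_all = ranks(btw_red)
    df = pd.DataFrame(
        {
            "age_sex": [network_full.node_class(v) for v in shared],
            "betweenness_full": btw_full[shared],
            "betweenness_reduced": btw_red[shared],
            "rank_full": rank_full_all[shared],
            "rank_reduced": rank_red_all[shared],
        },
        index=pd.Index(shared, name="id"),
    )
    df["rank_change"] = df["rank_full"] - df["rank_reduced"]
    df.attrs["top_full"] = list(btw_full.sort_values(ascending=False).index[:top_n])
    df.attrs["top_reduced"] = list(btw_red.sort_values(ascending=False).index[:top_n])
    return df
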