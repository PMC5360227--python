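"""End-to-end orchestration of the three analysis aims.

Aim 1 compares individual metrics between juveniles and adults using
selective node permutation.  Aim 2 quantifies how stepwise targeted
(adult / juvenile) and random removals change global network structure.
Aim 3 tracks how juvenile removal shifts the apparent metrics, slopes and
betweenness ranks of the remaining age-sex classes.  Every stage is
deterministic given the config seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    AgeClass,
    Behaviour,
    InteractionEvent,
    Normalization,
    ObservationEffort,
    Roster,
    SocialNetwork,
    build_aggression_network,
    build_grooming_network,
    merge_grooming_bouts,
)
from .knockout import (
    KnockoutTrajectory,
    betweenness_rank_table,
    class_effect_knockout,
    random_knockout,
    targeted_knockout,
)
from .metrics import node_metrics
from .permutation import (
    bootstrap_class_means,
    compare_class_distributions,
    selective_node_permutation,
)
from .stats import compare_slopes, kruskal_wallis, mann_whitney, scheirer_ray_hare, t_test_bootstrap

__all__ = ["AnalysisConfig", "build_networks", "run_aim1", "run_aim2", "run_aim3", "run_all"]

logger = logging.getLogger(__name__)

INDIVIDUAL_METRICS = ["in_degree", "out_degree", "in_strength", "out_strength",
                      "betweenness", "clustering"]
GLOBAL_METRICS = ["density", "degree_centralization", "mean_clustering"]


@dataclass
class AnalysisConfig:
    """Tunable parameters of the full analysis."""

    seed: int = 0
    normalization: str = Normalization.DYAD_HOURS.value
    alpha: float = 0.5
    triplet_value: str = "arithmetic_mean"
    bout_gap_s: float = 30.0
    subset_size: int = 5
    r_max: int = 10
    n_random_iterations: int = 500
    n_class_iterations: int = 50
    n_boot: int = 1000
    tracked_classes: tuple[str, ...] = ("adult_male", "adult_female", "subadult_female")

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def child_seeds(self, n: int) -> list[np.random.Generator]:
        return [np.random.default_rng(s) for s in np.random.SeedSequence(self.seed).spawn(n)]


def build_networks(
    roster: Roster,
    effort: ObservationEffort,
    events: Sequence[InteractionEvent],
    config: AnalysisConfig | None = None,
) -> dict[str, SocialNetwork]:
    """Grooming and aggression networks from a raw event table."""
    config = config or AnalysisConfig()
    grooming = sorted(
        (e for e in events if e.behaviour is Behaviour.GROOMING),
        key=lambda e: (e.actor, e.recipient, e.start_time_s),
    )
    aggression = [e for e in events if e.behaviour is Behaviour.AGGRESSION]
    bouts = merge_grooming_bouts(grooming, max_gap_s=config.bout_gap_s)
    return {
        "grooming": build_grooming_network(bouts, effort, roster, config.normalization),
        "aggression": build_aggression_network(aggression, effort, roster, config.normalization),
    }


def _age_class_ids(roster: Roster, age_class: AgeClass) -> list[str]:
    return roster.ids_in_class(age_class)


# ---------------------------------------------------------------------------
# aim 1: juvenile vs adult individual metrics
# ---------------------------------------------------------------------------

def run_aim1(
    networks: Mapping[str, SocialNetwork],
    roster: Roster,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Class-comparison table: one row per (network, metric).

    Reports juvenile and adult means and ranges, the rank-sum p-value of
    the selective-permutation subset-mean distributions (the descriptive
    comparison; anti-conservative by construction) and a plain
    Mann-Whitney p-value on the raw per-individual values (calibrated).
    """
    config = config or AnalysisConfig()
    juveniles = _age_class_ids(roster, AgeClass.JUVENILE)
    adults = _age_class_ids(roster, AgeClass.ADULT)
    rows = []
    for net_name, net in networks.items():
        table = node_metrics(net, alpha=config.alpha, triplet_value=config.triplet_value)
        for metric in INDIVIDUAL_METRICS:
            vals = table[metric].dropna()
            juv_vals = vals[vals.index.intersection(juveniles)]
            adu_vals = vals[vals.index.intersection(adults)]
            row = {
                "network": net_name,
                "metric": metric,
                "juvenile_mean": juv_vals.mean(),
                "juvenile_min": juv_vals.min(),
                "juvenile_max": juv_vals.max(),
                "adult_mean": adu_vals.mean(),
                "adult_min": adu_vals.min(),
                "adult_max": adu_vals.max(),
            }
            if min(len(juv_vals), len(adu_vals)) < config.subset_size:
                row.update(permutation_p=np.nan, mann_whitney_p=np.nan,
                           flag="class smaller than subset size")
            else:
                value_map = vals.to_dict()
                dist_j = selective_node_permutation(
                    value_map, list(juv_vals.index), config.subset_size, "juvenile")
                dist_a = selective_node_permutation(
                    value_map, list(adu_vals.index), config.subset_size, "adult")
                perm = compare_class_distributions(dist_j, dist_a)
                mw = mann_whitney(juv_vals.to_numpy(), adu_vals.to_numpy())
                row.update(
                    permutation_stat=perm.statistic,
                    permutation_p=perm.p_value,
                    permutation_n=len(dist_j),
                    mann_whitney_p=mw.p_value,
                    flag="",
                )
            rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["config_hash"] = config.hash()
    return out


# ---------------------------------------------------------------------------
# aim 2: knockout effects on global structure
# ---------------------------------------------------------------------------

def run_aim2(
    networks: Mapping[str, SocialNetwork],
    roster: Roster,
    config: AnalysisConfig | None = None,
) -> dict[str, object]:
    """Knockout test tables for every network.

    Returns trajectories per scheme, per-scheme Kruskal-Wallis tables over
    removal steps, the rank-based factorial (adult vs juvenile removal)
    table with interaction, and per-step Mann-Whitney post-hocs.
    """
    config = config or AnalysisConfig()
    juveniles = _age_class_ids(roster, AgeClass.JUVENILE)
    adults = _age_class_ids(roster, AgeClass.ADULT)
    rngs = iter(config.child_seeds(2 * len(networks)))

    trajectories: dict[str, dict[str, KnockoutTrajectory]] = {}
    kw_rows, srh_rows, mw_rows, summaries = [], [], [], []
    for net_name, net in networks.items():
        trajs = {
            "juveniles_removed": targeted_knockout(
                net, juveniles, r_max=min(config.r_max, len(juveniles)),
                scheme="juveniles_removed"),
            "adults_removed": targeted_knockout(
                net, adults, r_max=min(config.r_max, len(adults)),
                scheme="adults_removed"),
            "random_removed": random_knockout(
                net, r_max=min(config.r_max, net.n_nodes - 3),
                n_iterations=config.n_random_iterations,
                seed=next(rngs), scheme="random_removed"),
        }
        trajectories[net_name] = trajs
        for scheme, traj in trajs.items():
            summary = traj.summary()
            summary.insert(0, "network", net_name)
            summaries.append(summary)
            for metric in GLOBAL_METRICS:
                groups = [
                    traj.values_at(step, metric)
                    for step in sorted(traj.records["step"].unique())
                ]
                groups = [g[~np.isnan(g)] for g in groups]
                groups = [g for g in groups if len(g)]
                res = kruskal_wallis(groups)
                kw_rows.append({
                    "network": net_name, "scheme": scheme, "metric": metric,
                    "chi2": res.statistic, "df": res.df, "p_value": res.p_value,
                })
        # factorial comparison: adult-removal vs juvenile-removal categories
        for metric in GLOBAL_METRICS:
            frames = []
            for category in ("adults_removed", "juveniles_removed"):
                rec = trajs[category].records[["step", metric]].copy()
                rec["category"] = category
                frames.append(rec)
            data = pd.concat(frames).dropna(subset=[metric])
            srh = scheirer_ray_hare(
                data[metric].to_numpy(), data["step"].to_numpy(), data["category"].to_numpy()
            )
            for effect, label in (("A", "removal_steps"), ("B", "removal_category"),
                                  ("interaction", "interaction")):
                srh_rows.append({
                    "network": net_name, "metric": metric, "effect": label,
                    "H": srh[effect].statistic, "df": srh[effect].df,
                    "p_value": srh[effect].p_value,
                })
            for step in sorted(set(data["step"])):
                if step == 0:
                    continue
                a_vals = data.loc[(data["step"] == step) & (data["category"] == "adults_removed"), metric]
                j_vals = data.loc[(data["step"] == step) & (data["category"] == "juveniles_removed"), metric]
                if a_vals.empty or j_vals.empty:
                    continue
                mw = mann_whitney(a_vals.to_numpy(), j_vals.to_numpy())
                mw_rows.append({
                    "network": net_name, "metric": metric, "step": step,
                    "U": mw.statistic, "p_value": mw.p_value,
                })
    return {
        "trajectories": trajectories,
        "summaries": pd.concat(summaries, ignore_index=True),
        "kruskal_wallis": pd.DataFrame(kw_rows),
        "srh": pd.DataFrame(srh_rows),
        "mann_whitney": pd.DataFrame(mw_rows),
        "config_hash": config.hash(),
    }


# ---------------------------------------------------------------------------
# aim 3: class-specific effects of juvenile removal
# ---------------------------------------------------------------------------

def run_aim3(
    networks: Mapping[str, SocialNetwork],
    roster: Roster,
    config: AnalysisConfig | None = None,
) -> dict[str, object]:
    """Class-effect trajectories, slope comparisons, bootstrap t-tables and
    betweenness rank-change tables for the removal of juveniles."""
    config = config or AnalysisConfig()
    juveniles = _age_class_ids(roster, AgeClass.JUVENILE)
    if not juveniles:
        raise ValueError("aim 3 requires at least one juvenile in the roster")
    class_map = roster.class_map()
    # independent streams for the class knockouts and the bootstraps
    root = np.random.SeedSequence([config.seed, 3])
    rng_pool = iter(np.random.default_rng(s) for s in root.spawn(64))

    trajectories: dict[str, KnockoutTrajectory] = {}
    slope_rows, boot_rows, rank_tables = [], [], {}
    for net_name, net in networks.items():
        traj = class_effect_knockout(
            net, juveniles, class_map,
            tracked_classes=config.tracked_classes,
            r_max=min(config.r_max, len(juveniles)),
            n_iterations=config.n_class_iterations,
            seed=next(rng_pool),
            alpha=config.alpha,
            triplet_value=config.triplet_value,
        )
        trajectories[net_name] = traj
        summary = traj.summary()
        # slope comparisons on per-step means (removal steps only)
        for base_metric in ("betweenness", "clustering"):
            series = {}
            for cls in config.tracked_classes:
                col = f"{base_metric}[{cls}]"
                sub = summary[(summary["metric"] == col) & (summary["step"] > 0)]
                series[cls] = list(zip(sub["step"], sub["mean"]))
            for i, cls_a in enumerate(config.tracked_classes):
                for cls_b in config.tracked_classes[i + 1:]:
                    res = compare_slopes(series[cls_a], series[cls_b])
                    slope_rows.append({
                        "network": net_name, "metric": base_metric,
                        "class_a": cls_a, "class_b": cls_b,
                        "slope_a": res.notes["slope_a"],
                        "slope_b": res.notes["slope_b"],
                        "F": res.statistic, "df": str(res.df),
                        "p_value": res.p_value,
                    })
        # bootstrap before / after removal of all juveniles
        reduced = net.without_nodes(juveniles)
        full_tbl = node_metrics(net, alpha=config.alpha, triplet_value=config.triplet_value)
        red_tbl = node_metrics(reduced, alpha=config.alpha, triplet_value=config.triplet_value)
        for when, tbl in (("before", full_tbl), ("after", red_tbl)):
            for base_metric in ("betweenness", "clustering"):
                vals = tbl[base_metric].dropna().to_dict()
                boots = {}
                for cls in config.tracked_classes:
                    members = [i for i, lab in class_map.items()
                               if lab == cls and i in vals]
                    if len(members) >= 2:
                        boots[cls] = bootstrap_class_means(
                            vals, members, n_boot=config.n_boot,
                            seed=next(rng_pool))
                for i, cls_a in enumerate(config.tracked_classes):
                    for cls_b in config.tracked_classes[i + 1:]:
                        if cls_a not in boots or cls_b not in boots:
                            continue
                        res = t_test_bootstrap(boots[cls_a], boots[cls_b])
                        boot_rows.append({
                            "network": net_name, "metric": base_metric, "when": when,
                            "class_a": cls_a, "class_b": cls_b,
                            "t": res.statistic, "df": res.df, "p_value": res.p_value,
                        })
        rank_tables[net_name] = betweenness_rank_table(net, reduced, alpha=config.alpha)
    return {
        "trajectories": trajectories,
        "slopes": pd.DataFrame(slope_rows),
        "bootstrap_t": pd.DataFrame(boot_rows),
        "rank_tables": rank_tables,
        "config_hash": config.hash(),
    }


# ---------------------------------------------------------------------------
# full run + artifact writing
# ---------------------------------------------------------------------------

def run_all(
    roster: Roster,
    effort: ObservationEffort,
    events: Sequence[InteractionEvent],
    config: AnalysisConfig | None = None,
    output_dir: str | Path | None = None,
) -> dict[str, object]:
    """Build networks, run aims 1-3, optionally write artifact tables."""
    config = config or AnalysisConfig()
    networks = build_networks(roster, effort, events, config)
    results = {
        "networks": networks,
        "aim1": run_aim1(networks, roster, config),
        "aim2": run_aim2(networks, roster, config),
        "aim3": run_aim3(networks, roster, config),
        "config_hash": config.hash(),
    }
    if output_dir is not None:
        save_results(results, config, output_dir)
    return results


def save_results(results: Mapping[str, object], config: AnalysisConfig,
                 output_dir: str | Path) -> None:
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config": dataclasses.asdict(config), "config_hash": config.hash()}
    (out / "run_metadata.json").write_text(json.dumps(meta, indent=2, default=str))
    results["aim1"].to_csv(out / "aim1_class_comparison.csv", index=False)
    aim2 = results["aim2"]
    aim2["summaries"].to_csv(out / "aim2_trajectory_summaries.csv", index=False)
    aim2["kruskal_wallis"].to_csv(out / "aim2_kruskal_wallis.csv", index=False)
    aim2["srh"].to_csv(out / "aim2_factorial.csv", index=False)
    aim2["mann_whitney"].to_csv(out / "aim2_posthoc_mann_whitney.csv", index=False)
    for net_name, trajs in aim2["trajectories"].items():
        for scheme, traj in trajs.items():
            traj.to_long().to_csv(out / f"aim2_{net_name}_{scheme}_long.csv", index=False)
    aim3 = results["aim3"]
    aim3["slopes"].to_csv(out / "aim3_slope_comparisons.csv", index=False)
    aim3["bootstrap_t"].to_csv(out / "aim3_bootstrap_t.csv", index=False)
    for net_name, traj in aim3["trajectories"].items():
        traj.summary().assign(network=net_name).to_csv(
            out / f"aim3_{net_name}_class_trajectories.csv", index=False)
    for net_name, table in aim3["rank_tables"].items():
        table.assign(
            top_full=";".join(table.attrs["top_full"]),
            top_reduced=";".join(table.attrs["top_reduced"]),
        ).to_csv(out / f"aim3_{net_name}_betweenness_ranks.csv")


def plot_trajectories(summary: pd.DataFrame, path: str | Path) -> None:
    """One panel per (network, metric) of mean +/- SE trajectories per scheme."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    panels = summary.groupby(["network", "metric"])
    n = len(panels)
    ncols = 3
    nrows = (n + ncols - 1) // ncols
    fig, axes = plt.subplots(nrows, ncols, figsize=(4.2 * ncols, 3.2 * nrows),
                             squeeze=False)
    for ax, ((net_name, metric), sub) in zip(axes.flat, panels):
        for scheme, traj in sub.groupby("scheme"):
            traj = traj.sort_values("step")
            ax.errorbar(traj["step"], traj["mean"], yerr=traj["se"],
                        label=scheme, marker="o", markersize=3, capsize=2)
        ax.set_title(f"{net_name}: {metric}", fontsize=9)
        ax.set_xlabel("individuals removed")
        ax.legend(fontsize=6)
    for ax in axes.flat[n:]:
        ax.set_visible(False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
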