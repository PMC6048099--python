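"""End-to-end study orchestration.

``run_study`` executes the full analysis on a cohort: month-12
imputation -> pooled confound adjustment -> one |r| network per (group,
month) -> six network metrics per network -> subject-resampling
bootstrap of baseline / follow-up / paired change per group -> combined
B x B contrasts between configured group pairs -> nodal monthly-change
slopes. Composite groups (e.g. all patients = converters +
non-converters) are configured as regroupings, so the study's post-hoc
group definitions are config changes, not code changes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from . import metrics as gm
from .bootstrap import (
    bootstrap_metric_distributions,
    ci_and_p,
    compare_groups,
    nodal_monthly_change,
)
from .network import build_group_network
from .preprocess import adjust_thickness, impute_month12

logger = logging.getLogger("longscn")

__all__ = ["StudyConfig", "StudyReport", "run_study", "apply_regroup"]


@dataclass
class StudyConfig:
    """Configuration of one study run."""

    contrasts: list[tuple[str, str]] = field(default_factory=list)
    regroup: dict[str, list[str]] = field(default_factory=dict)
    baseline_month: int = 0
    followup_month: int = 12
    B: int = 1000
    seed: int = 0
    include_lesion_load: bool = True
    tiv_rule: bool = False
    metrics: tuple[str, ...] = gm.METRIC_NAMES
    modularity_restarts: int = 10
    network_months: tuple[int, ...] | None = None  # default: all months present

    def __post_init__(self) -> None:
        if self.baseline_month >= self.followup_month:
            raise ValueError("baseline_month must precede followup_month")
        self.contrasts = [tuple(c) for c in self.contrasts]
        self.metrics = tuple(self.metrics)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def digest(self) -> str:
        canon = json.dumps(
            {
                "contrasts": self.contrasts,
                "regroup": self.regroup,
                "baseline_month": self.baseline_month,
                "followup_month": self.followup_month,
                "B": self.B,
                "seed": self.seed,
                "include_lesion_load": self.include_lesion_load,
                "tiv_rule": self.tiv_rule,
                "metrics": list(self.metrics),
                "modularity_restarts": self.modularity_restarts,
                "network_months": self.network_months,
            },
            sort_keys=True,
            default=list,
        )
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class StudyReport:
    """All outputs of one study run, JSON-serializable."""

    config_digest: str
    seed: int
    adjustment: dict
    network_metrics: dict  # group -> month -> {metric: value}
    inference: dict  # group -> metric -> phase -> InferenceResult dict
    comparisons: list[dict]
    nodal_changes: dict  # group -> metric -> {region: slope per month}
    group_sizes: dict
    n_imputed_subjects: int
    version: str = __version__

    def to_dict(self) -> dict:
        return {
            "config_digest": self.config_digest,
            "seed": self.seed,
            "version": self.version,
            "group_sizes": self.group_sizes,
            "n_imputed_subjects": self.n_imputed_subjects,
            "adjustment": self.adjustment,
            "network_metrics": self.network_metrics,
            "inference": self.inference,
            "comparisons": self.comparisons,
            "nodal_changes": self.nodal_changes,
        }

    def write(self, path: str | Path) -> None:
        io.write_json(self.to_dict(), path)


def apply_regroup(df: pd.DataFrame, regroup: dict[str, list[str]]) -> pd.DataFrame:
    """Append copies of member-group rows under each composite label."""
    if not regroup:
        return df
    known = set(df["group"].unique())
    parts = [df]
    for new_label, members in regroup.items():
        unknown = set(members) - known
        if unknown:
            raise ValueError(
                f"regroup {new_label!r} references undefined groups {sorted(unknown)}"
            )
        sub = df[df["group"].isin(members)].copy()
        sub["group"] = new_label
        parts.append(sub)
    return pd.concat(parts, ignore_index=True)


def _group_seed(master: int, label: str) -> int:
    h = hashlib.sha256(f"{master}:{label}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_study(
    config: StudyConfig,
    thickness: pd.DataFrame,
    covariates: pd.DataFrame,
) -> StudyReport:
    """Run the full pipeline on a cohort; deterministic given config.seed."""
    all_groups = list(dict.fromkeys(thickness["group"])) + list(config.regroup)
    for a, b in config.contrasts:
        for g in (a, b):
            if g not in all_groups:
                raise ValueError(f"contrast references undefined group {g!r}")

    logger.info("imputing missing month-%d visits", config.followup_month)
    had_12 = set(
        thickness.loc[thickness["month"] == config.followup_month, "subject_id"]
    )
    imputed_df = impute_month12(thickness)
    n_imputed = thickness["subject_id"].nunique() - len(had_12)

    logger.info("adjusting thickness (pooled regression)")
    adjusted, adj_report = adjust_thickness(
        imputed_df,
        covariates,
        include_lesion_load=config.include_lesion_load,
        tiv_rule=config.tiv_rule,
    )
    adjusted = apply_regroup(adjusted, config.regroup)

    months = (
        tuple(config.network_months)
        if config.network_months is not None
        else tuple(sorted(adjusted["month"].unique()))
    )
    groups = list(dict.fromkeys(adjusted["group"]))
    group_sizes = {
        g: int(adjusted.loc[adjusted["group"] == g, "subject_id"].nunique())
        for g in groups
    }

    logger.info("building %d networks and metrics", len(groups) * len(months))
    networks: dict[str, dict[int, object]] = {}
    net_metrics: dict[str, dict[int, dict[str, float]]] = {}
    for g in groups:
        networks[g] = {}
        net_metrics[g] = {}
        for m in months:
            _, net = build_group_network(adjusted, g, m)
            networks[g][m] = net
            ms = gm.summarize_network(
                net, seed=_group_seed(config.seed, f"{g}@{m}"),
                restarts=config.modularity_restarts,
            )
            net_metrics[g][m] = ms.network_level()

    logger.info("bootstrapping %d groups (B=%d)", len(groups), config.B)
    dists = {}
    inference: dict[str, dict] = {}
    for g in groups:
        dists[g] = bootstrap_metric_distributions(
            adjusted,
            g,
            months=(config.baseline_month, config.followup_month),
            B=config.B,
            seed=_group_seed(config.seed, g),
            metrics=config.metrics,
            modularity_restarts=config.modularity_restarts,
        )
        inference[g] = {}
        for metric, dist in dists[g].items():
            inference[g][metric] = {
                phase: ci_and_p(
                    dist.series(phase), point_estimate=dist.original(phase)
                ).to_dict()
                for phase in ("baseline", "followup", "change")
            }

    comparisons = []
    for a, b in config.contrasts:
        for metric in config.metrics:
            for phase in ("baseline", "followup", "change"):
                comparisons.append(
                    compare_groups(dists[a][metric], dists[b][metric], phase).to_dict()
                )

    nodal_changes: dict[str, dict] = {}
    for g in groups:
        nodal_changes[g] = {}
        for metric in ("strength", "clustering", "local_efficiency"):
            slopes = nodal_monthly_change(networks[g], metric)
            nodal_changes[g][metric] = {r: float(v) for r, v in slopes.items()}

    return StudyReport(
        config_digest=config.digest(),
        seed=config.seed,
        adjustment=adj_report.to_dict(),
        network_metrics={
            g: {int(m): v for m, v in per.items()} for g, per in net_metrics.items()
        },
        inference=inference,
        comparisons=comparisons,
        nodal_changes=nodal_changes,
        group_sizes=group_sizes,
        n_imputed_subjects=int(n_imputed),
    )
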