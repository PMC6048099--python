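"""Subject-resampling bootstrap inference for covariance-network metrics.

Because each network metric yields a single value per group and
timepoint, classical subject-level statistics cannot test group
differences or change over time. Instead, subjects are resampled with
replacement B times (default 1000); each replicate rebuilds the
baseline and follow-up networks FROM THE SAME resampled subjects and
recomputes the metrics, so the within-replicate change is paired.
Percentile 95% CIs and tail-counting p-values come from the resulting
bootstrap distributions; between-group tests use the combined
distribution of all B x B differences between the two groups' bootstrap
estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import metrics as gm
from .network import WeightedNetwork, pivot_visit

__all__ = [
    "BootstrapDistribution",
    "InferenceResult",
    "GroupComparisonResult",
    "bootstrap_metric_distributions",
    "ci_and_p",
    "compare_groups",
    "bootstrap_se",
    "nodal_monthly_change",
]

PHASES = ("baseline", "followup", "change")


@dataclass
class BootstrapDistribution:
    """Bootstrap series of one metric for one group (paired across phases)."""

    metric: str
    group: str
    baseline: np.ndarray
    followup: np.ndarray
    change: np.ndarray  # == followup - baseline elementwise
    original_baseline: float
    original_followup: float
    original_change: float
    seed: int
    n_subjects: int
    n_redrawn: int = 0

    @property
    def B(self) -> int:
        return len(self.baseline)

    def series(self, phase: str) -> np.ndarray:
        if phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}")
        return getattr(self, phase)

    def original(self, phase: str) -> float:
        return getattr(self, f"original_{phase}")


@dataclass
class InferenceResult:
    """Point estimate with percentile bootstrap CI and tail-count p."""

    estimate: float
    ci_lower: float
    ci_upper: float
    p_value: float
    significant: bool
    se: float

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "p_value": self.p_value,
            "significant": self.significant,
            "se": self.se,
        }


@dataclass
class GroupComparisonResult:
    """Between-group test from the combined B x B difference distribution."""

    metric: str
    group_a: str
    group_b: str
    phase: str
    observed_difference: float
    ci_lower: float
    ci_upper: float
    p_value: float
    significant: bool
    n_combinations: int
    quantiles: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "group_a": self.group_a,
            "group_b": self.group_b,
            "phase": self.phase,
            "observed_difference": self.observed_difference,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "p_value": self.p_value,
            "significant": self.significant,
            "n_combinations": self.n_combinations,
            "quantiles": self.quantiles,
        }


def _network_metrics(
    w: np.ndarray,
    which: tuple[str, ...],
    *,
    seed: int = 0,
    modularity_restarts: int = 10,
) -> dict[str, float]:
    """Network-level values of the requested metrics for one weight matrix."""
    out: dict[str, float] = {}
    if "mean_strength" in which:
        out["mean_strength"] = gm.nodal_strengths(w)[1]
    if "mean_clustering" in which:
        out["mean_clustering"] = gm.clustering_coefficients(w)[1]
    if "char_path_length" in which or "global_efficiency" in which:
        lmat = gm.path_length_matrix(w)
        if "char_path_length" in which:
            out["char_path_length"] = gm.characteristic_path_length(lmat)
        if "global_efficiency" in which:
            out["global_efficiency"] = gm.global_efficiency(lmat)
    if "local_efficiency" in which:
        out["local_efficiency"] = gm.local_efficiencies(w)[1]
    if "modularity" in which:
        out["modularity"] = gm.modularity_coefficient(
            w, seed=seed, restarts=modularity_restarts
        )[0]
    return out


def _abs_corr(x: np.ndarray) -> np.ndarray:
    w = np.abs(np.corrcoef(x, rowvar=False))
    np.fill_diagonal(w, 0.0)
    return w


def bootstrap_metric_distributions(
    adjusted: pd.DataFrame,
    group: str,
    *,
    months: tuple[int, int] = (0, 12),
    B: int = 1000,
    seed: int = 0,
    metrics: tuple[str, ...] = gm.METRIC_NAMES,
    modularity_restarts: int = 10,
    max_redraws: int = 1000,
) -> dict[str, BootstrapDistribution]:
    """Bootstrap the network metrics of one group, paired across two visits.

    Each replicate draws n subjects with replacement (the same subjects
    at both visits), rebuilds the |r| networks, and computes the
    requested network-level metrics at baseline and follow-up plus their
    paired change. Replicates whose resampled data leave any region with
    zero variance at either visit are redrawn (counted in
    ``n_redrawn``). Deterministic given ``seed``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    base_month, fu_month = months
    x0 = pivot_visit(adjusted, group, base_month)
    x1 = pivot_visit(adjusted, group, fu_month)
    common = x0.index.intersection(x1.index)
    if len(common) < 3:
        raise ValueError(
            f"group {group!r}: need >= 3 subjects with both visits, got {len(common)}"
        )
    a0 = x0.loc[common].to_numpy()
    a1 = x1.loc[common].to_numpy()
    n = len(common)
    for arr, month in ((a0, base_month), (a1, fu_month)):
        zero = np.flatnonzero(arr.std(axis=0) == 0)
        if zero.size:
            names = [x0.columns[i] for i in zero]
            raise ValueError(
                f"group {group!r} month {month}: zero-variance region(s) {names}"
            )

    orig0 = _network_metrics(_abs_corr(a0), metrics, seed=seed,
                             modularity_restarts=modularity_restarts)
    orig1 = _network_metrics(_abs_corr(a1), metrics, seed=seed,
                             modularity_restarts=modularity_restarts)

    rng = np.random.default_rng(seed)
    series0 = {m: np.empty(B) for m in metrics}
    series1 = {m: np.empty(B) for m in metrics}
    n_redrawn = 0
    for b in range(B):
        for attempt in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            r0, r1 = a0[idx], a1[idx]
            if (r0.std(axis=0) > 0).all() and (r1.std(axis=0) > 0).all():
                break
            n_redrawn += 1
        else:
            raise RuntimeError(
                f"group {group!r}: could not draw a replicate without a "
                f"zero-variance region in {max_redraws} attempts"
            )
        v0 = _network_metrics(_abs_corr(r0), metrics, seed=seed + b,
                              modularity_restarts=modularity_restarts)
        v1 = _network_metrics(_abs_corr(r1), metrics, seed=seed + b,
                              modularity_restarts=modularity_restarts)
        for m in metrics:
            series0[m][b] = v0[m]
            series1[m][b] = v1[m]

    return {
        m: BootstrapDistribution(
            metric=m,
            group=group,
            baseline=series0[m],
            followup=series1[m],
            change=series1[m] - series0[m],
            original_baseline=float(orig0[m]),
            original_followup=float(orig1[m]),
            original_change=float(orig1[m] - orig0[m]),
            seed=seed,
            n_subjects=n,
            n_redrawn=n_redrawn,
        )
        for m in metrics
    }


def _tail_p(series: np.ndarray, null_value: float, denom: int | None = None) -> float:
    n = denom if denom is not None else len(series)
    p_lo = (np.count_nonzero(series <= null_value) + 1) / (n + 1)
    p_hi = (np.count_nonzero(series >= null_value) + 1) / (n + 1)
    return float(min(1.0, 2.0 * min(p_lo, p_hi)))


def ci_and_p(
    series: np.ndarray,
    *,
    point_estimate: float | None = None,
    null_value: float = 0.0,
    alpha: float = 0.05,
    method: str = "percentile",
) -> InferenceResult:
    """Percentile CI and two-sided tail-counting p for a bootstrap series.

    CI = (100*alpha/2, 100*(1-alpha/2)) percentiles of the series;
    p = 2 * min((#{x <= null} + 1)/(B + 1), (#{x >= null} + 1)/(B + 1)),
    capped at 1. Significance means the CI excludes the null value.

    ``method="bc"`` applies median bias correction to the percentile
    levels (requires ``point_estimate``); acceleration is not estimable
    from the series alone, so this is BC, not full BCa.
    """
    series = np.asarray(series, dtype=float)
    if len(series) < 40:
        raise ValueError("need B >= 40 bootstrap values to estimate a 95% CI")
    levels = np.array([alpha / 2, 1 - alpha / 2])
    if method == "bc":
        if point_estimate is None:
            raise ValueError("bias correction requires point_estimate")
        frac = np.clip(np.mean(series < point_estimate), 1e-6, 1 - 1e-6)
        z0 = stats.norm.ppf(frac)
        levels = stats.norm.cdf(2 * z0 + stats.norm.ppf(levels))
    elif method != "percentile":
        raise ValueError("method must be 'percentile' or 'bc'")
    lo, hi = np.percentile(series, 100 * levels)
    p = _tail_p(series, null_value)
    estimate = float(point_estimate) if point_estimate is not None else float(
        np.mean(series)
    )
    significant = not (lo <= null_value <= hi)
    return InferenceResult(
        estimate=estimate,
        ci_lower=float(lo),
        ci_upper=float(hi),
        p_value=p,
        significant=significant,
        se=bootstrap_se(series),
    )


def bootstrap_se(series: np.ndarray) -> float:
    """Bootstrap standard error: sample SD of the bootstrap series."""
    series = np.asarray(series, dtype=float)
    if len(series) < 2:
        raise ValueError("need at least 2 bootstrap values")
    return float(np.std(series, ddof=1))


def compare_groups(
    dist_a: BootstrapDistribution,
    dist_b: BootstrapDistribution,
    phase: str,
    *,
    alpha: float = 0.05,
    chunk: int = 128,
) -> GroupComparisonResult:
    """Test a group difference via the combined B x B difference distribution.

    All B_a x B_b differences a_i - b_j between the two groups' bootstrap
    estimates form the combined distribution; its percentile interval and
    tail counts give the CI and p for the observed difference.
    """
    if dist_a.metric != dist_b.metric:
        raise ValueError(
            f"metric mismatch: {dist_a.metric!r} vs {dist_b.metric!r}"
        )
    if phase not in PHASES:
        raise ValueError(f"phase must be one of {PHASES}")
    a = dist_a.series(phase)
    b = dist_b.series(phase)
    # chunked broadcasting bounds peak memory while keeping exact percentiles
    parts = [a[i : i + chunk, None] - b[None, :] for i in range(0, len(a), chunk)]
    diffs = np.concatenate([p.ravel() for p in parts])
    n_comb = diffs.size
    lo, hi = np.percentile(diffs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    p = _tail_p(diffs, 0.0)
    qs = np.percentile(diffs, [1, 2.5, 25, 50, 75, 97.5, 99])
    observed = dist_a.original(phase) - dist_b.original(phase)
    return GroupComparisonResult(
        metric=dist_a.metric,
        group_a=dist_a.group,
        group_b=dist_b.group,
        phase=phase,
        observed_difference=float(observed),
        ci_lower=float(lo),
        ci_upper=float(hi),
        p_value=p,
        significant=not (lo <= 0.0 <= hi),
        n_combinations=int(n_comb),
        quantiles={
            "q01": float(qs[0]),
            "q025": float(qs[1]),
            "q25": float(qs[2]),
            "q50": float(qs[3]),
            "q75": float(qs[4]),
            "q975": float(qs[5]),
            "q99": float(qs[6]),
        },
    )


_NODAL_EXTRACTORS = {
    "strength": lambda w: gm.nodal_strengths(w)[0],
    "clustering": lambda w: gm.clustering_coefficients(w)[0],
    "local_efficiency": lambda w: gm.local_efficiencies(w)[0],
}


def nodal_monthly_change(
    networks: dict[int, WeightedNetwork],
    metric: str,
    *,
    mode: str = "slope",
) -> pd.Series:
    """Per-node monthly rate of change of a node-level metric.

    ``networks`` maps month -> network for ONE group (all sharing region
    labels). With ``mode='slope'`` (default) the rate is the per-node OLS
    slope of the metric against month across all snapshots; with
    ``mode='endpoint'`` it is (last - first) / (month span). Units:
    metric units per month. Feeds the nodal-change brain maps (node size
    = |slope|, colour = sign).
    """
    if metric not in _NODAL_EXTRACTORS:
        raise ValueError(
            f"metric must be one of {sorted(_NODAL_EXTRACTORS)}, got {metric!r}"
        )
    if len(networks) < 2:
        raise ValueError("need at least two timepoints")
    months = sorted(networks)
    regions = networks[months[0]].regions
    for m in months:
        if networks[m].regions != regions:
            raise ValueError(f"region labels differ at month {m}")
    values = np.column_stack(
        [_NODAL_EXTRACTORS[metric](networks[m].weights) for m in months]
    )  # regions x months
    t = np.array(months, dtype=float)
    if mode == "slope":
        tc = t - t.mean()
        slopes = (values - values.mean(axis=1, keepdims=True)) @ tc / (tc @ tc)
    elif mode == "endpoint":
        slopes = (values[:, -1] - values[:, 0]) / (t[-1] - t[0])
    else:
        raise ValueError("mode must be 'slope' or 'endpoint'")
    return pd.Series(slopes, index=regions, name=f"{metric}_per_month")
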