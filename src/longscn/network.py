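"""Group-level weighted structural covariance networks.

One network per (group, timepoint): nodes are cortical regions, edge
weights are the absolute Pearson correlations of adjusted thickness
across the group's subjects at that visit. Networks are fully weighted
complete graphs — no thresholding or binarization; a weight of exactly 0
simply contributes no edge to path computations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CorrelationMatrix", "WeightedNetwork", "build_group_network", "pivot_visit"]


@dataclass
class CorrelationMatrix:
    """Pearson correlation matrix of one group at one timepoint."""

    values: np.ndarray  # N x N, symmetric, unit diagonal
    regions: list[str]
    group: str
    month: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.regions, columns=self.regions)


@dataclass
class WeightedNetwork:
    """|r| network of one group at one timepoint: zero diagonal, weights in [0, 1]."""

    weights: np.ndarray
    regions: list[str]
    group: str
    month: int

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        """Number of undirected weighted edge slots, N(N-1)/2."""
        n = self.n_nodes
        return n * (n - 1) // 2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.regions, columns=self.regions)


def pivot_visit(adjusted: pd.DataFrame, group: str, month: int) -> pd.DataFrame:
    """Subjects x regions matrix of one group's visit, sorted labels."""
    sel = adjusted[(adjusted["group"] == group) & (adjusted["month"] == month)]
    if sel.empty:
        raise ValueError(f"no records for group {group!r} at month {month}")
    wide = sel.pivot(index="subject_id", columns="region", values="thickness_mm")
    if wide.isna().any().any():
        bad = wide.columns[wide.isna().any()].tolist()
        raise ValueError(
            f"incomplete region set for group {group!r} month {month}: {bad}"
        )
    return wide.sort_index(axis=0).sort_index(axis=1)


def correlation_network(
    x: np.ndarray, regions: list[str], group: str, month: int
) -> tuple[CorrelationMatrix, WeightedNetwork]:
    """Build (CorrelationMatrix, WeightedNetwork) from a subjects x regions array."""
    n_subj = x.shape[0]
    if n_subj < 3:
        raise ValueError(
            f"group {group!r} month {month}: need >= 3 subjects, got {n_subj}"
        )
    sd = x.std(axis=0)
    if np.any(sd == 0):
        zero = [regions[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(
            f"zero-variance region(s) for group {group!r} month {month}: {zero}"
        )
    r = np.corrcoef(x, rowvar=False)
    np.fill_diagonal(r, 1.0)
    w = np.abs(r)
    np.fill_diagonal(w, 0.0)
    return (
        CorrelationMatrix(r, list(regions), group, month),
        WeightedNetwork(w, list(regions), group, month),
    )


def build_group_network(
    adjusted: pd.DataFrame, group: str, month: int
) -> tuple[CorrelationMatrix, WeightedNetwork]:
    """Correlation matrix and |r| network for one group at one month.

    Correlations are computed across the group's subjects at that visit
    (each region pair's r over subjects); the network weights are the
    absolute correlations with the diagonal forced to zero. Requires at
    least 3 subjects and nonzero variance in every region.
    """
    wide = pivot_visit(adjusted, group, month)
    return correlation_network(
        wide.to_numpy(), list(wide.columns), group, month
    )
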