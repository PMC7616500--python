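"""Cluster-level consolidation and significance testing of doublet scores.

Per-cell doublet scores (e.g. from Scrublet, computed upstream per lane) are
replaced by the median of their fine cluster; cluster medians are then tested
right-tailed against a robust normal null whose centre is the median of
cluster medians and whose spread is a MAD-derived standard deviation
estimate computed from above-median values only (so a mass of zeros cannot
truncate the scale). P values are Benjamini–Hochberg adjusted and clusters
are flagged when significant and above a configurable score floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "NullModel",
    "ClusterScoreTable",
    "consolidate_scores",
    "fit_null",
    "cluster_pvalues",
    "bh_adjust",
    "flag_doublet_clusters",
    "analyze_scores",
]

#: Scale constant making the MAD consistent with a normal standard deviation.
MAD_SCALE = 1.4826


@dataclass(frozen=True)
class NullModel:
    """Normal null for cluster medians: centre and robust sigma."""

    center: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class ClusterScoreTable:
    """Result of the full procedure.

    ``cells`` is the input table plus ``consolidated_score``, ``p_value``,
    ``q_value`` and ``flagged`` columns; ``clusters`` is one row per fine
    cluster with the same statistics plus a ``borderline`` marker for
    clusters that are significant but sit below the score floor (left to
    manual curation rather than decided here).
    """

    cells: pd.DataFrame
    clusters: pd.DataFrame
    null: NullModel


def consolidate_scores(scores, fine_clusters) -> np.ndarray:
    """Replace each cell's score by the median of its fine cluster."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(fine_clusters)
    if scores.size == 0:
        raise ValueError("empty score vector")
    if scores.shape != labels.shape:
        raise ValueError("scores and fine_clusters must have equal length")
    medians = pd.Series(scores).groupby(pd.Series(labels), sort=False).transform("median")
    return medians.to_numpy()


def fit_null(cluster_medians) -> NullModel:
    """Fit the robust normal null from per-cluster median scores.

    centre = median of the cluster medians; sigma = 1.4826 x median of
    (x - centre) over values strictly above the centre.
    """
    x = np.asarray(cluster_medians, dtype=float)
    if x.size < 2 or np.unique(x).size < 2:
        raise ValueError("need >= 2 distinct cluster medians to fit a null")
    center = float(np.median(x))
    above = x[x > center]
    if above.size == 0:
        raise ValueError("degenerate null: no cluster medians above the median")
    sigma = MAD_SCALE * float(np.median(above - center))
    if sigma <= 0:
        raise ValueError("degenerate null: zero spread above the median")
    return NullModel(center=center, sigma=sigma)


def cluster_pvalues(cluster_medians, null: NullModel) -> np.ndarray:
    """Right-tailed normal p-values for cluster medians under the null."""
    x = np.asarray(cluster_medians, dtype=float)
    return norm.sf((x - null.center) / null.sigma)


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, clipped to 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def flag_doublet_clusters(
    clusters: pd.DataFrame,
    q_threshold: float = 0.05,
    score_floor: float = 0.1,
) -> pd.DataFrame:
    """Flag clusters with ``q_value < q_threshold`` and median >= score floor.

    Clusters that are significant but fall below the floor are reported as
    ``borderline`` for manual curation, not flagged automatically.
    """
    for name, val in (("q_threshold", q_threshold), ("score_floor", score_floor)):
        if not (0 <= val <= 1):
            raise ValueError(f"{name} must lie in [0, 1]")
    out = clusters.copy()
    significant = out["q_value"] < q_threshold
    out["flagged"] = significant & (out["consolidated_score"] >= score_floor)
    out["borderline"] = significant & ~out["flagged"]
    return out


def analyze_scores(
    table: pd.DataFrame,
    score_col: str = "raw_score",
    cluster_col: str = "fine_cluster",
    q_threshold: float = 0.05,
    score_floor: float = 0.1,
    per_lane: bool = False,
    lane_col: str = "lane_id",
) -> ClusterScoreTable:
    """Run the full consolidation + testing + flagging procedure.

    With ``per_lane=True`` the null is fitted within each lane separately;
    the default is a single global null.
    """
    if table.empty:
        raise ValueError("empty score table")
    if per_lane:
        parts = [
            analyze_scores(
                sub, score_col, cluster_col, q_threshold, score_floor, per_lane=False
            )
            for _, sub in table.groupby(lane_col, sort=False)
        ]
        cells = pd.concat([p.cells for p in parts], ignore_index=True)
        clusters = pd.concat([p.clusters for p in parts], ignore_index=True)
        return ClusterScoreTable(cells=cells, clusters=clusters, null=parts[0].null)

    cells = table.copy()
    cells["consolidated_score"] = consolidate_scores(
        cells[score_col], cells[cluster_col]
    )
    medians = cells.groupby(cluster_col, sort=False)[score_col].median()
    null = fit_null(medians.to_numpy())
    clusters = pd.DataFrame(
        {
            "fine_cluster": medians.index.to_numpy(),
            "n_cells": cells.groupby(cluster_col, sort=False).size().to_numpy(),
            "consolidated_score": medians.to_numpy(),
        }
    )
    clusters["p_value"] = cluster_pvalues(clusters["consolidated_score"], null)
    clusters["q_value"] = bh_adjust(clusters["p_value"].to_numpy())
    clusters = flag_doublet_clusters(clusters, q_threshold, score_floor)

    lut = clusters.set_index("fine_cluster")
    for col in ("p_value", "q_value", "flagged"):
        cells[col] = cells[cluster_col].map(lut[col]).to_numpy()
    return ClusterScoreTable(cells=cells, clusters=clusters, null=null)
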