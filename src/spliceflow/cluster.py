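"""Density-based clustering of splicing profiles across conditions.

Events that change significantly in at least one pair of adjacent
conditions are clustered by their per-condition mean PSI vectors using
DBSCAN or OPTICS. DBSCAN needs the neighborhood radius D and minimum
cluster size N up front; OPTICS only bounds the reachability distance by S
and a flat partition is extracted afterwards at the cut distance D <= S
that maximizes a coverage-weighted silhouette (the silhouette score over
clustered events times the fraction of events clustered — the weighting
stops a tiny D from looking optimal by trimming every border event to
noise). Cluster quality
is reported as the silhouette score (separation) and the root mean square
standard deviation, RMSSTD (within-cluster homogeneity). Noise events
(label -1) are excluded from both scores.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN, OPTICS, cluster_optics_dbscan
from sklearn.metrics import silhouette_score

from .psi import ExpressionMatrix, PsiMatrix

logger = logging.getLogger(__name__)

METRICS = ("euclidean", "manhattan", "cosine")


@dataclass
class ClusterConfig:
    """Parameters for density-based clustering of PSI profiles."""

    method: str = "DBSCAN"
    min_events: int = 20  # N: minimum events per cluster
    eps: float = 0.05  # D: DBSCAN neighborhood radius
    max_reachability: float = 0.11  # S: OPTICS reachability bound
    metric: str = "euclidean"
    sig_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.method not in ("DBSCAN", "OPTICS"):
            raise ValueError(f"unknown clustering method {self.method!r}")
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}; choose from {METRICS}")
        if self.min_events < 2:
            raise ValueError("min_events (N) must be >= 2")
        if self.eps <= 0 or self.max_reachability <= 0:
            raise ValueError("distance parameters must be > 0")


@dataclass
class ClusterResult:
    """Flat partition of events plus quality scores.

    ``labels`` maps event_id to a cluster id, -1 meaning noise. ``eps`` is
    the radius actually used (for OPTICS, the chosen cut distance).
    """

    labels: pd.Series
    silhouette: float
    rmsstd: float
    n_clustered: int
    pct_clustered: float
    eps: float
    method: str


def select_clusterable(
    results: Mapping[tuple[str, str], pd.DataFrame],
    psi: PsiMatrix,
    expr: ExpressionMatrix,
    sig_threshold: float = 0.05,
    use_adjusted: bool = False,
) -> pd.DataFrame:
    """Mean PSI per condition for events significant in >= 1 comparison.

    Eligibility uses nominal p-values by default (adjusted on request).
    Rows with an undefined per-condition mean are dropped with a log note.
    Returns an empty frame (with a warning) when nothing is eligible.
    """
    col = "adj_pvalue" if use_adjusted else "pvalue"
    eligible: set[str] = set()
    for df in results.values():
        eligible |= set(df.index[df[col] < sig_threshold])
    if not eligible:
        warnings.warn("no events pass the significance threshold; nothing to cluster")
        return pd.DataFrame(columns=expr.conditions)
    index = [e for e in psi.values.index if e in eligible]
    profile = pd.DataFrame(index=pd.Index(index, name="event_id"))
    for cond in expr.conditions:
        profile[cond] = psi.values.loc[index, expr.samples_of(cond)].mean(axis=1)
    defined = profile.notna().all(axis=1)
    if (~defined).any():
        logger.info(
            "%d eligible events dropped for undefined condition means",
            int((~defined).sum()),
        )
    return profile[defined]


def _result(
    profiles: pd.DataFrame, labels: np.ndarray, eps: float, metric: str, method: str
) -> ClusterResult:
    n = len(labels)
    clustered = labels >= 0
    sil = silhouette(profiles.to_numpy(), labels, metric=metric)
    return ClusterResult(
        labels=pd.Series(labels, index=profiles.index, name="cluster_id"),
        silhouette=sil,
        rmsstd=rmsstd(profiles.to_numpy(), labels),
        n_clustered=int(clustered.sum()),
        pct_clustered=100.0 * clustered.sum() / n if n else 0.0,
        eps=eps,
        method=method,
    )


def _drop_zero_rows_for_cosine(profiles: pd.DataFrame, metric: str) -> pd.DataFrame:
    if metric != "cosine":
        return profiles
    norms = np.linalg.norm(profiles.to_numpy(), axis=1)
    if (norms == 0).any():
        warnings.warn(
            f"{int((norms == 0).sum())} all-zero profiles dropped: cosine distance undefined"
        )
        profiles = profiles[norms > 0]
    return profiles


def dbscan(
    profiles: pd.DataFrame,
    eps: float,
    min_events: int,
    metric: str = "euclidean",
) -> ClusterResult:
    """DBSCAN partition: core events have >= ``min_events`` neighbors
    (themselves included) within ``eps``; unreachable events are noise."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    profiles = _drop_zero_rows_for_cosine(profiles, metric)
    if len(profiles) < min_events:
        raise ValueError(
            f"need at least N={min_events} events to cluster, got {len(profiles)}"
        )
    labels = DBSCAN(eps=eps, min_samples=min_events, metric=metric).fit_predict(
        profiles.to_numpy()
    )
    return _result(profiles, labels, eps, metric, "DBSCAN")


def optics(
    profiles: pd.DataFrame,
    max_reachability: float,
    min_events: int,
    metric: str = "euclidean",
    n_grid: int = 20,
) -> ClusterResult:
    """OPTICS partition with a quality-optimized flat cut.

    The reachability profile is computed once with ``max_eps`` = S; flat
    partitions are extracted at ``n_grid`` evenly spaced cut distances
    D in (0, S] and the partition with the best coverage-weighted
    silhouette (:func:`extraction_quality`) is kept, ties resolved toward
    the larger D.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    profiles = _drop_zero_rows_for_cosine(profiles, metric)
    if len(profiles) < min_events:
        raise ValueError(
            f"need at least N={min_events} events to cluster, got {len(profiles)}"
        )
    model = OPTICS(
        min_samples=min_events, max_eps=max_reachability, metric=metric
    ).fit(profiles.to_numpy())
    best_labels = np.full(len(profiles), -1)
    best_quality = -np.inf
    best_d = max_reachability
    for d in np.linspace(max_reachability / n_grid, max_reachability, n_grid):
        labels = extract_at_distance(model, d)
        quality = extraction_quality(profiles.to_numpy(), labels, metric=metric)
        if not np.isnan(quality) and quality >= best_quality:
            best_quality, best_labels, best_d = quality, labels, d
    if not np.isfinite(best_quality):
        # no cut produced >= 2 clusters; keep the largest-D extraction
        best_labels = extract_at_distance(model, max_reachability)
        best_d = max_reachability
    return _result(profiles, best_labels, float(best_d), metric, "OPTICS")


def extraction_quality(
    vectors: np.ndarray, labels: np.ndarray, metric: str = "euclidean"
) -> float:
    """Coverage-weighted silhouette: the objective of the OPTICS flat cut.

    Silhouette over clustered points times the fraction of points
    clustered; NaN when the silhouette itself is undefined.
    """
    labels = np.asarray(labels)
    sil = silhouette(vectors, labels, metric=metric, warn=False)
    if np.isnan(sil):
        return float("nan")
    return float(sil * (labels >= 0).mean())


def extract_at_distance(model: OPTICS, eps: float) -> np.ndarray:
    """DBSCAN-equivalent flat labels from a fitted OPTICS model at radius eps."""
    return cluster_optics_dbscan(
        reachability=model.reachability_,
        core_distances=model.core_distances_,
        ordering=model.ordering_,
        eps=eps,
    )


def silhouette(
    vectors: np.ndarray,
    labels: np.ndarray,
    metric: str = "euclidean",
    warn: bool = True,
) -> float:
    """Mean silhouette (b - a)/max(a, b) over clustered points; noise excluded.

    Undefined (NaN) with fewer than two clusters or when every cluster is a
    singleton.
    """
    labels = np.asarray(labels)
    mask = labels >= 0
    kept = labels[mask]
    if len(set(kept)) < 2 or len(kept) <= len(set(kept)):
        if warn:
            warnings.warn("silhouette undefined: fewer than two non-noise clusters")
        return float("nan")
    return float(silhouette_score(np.asarray(vectors)[mask], kept, metric=metric))


def rmsstd(vectors: np.ndarray, labels: np.ndarray) -> float:
    """Pooled within-cluster standard deviation across profile dimensions.

    sqrt( sum_c sum_{x in c} ||x - centroid_c||^2 / (d * sum_c (n_c - 1)) )
    with d the number of conditions; noise excluded; NaN when every cluster
    is a singleton (zero pooled degrees of freedom).
    """
    vectors = np.asarray(vectors, dtype=float)
    labels = np.asarray(labels)
    ss = 0.0
    dof = 0
    for c in set(labels[labels >= 0]):
        members = vectors[labels == c]
        centroid = members.mean(axis=0)
        ss += float(((members - centroid) ** 2).sum())
        dof += len(members) - 1
    if dof == 0:
        return float("nan")
    d = vectors.shape[1]
    return float(np.sqrt(ss / (d * dof)))


def cluster_events(profiles: pd.DataFrame, config: ClusterConfig) -> ClusterResult:
    """Dispatch to DBSCAN or OPTICS according to the configuration."""
    if config.method == "DBSCAN":
        return dbscan(profiles, config.eps, config.min_events, config.metric)
    return optics(
        profiles, config.max_reachability, config.min_events, config.metric
    )
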