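"""Temporal segmentation clustering of bioprocess parameters.

A gap-intolerant downstream consumer of the imputed time series: the day
axis is first segmented into contiguous intervals of similar behaviour,
then parameters are clustered by their per-segment mean profiles.  Running
the procedure over a sweep of segmentation thresholds classifies each
parameter pair by how robustly it co-clusters — pairs that stay together
at every threshold share a temporal trend throughout the culture, so one
member could be monitored as a representative of the group.

This is a from-scratch implementation honouring the conventional
merge/extension threshold interface (defaults m = e = 0.5):

* segmentation is a greedy left-to-right scan on the standardised
  day-mean profile matrix: day j starts a new segment when its profile
  change from day j-1 (normalised to [0, 1] by the largest day-to-day
  change) exceeds ``threshold * e`` — so the boundary set is nested in the
  threshold and segment counts are weakly decreasing;
* clustering is agglomerative on per-segment parameter profiles with
  Pearson-correlation similarity, merging while the best inter-cluster
  similarity is at least ``m``, ties broken by lexicographic parameter
  order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import DAY_COL, TimeSeriesTable


@dataclass
class ClusteringConfig:
    merge_threshold: float = 0.5  # m
    extension_threshold: float = 0.5  # e
    threshold_sweep: tuple = (0.05, 0.2, 0.4, 0.6, 0.8, 1.0)
    similarity: str = "correlation"

    def __post_init__(self):
        if not 0 <= self.merge_threshold <= 1 or not 0 <= self.extension_threshold <= 1:
            raise ValueError("merge and extension thresholds must lie in [0, 1]")
        if len(self.threshold_sweep) == 0:
            raise ValueError("threshold_sweep must be non-empty")
        if list(self.threshold_sweep) != sorted(self.threshold_sweep):
            raise ValueError("threshold_sweep must be ordered")


@dataclass
class SegmentSet:
    """Ordered contiguous day intervals covering the day axis."""

    segments: list  # list of (first_day_index, last_day_index) inclusive
    day_axis: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        last = -1
        for lo, hi in self.segments:
            if lo != last + 1 or hi < lo:
                raise ValueError("segments must be contiguous, ordered and non-empty")
            last = hi

    def __len__(self) -> int:
        return len(self.segments)

    def day_intervals(self) -> list:
        return [(self.day_axis[lo], self.day_axis[hi]) for lo, hi in self.segments]


@dataclass
class ClusterAssignment:
    """Partitions per sweep threshold plus pair co-clustering stability."""

    partitions: dict  # threshold -> {parameter: cluster label}
    stability: dict  # frozenset({p, q}) -> "always-together" | "sometimes" | "never"

    def always_together_groups(self) -> list:
        """Connected components of the always-together pair relation (size >= 2)."""
        params = sorted({p for pair in self.stability for p in pair})
        parent = {p: p for p in params}

        def find(p):
            while parent[p] != p:
                parent[p] = parent[parent[p]]
                p = parent[p]
            return p

        for pair, cls in self.stability.items():
            if cls == "always-together":
                a, b = sorted(pair)
                parent[find(a)] = find(b)
        groups: dict = {}
        for p in params:
            groups.setdefault(find(p), []).append(p)
        return sorted(sorted(g) for g in groups.values() if len(g) > 1)


def _profile_matrix(ts: TimeSeriesTable) -> pd.DataFrame:
    """Standardised day-mean profile per parameter (days x parameters)."""
    if ts.mask.to_numpy().any() or ts.data.isna().to_numpy().any():
        raise ValueError(
            "time series still contains gaps; impute before segmentation clustering"
        )
    daily = ts.data.groupby(level=DAY_COL).mean().sort_index()
    mu, sd = daily.mean(axis=0), daily.std(axis=0, ddof=0)
    sd = sd.replace(0.0, 1.0)
    return (daily - mu) / sd


def segment_time_axis(ts: TimeSeriesTable, threshold: float, e: float = 0.5) -> SegmentSet:
    """Greedy left-to-right segmentation of the day axis.

    Day-to-day profile changes (RMS over parameters of the standardised
    day-mean profiles) are normalised by their maximum; a new segment
    starts wherever the normalised change exceeds ``threshold * e``.
    Larger thresholds therefore give weakly fewer, longer segments.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    prof = _profile_matrix(ts)
    n_days = len(prof)
    if n_days == 1:
        return SegmentSet([(0, 0)], prof.index.to_numpy())
    deltas = np.sqrt(np.mean(np.diff(prof.to_numpy(), axis=0) ** 2, axis=1))
    max_delta = deltas.max()
    norm = deltas / max_delta if max_delta > 0 else np.zeros_like(deltas)
    tol = threshold * e
    segments = []
    start = 0
    for j in range(1, n_days):
        if norm[j - 1] > tol:
            segments.append((start, j - 1))
            start = j
    segments.append((start, n_days - 1))
    return SegmentSet(segments, prof.index.to_numpy())


def _segment_profiles(ts: TimeSeriesTable, segments: SegmentSet) -> pd.DataFrame:
    """Per-segment means of the standardised day profiles (segments x params)."""
    prof = _profile_matrix(ts)
    rows = [prof.iloc[lo : hi + 1].mean(axis=0) for lo, hi in segments.segments]
    return pd.DataFrame(rows).reset_index(drop=True)


def _similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson correlation; degenerate profiles compare by near-identity."""
    if len(u) >= 2 and np.std(u) > 1e-12 and np.std(v) > 1e-12:
        return float(np.corrcoef(u, v)[0, 1])
    return 1.0 if np.allclose(u, v, atol=1e-8) else -1.0


def cluster_parameters(ts: TimeSeriesTable, segments: SegmentSet, m: float = 0.5) -> dict:
    """Agglomerative clustering of parameters on segment-mean profiles.

    Clusters merge (average linkage on member profiles) while the best
    inter-cluster similarity is >= ``m``; the result maps each parameter
    to an integer cluster label forming a partition.
    """
    profiles = _segment_profiles(ts, segments)
    params = sorted(profiles.columns)
    clusters = {p: [p] for p in params}  # label -> members; label = lexicographic head

    def centroid(members):
        return profiles[members].mean(axis=1).to_numpy()

    while len(clusters) > 1:
        labels = sorted(clusters)
        best = None
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                sim = _similarity(centroid(clusters[labels[i]]), centroid(clusters[labels[j]]))
                if best is None or sim > best[0] + 1e-15:
                    best = (sim, labels[i], labels[j])
        if best is None or best[0] < m:
            break
        _, la, lb = best
        clusters[la] = sorted(clusters[la] + clusters[lb])
        del clusters[lb]

    assignment = {}
    for label, members in clusters.items():
        idx = sorted(clusters).index(label)
        for p in members:
            assignment[p] = idx
    return assignment


def threshold_sweep(ts: TimeSeriesTable, config: ClusteringConfig = None) -> ClusterAssignment:
    """Segment + cluster at every sweep threshold and classify pair stability."""
    config = config or ClusteringConfig()
    partitions = {}
    for t in config.threshold_sweep:
        segs = segment_time_axis(ts, t, config.extension_threshold)
        partitions[t] = cluster_parameters(ts, segs, config.merge_threshold)

    params = sorted(ts.param_columns)
    stability = {}
    for i in range(len(params)):
        for j in range(i + 1, len(params)):
            pair = frozenset((params[i], params[j]))
            together = [
                partitions[t][params[i]] == partitions[t][params[j]]
                for t in config.threshold_sweep
            ]
            if all(together):
                stability[pair] = "always-together"
            elif any(together):
                stability[pair] = "sometimes"
            else:
                stability[pair] = "never"
    return ClusterAssignment(partitions, stability)
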