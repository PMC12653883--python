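"""Species-cluster (BIN-like) delimitation on the pooled distance matrix.

Records are linked whenever their K2P distance is strictly below the merge
threshold (default 3%); connected components under that relation are the
clusters.  By construction every cluster's nearest-neighbor distance — the
minimum distance from any member to any record outside — is at least the
threshold, operationalizing the ">3% to the nearest neighbor" criterion
used to call discrete species groups.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .distance import DistanceMatrix


@dataclass(frozen=True)
class ClusterSettings:
    merge_threshold: float = 0.03  # K2P distance; link when d < threshold

    def __post_init__(self) -> None:
        if not (0 < self.merge_threshold < 1):
            raise ValueError("merge_threshold must lie in (0, 1)")


@dataclass
class ClusterSet:
    """A partition of record ids with per-cluster diagnostics.

    ``clusters`` maps cluster id -> sorted member ids; cluster ids are
    assigned deterministically in order of each cluster's smallest member
    id.  ``nn_distance`` is the minimum distance from the cluster to any
    outside record (``inf`` for a lone cluster covering everything).
    """

    clusters: dict[int, tuple[str, ...]]
    nn_distance: dict[int, float]
    membership: dict[str, int] = field(default_factory=dict)
    label_census: dict[int, Counter] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.membership:
            self.membership = {
                rid: cid for cid, members in self.clusters.items() for rid in members
            }

    def __len__(self) -> int:
        return len(self.clusters)

    def cluster_of(self, record_id: str) -> int:
        """The unique cluster containing ``record_id``."""
        try:
            return self.membership[record_id]
        except KeyError:
            raise KeyError(f"unknown record id {record_id!r}") from None

    def members(self, cluster_id: int) -> tuple[str, ...]:
        return self.clusters[cluster_id]


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def delimit(
    dm: DistanceMatrix,
    settings: ClusterSettings = ClusterSettings(),
    labels: Mapping[str, str] | None = None,
) -> ClusterSet:
    """Single-linkage connected components under ``distance < threshold``.

    ``labels`` (record id -> species name) populates the per-cluster label
    census when given.  Saturated entries are not allowed: saturation
    implies distances far beyond any sensible merge threshold, but the
    matrix must be cleaned explicitly first.
    """
    if dm.has_saturation:
        raise ValueError("distance matrix contains saturated entries")
    n = len(dm.ids)
    uf = _UnionFind(n)
    close = np.argwhere(dm.values < settings.merge_threshold)
    for i, j in close:
        if i < j:
            uf.union(int(i), int(j))

    by_root: dict[int, list[int]] = defaultdict(list)
    for i in range(n):
        by_root[uf.find(i)].append(i)

    # deterministic numbering by smallest member id
    groups = sorted(by_root.values(), key=lambda idxs: min(dm.ids[i] for i in idxs))
    clusters: dict[int, tuple[str, ...]] = {}
    nn: dict[int, float] = {}
    census: dict[int, Counter] = {}
    member_idx: dict[int, list[int]] = {}
    for cid, idxs in enumerate(groups):
        clusters[cid] = tuple(sorted(dm.ids[i] for i in idxs))
        member_idx[cid] = idxs
    for cid, idxs in member_idx.items():
        mask = np.ones(n, dtype=bool)
        mask[idxs] = False
        nn[cid] = float(dm.values[np.ix_(idxs, np.where(mask)[0])].min()) if mask.any() else float("inf")
        if labels is not None:
            census[cid] = Counter(labels.get(dm.ids[i], "") for i in idxs)
    return ClusterSet(clusters=clusters, nn_distance=nn, label_census=census)


def cluster_of(record_id: str, clusters: ClusterSet) -> int:
    return clusters.cluster_of(record_id)


def split_census(
    clusters: ClusterSet, query_labels: Mapping[str, str]
) -> list[tuple[str, int]]:
    """How many distinct clusters each morphology label is scattered over.

    A count above 1 flags a species whose specimens split across clusters
    (e.g. an anomalous, deeply diverged haplotype).
    """
    seen: dict[str, set[int]] = defaultdict(set)
    for rid, label in query_labels.items():
        seen[label].add(clusters.cluster_of(rid))
    return sorted((label, len(cids)) for label, cids in seen.items())
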