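"""Cluster-level aggregation of specimen audits and headline statistics.

Specimen-level audit records are rolled up to the species-cluster level
(one record per cluster containing at least one query; a cluster is
problematic if any member query is).  The summary reports the share of
clusters with problematic identifications and the share whose problems
are *not* attributable to an incomplete reference library.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from .categories import CATEGORY_ORDER, ProblemCategory, sort_categories
from .classify import AuditRecord
from .cluster import ClusterSet


@dataclass(frozen=True)
class ClusterAudit:
    cluster_id: int | str
    query_ids: tuple[str, ...]
    morphology_labels: tuple[str, ...]
    problematic: bool
    categories: tuple[ProblemCategory, ...]


@dataclass(frozen=True)
class AuditSummary:
    n_clusters: int
    n_problematic: int
    #: per-category cluster counts, fixed enum order
    category_counts: dict[ProblemCategory, int]

    @property
    def n_clean(self) -> int:
        return self.n_clusters - self.n_problematic

    @property
    def pct_problematic_raw(self) -> float:
        return 100.0 * self.n_problematic / self.n_clusters

    @property
    def pct_problematic(self) -> float:
        """Problematic share, printed to 1 decimal."""
        return round(self.pct_problematic_raw, 1)

    @property
    def pct_problematic_printed(self) -> int:
        """Problematic share as printed in a headline (0 decimals)."""
        return int(self.pct_problematic_raw + 0.5)

    @property
    def pct_clean_printed(self) -> int:
        return 100 - self.pct_problematic_printed

    @property
    def pct_not_db_incomplete(self) -> float:
        """Share of clusters whose problems are not library incompleteness."""
        n_incomplete = self.category_counts.get(ProblemCategory.DB_INCOMPLETE, 0)
        return round(100.0 * (self.n_clusters - n_incomplete) / self.n_clusters, 1)

    def category_percentages(self) -> dict[ProblemCategory, float]:
        """Share of each category over all category assignments.

        Multi-category clusters contribute once per category; reported for
        orientation only, since the counting unit for such breakdowns is
        ambiguous when clusters carry alternative ("and/or") reasons.
        """
        total = sum(self.category_counts.values())
        if total == 0:
            return {c: 0.0 for c in CATEGORY_ORDER}
        return {
            c: round(100.0 * self.category_counts.get(c, 0) / total, 1)
            for c in CATEGORY_ORDER
        }

    def summary(self) -> str:
        lines = [
            f"clusters audited:          {self.n_clusters}",
            f"problematic clusters:      {self.n_problematic} "
            f"({self.pct_problematic_printed}%)",
            f"clean clusters:            {self.n_clean} ({self.pct_clean_printed}%)",
            f"not library-incomplete:    {self.pct_not_db_incomplete}%",
            "category breakdown (over category assignments):",
        ]
        pcts = self.category_percentages()
        for cat in CATEGORY_ORDER:
            lines.append(
                f"  {cat.name:<26} {self.category_counts.get(cat, 0):>3} ({pcts[cat]}%)"
            )
        return "\n".join(lines)


def to_cluster_level(
    records: Sequence[AuditRecord], clusters: ClusterSet
) -> list[ClusterAudit]:
    """One aggregate record per cluster containing at least one query."""
    by_cluster: dict[int, list[AuditRecord]] = {}
    for rec in records:
        cid = clusters.cluster_of(rec.query_id)
        by_cluster.setdefault(cid, []).append(rec)
    out = []
    for cid in sorted(by_cluster):
        members = by_cluster[cid]
        cats = sort_categories(c for rec in members for c in rec.categories)
        out.append(
            ClusterAudit(
                cluster_id=cid,
                query_ids=tuple(sorted(r.query_id for r in members)),
                morphology_labels=tuple(sorted({r.morphology_label for r in members})),
                problematic=any(r.problematic for r in members),
                categories=cats,
            )
        )
    return out


def summarize(
    cluster_records: Sequence[ClusterAudit], n_clusters_total: int | None = None
) -> AuditSummary:
    """Headline statistics over cluster-level records.

    ``n_clusters_total`` overrides the denominator when the record list
    covers only part of the clustering (e.g. only the problematic rows of
    a published table); clusters beyond the records are counted as clean.
    """
    n = n_clusters_total if n_clusters_total is not None else len(cluster_records)
    if n == 0:
        raise ValueError("no clusters to summarize")
    if n < len(cluster_records):
        raise ValueError("n_clusters_total smaller than the record list")
    counts: Counter = Counter()
    n_problematic = 0
    for rec in cluster_records:
        if rec.problematic:
            n_problematic += 1
        for cat in rec.categories:
            counts[cat] += 1
    return AuditSummary(
        n_clusters=n, n_problematic=n_problematic, category_counts=dict(counts)
    )
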