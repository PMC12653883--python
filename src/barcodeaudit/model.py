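"""Model/Results facade tying the audit stages into one object.

:class:`BarcodeAudit` is constructed from a labeled reference library and
a query set (plus optional range and synonymy tables); ``fit()`` runs the
full audit — similarity search, consensus identification, cluster
delimitation, category classification and geographic correction — and
returns an :class:`AuditResults` carrying the per-specimen records, the
cluster-level roll-up, the summary statistics and, on demand, the
neighbor-joining identification tree.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Sequence

from .aggregate import AuditSummary, ClusterAudit, summarize, to_cluster_level
from .classify import (
    AuditRecord,
    ClassifierSettings,
    apply_geographic_correction,
    classify,
)
from .cluster import ClusterSet, ClusterSettings, delimit, split_census
from .distance import DistanceMatrix, distance_matrix, nj_tree, similarity_matrix
from .identify import SearchSettings, consensus_identify, top_k_search
from .io_formats import (
    AuditReportRow,
    RangeTable,
    SynonymyTable,
    read_fasta_with_metadata,
    read_range_table,
    read_synonymy_table,
    write_audit_report,
    write_newick,
)
from .records import BarcodeRecord
from .tree import TreeNode


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


class BarcodeAudit:
    """The audit model: a reference library judged against morphology-labeled
    queries.

    Parameters
    ----------
    references, queries
        Barcode records with ``role`` "reference" and "query".
    ranges
        Species range table enabling the geographic-correction verdict;
        omit to leave the verdict "N/A"-or-"No"-free (all rows N/A unless
        undifferentiated, then computed from ranges).
    synonymy
        Name canonicalization and unresolved pairs; defaults to empty.
    """

    def __init__(
        self,
        references: Sequence[BarcodeRecord],
        queries: Sequence[BarcodeRecord],
        ranges: RangeTable | None = None,
        synonymy: SynonymyTable | None = None,
        search: SearchSettings = SearchSettings(),
        clustering: ClusterSettings = ClusterSettings(),
        classifier: ClassifierSettings = ClassifierSettings(),
    ) -> None:
        if not references:
            raise ValueError("reference library is empty")
        if not queries:
            raise ValueError("query set is empty")
        for q in queries:
            if q.role != "query":
                raise ValueError(f"record {q.record_id!r} in queries has role {q.role!r}")
        self.references = list(references)
        self.queries = list(queries)
        self.ranges = ranges
        self.synonymy = synonymy or SynonymyTable.empty()
        self.search = search
        self.clustering = clustering
        self.classifier = classifier

    @classmethod
    def from_files(
        cls,
        references_fasta,
        references_metadata,
        queries_fasta,
        queries_metadata,
        ranges_path=None,
        focal_region: str = "",
        synonymy_path=None,
        **settings,
    ) -> "BarcodeAudit":
        references = read_fasta_with_metadata(references_fasta, references_metadata)
        queries = read_fasta_with_metadata(queries_fasta, queries_metadata)
        ranges = (
            read_range_table(ranges_path, focal_region) if ranges_path is not None else None
        )
        synonymy = read_synonymy_table(synonymy_path) if synonymy_path is not None else None
        return cls(references, queries, ranges=ranges, synonymy=synonymy, **settings)

    def fit(self) -> "AuditResults":
        pooled = self.references + self.queries
        dm = distance_matrix(pooled, metric="k2p")
        labels = {r.record_id: r.species for r in self.references}
        clusters = delimit(dm, self.clustering, labels=labels)

        sims = similarity_matrix(self.queries, self.references)
        ref_species = Counter(self.synonymy.resolve(r.species) for r in self.references)

        records: list[AuditRecord] = []
        for i, query in enumerate(self.queries):
            hits = top_k_search(
                query, self.references, self.search, self.synonymy, _similarities=sims[i]
            )
            ident = consensus_identify(hits, self.search)
            rec = classify(
                query, hits, ident, clusters, self.synonymy, ref_species, self.classifier
            )
            if self.ranges is not None:
                rec = apply_geographic_correction(rec, self.ranges)
            records.append(rec)

        cluster_records = to_cluster_level(records, clusters)
        return AuditResults(
            model=self,
            records=records,
            clusters=clusters,
            cluster_records=cluster_records,
            distances=dm,
        )


@dataclass
class AuditResults:
    """Fitted audit: per-query verdicts plus cluster-level aggregates."""

    model: BarcodeAudit
    records: list[AuditRecord]
    clusters: ClusterSet
    cluster_records: list[ClusterAudit]
    distances: DistanceMatrix
    _tree: TreeNode | None = field(default=None, repr=False)

    @property
    def summary_stats(self) -> AuditSummary:
        return summarize(self.cluster_records)

    def summary(self) -> str:
        """Human-readable audit summary."""
        s = self.summary_stats
        header = (
            f"Barcode identification audit\n"
            f"references: {len(self.model.references)}  "
            f"queries: {len(self.model.queries)}\n"
        )
        return header + s.summary()

    def split_census(self) -> list[tuple[str, int]]:
        """Clusters per morphology label (values > 1 flag split species)."""
        return split_census(
            self.clusters, {q.record_id: q.morphology_label for q in self.model.queries}
        )

    def identification_tree(self) -> TreeNode:
        """Neighbor-joining identification tree over all pooled records."""
        if self._tree is None:
            self._tree = nj_tree(self.distances)
        return self._tree

    def report_rows(self) -> list[AuditReportRow]:
        rows = []
        for rec in self.records:
            ident = rec.identification
            rows.append(
                AuditReportRow(
                    query_id=rec.query_id,
                    morphology_label=rec.morphology_label,
                    majority_id=rec.majority_name,
                    other_ids=tuple((n, _round2(s)) for n, s in rec.conflicting),
                    final_id=ident.taxon,
                    final_rank=ident.rank,
                    confidence_pct=ident.confidence_pct,
                    categories=rec.categories,
                    geographic_correction=rec.geographic_correction,
                )
            )
        return rows

    def write_report(self, path) -> str:
        return write_audit_report(self.report_rows(), path)

    def write_tree(self, path) -> str:
        return write_newick(self.identification_tree(), path)

    def write_all(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.write_report(out / "report.tsv")
        self.write_tree(out / "tree.nwk")
        (out / "summary.txt").write_text(self.summary() + "\n", encoding="utf-8")
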