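"""Published in-study data shipped with the package.

``table1_problematic.tsv`` transcribes the 45 problematic specimen rows of
the published audit (abbreviated genus names expanded, indeterminate
"sp." entries omitted from the machine-readable conflict column, and the
published clustering encoded in ``cluster_id``).  ``table1_ranges.tsv``
gives ranges for the species conflicting with the undifferentiated rows,
relative to the focal Volga region (``VLG``).
"""

from __future__ import annotations

from importlib import resources

from ..categories import ProblemCategory
from ..classify import AuditRecord
from ..cluster import ClusterSet
from ..identify import IdentificationResult
from ..io_formats import RangeTable, _read_table, read_range_table

#: Total species clusters delimited in the published study (clean + problematic).
TABLE1_TOTAL_CLUSTERS = 76

_COLUMNS = (
    "query_id",
    "morphology_label",
    "majority_id",
    "other_ids_with_similarity",
    "final_id",
    "final_rank",
    "confidence_pct",
    "categories",
    "geographic_correction_printed",
    "cluster_id",
)


def _parse_conflicts(text: str) -> tuple[tuple[str, float], ...]:
    if not text:
        return ()
    out = []
    for chunk in text.split("; "):
        name, _, sim = chunk.rpartition(" (")
        out.append((name, float(sim.rstrip(")"))))
    return tuple(out)


def load_table1() -> tuple[list[AuditRecord], ClusterSet, dict[str, str]]:
    """The published problematic rows as audit records.

    Returns the 45 specimen-level records, a :class:`ClusterSet` encoding
    the published clustering of those specimens, and the published
    geographic-correction column keyed by query id.  Identification hit
    lists are not part of the published table and are left empty.
    """
    with resources.files(__package__).joinpath("table1_problematic.tsv").open(
        encoding="utf-8"
    ) as fh:
        rows = _read_table(fh, _COLUMNS)

    records: list[AuditRecord] = []
    printed_gc: dict[str, str] = {}
    members: dict[str, list[str]] = {}
    for row in rows:
        cats = tuple(
            ProblemCategory[name] for name in row["categories"].split(";") if name
        )
        ident = IdentificationResult(
            taxon=row["final_id"],
            rank=row["final_rank"],
            confidence_pct=int(row["confidence_pct"]),
        )
        records.append(
            AuditRecord(
                query_id=row["query_id"],
                morphology_label=row["morphology_label"],
                identification=ident,
                majority_name=row["majority_id"],
                conflicting=_parse_conflicts(row["other_ids_with_similarity"]),
                categories=cats,
                # the published column, coerced to the footnote's structure:
                # a non-N/A verdict is only meaningful for undifferentiated
                # rows (one published row diverges from its own footnote)
                geographic_correction=(
                    row["geographic_correction_printed"]
                    if ProblemCategory.UNDIFFERENTIATED in cats
                    or row["geographic_correction_printed"] == "N/A"
                    else "N/A"
                ),
            )
        )
        printed_gc[row["query_id"]] = row["geographic_correction_printed"]
        members.setdefault(row["cluster_id"], []).append(row["query_id"])

    slugs = sorted(members)
    clusters = ClusterSet(
        clusters={i: tuple(sorted(members[slug])) for i, slug in enumerate(slugs)},
        nn_distance={i: float("inf") for i in range(len(slugs))},
    )
    return records, clusters, printed_gc


def load_table1_ranges() -> RangeTable:
    """Range table for the undifferentiated-row conflicts (focal: VLG)."""
    with resources.files(__package__).joinpath("table1_ranges.tsv").open(
        encoding="utf-8"
    ) as fh:
        return read_range_table(fh, focal_region="VLG")
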