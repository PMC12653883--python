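"""Readers and writers for every external representation of the audit.

Sequences travel as standard FASTA (Biopython), specimen metadata in a
sidecar tab-separated table keyed by FASTA id, species ranges and the
synonymy table as TSV, the identification tree as Newick, and the audit
report as a Table-style TSV.  All tables are UTF-8, tab-separated, with
``#``-prefixed comment lines ignored.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import yaml
from Bio import SeqIO

from .categories import ProblemCategory, sort_categories
from .records import BarcodeRecord
from .tree import TreeNode

logger = logging.getLogger("barcodeaudit")

#: Sentinel returned by RangeTable for species with no known range.
UNKNOWN_RANGE = "unknown"

METADATA_COLUMNS = (
    "record_id",
    "species",
    "genus",
    "subfamily",
    "family",
    "regions",
    "role",
    "morphology_label",
)

REPORT_COLUMNS = (
    "query_id",
    "morphology_label",
    "majority_id",
    "other_ids_with_similarity",
    "final_id",
    "final_rank",
    "confidence_pct",
    "categories",
    "geographic_correction",
)


# ---------------------------------------------------------------------------
# generic TSV helpers


def _iter_tsv_rows(source: str | Path | TextIO) -> Iterable[list[str]]:
    if isinstance(source, (str, Path)):
        handle: TextIO = open(source, encoding="utf-8")
        close = True
    else:
        handle, close = source, False
    try:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield line.split("\t")
    finally:
        if close:
            handle.close()


def _read_table(source, columns: Sequence[str]) -> list[dict[str, str]]:
    rows = list(_iter_tsv_rows(source))
    if not rows:
        return []
    header = rows[0]
    if header != list(columns):
        raise ValueError(
            f"bad header: expected {list(columns)}, found {header}"
        )
    out = []
    for cells in rows[1:]:
        if len(cells) != len(columns):
            raise ValueError(f"row has {len(cells)} fields, expected {len(columns)}: {cells!r}")
        out.append(dict(zip(columns, cells)))
    return out


# ---------------------------------------------------------------------------
# FASTA + metadata


def read_fasta_with_metadata(
    fasta_source: str | Path | TextIO, metadata_source: str | Path | TextIO
) -> list[BarcodeRecord]:
    """Join a FASTA file with its sidecar specimen table.

    Every FASTA id must have exactly one metadata row; the FASTA order is
    preserved.  Sequences are uppercased ('U' normalized to 'T') and
    validated against the IUPAC alphabet.
    """
    meta_rows = _read_table(metadata_source, METADATA_COLUMNS)
    meta: dict[str, dict[str, str]] = {}
    for row in meta_rows:
        rid = row["record_id"]
        if rid in meta:
            raise ValueError(f"duplicate metadata row for id {rid!r}")
        meta[rid] = row

    records: list[BarcodeRecord] = []
    seen: set[str] = set()
    for seq_rec in SeqIO.parse(_ensure_handle(fasta_source), "fasta"):
        rid = seq_rec.id
        if rid in seen:
            raise ValueError(f"duplicate FASTA id {rid!r}")
        seen.add(rid)
        if rid not in meta:
            raise ValueError(f"FASTA id {rid!r} has no metadata row")
        row = meta[rid]
        regions = frozenset(r for r in row["regions"].split(";") if r)
        records.append(
            BarcodeRecord(
                record_id=rid,
                sequence=str(seq_rec.seq),
                species=row["species"],
                genus=row["genus"],
                subfamily=row["subfamily"],
                family=row["family"],
                regions=regions,
                role=row["role"],
                morphology_label=row["morphology_label"],
            )
        )
    return records


def _ensure_handle(source):
    if isinstance(source, (str, Path)):
        return str(source)
    return source


def write_fasta_with_metadata(
    records: Sequence[BarcodeRecord], fasta_path: str | Path, metadata_path: str | Path
) -> None:
    with open(fasta_path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">{rec.record_id}\n{rec.sequence}\n")
    with open(metadata_path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(METADATA_COLUMNS) + "\n")
        for rec in records:
            fh.write(
                "\t".join(
                    (
                        rec.record_id,
                        rec.species,
                        rec.genus,
                        rec.subfamily,
                        rec.family,
                        ";".join(sorted(rec.regions)),
                        rec.role,
                        rec.morphology_label,
                    )
                )
                + "\n"
            )


def filter_min_length(
    records: Sequence[BarcodeRecord], min_length: int
) -> list[BarcodeRecord]:
    """Drop records with fewer than ``min_length`` non-gap characters.

    Order-preserving and idempotent; logs how many records were removed.
    """
    if min_length <= 0:
        raise ValueError("min_length must be positive")
    kept = [r for r in records if r.ungapped_length >= min_length]
    removed = len(records) - len(kept)
    if removed:
        logger.info("filter_min_length: removed %d of %d records", removed, len(records))
    return kept


# ---------------------------------------------------------------------------
# range table


@dataclass
class RangeTable:
    """Species -> set of region codes, plus the focal region of the audit.

    Lookup of an absent species returns the explicit sentinel
    :data:`UNKNOWN_RANGE`, never an empty set.
    """

    ranges: dict[str, frozenset[str]] = field(default_factory=dict)
    focal_region: str = ""

    def __post_init__(self) -> None:
        if not self.focal_region:
            raise ValueError("RangeTable requires a focal region code")

    def regions_of(self, species: str) -> frozenset[str] | str:
        if species not in self.ranges:
            return UNKNOWN_RANGE
        return self.ranges[species]

    def occurs_in_focal(self, species: str) -> bool | str:
        """True/False if the range is known; UNKNOWN_RANGE otherwise."""
        regions = self.regions_of(species)
        if regions == UNKNOWN_RANGE:
            return UNKNOWN_RANGE
        return self.focal_region in regions


def read_range_table(source, focal_region: str) -> RangeTable:
    rows = _read_table(source, ("species", "regions"))
    ranges = {
        row["species"]: frozenset(r for r in row["regions"].split(";") if r)
        for row in rows
    }
    return RangeTable(ranges=ranges, focal_region=focal_region)


def write_range_table(table: RangeTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("species\tregions\n")
        for species in sorted(table.ranges):
            fh.write(f"{species}\t{';'.join(sorted(table.ranges[species]))}\n")


# ---------------------------------------------------------------------------
# synonymy table


@dataclass
class SynonymyTable:
    """Name canonicalization plus unresolved ("uncertain") species pairs.

    ``canonical`` maps any name to its valid name; resolving a resolved
    name is a no-op (validated at construction: idempotent, acyclic).
    ``uncertain_pairs`` holds unordered pairs whose taxonomy is unsettled;
    those names do *not* collapse into one another.
    """

    canonical: dict[str, str] = field(default_factory=dict)
    uncertain_pairs: set[frozenset[str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        for name, valid in self.canonical.items():
            final = self.canonical.get(valid, valid)
            if final != valid:
                raise ValueError(
                    f"synonymy not idempotent: {name!r} -> {valid!r} -> {final!r}"
                )
            if valid == name and self.canonical[name] != name:
                raise ValueError(f"synonymy cycle at {name!r}")

    def resolve(self, name: str) -> str:
        return self.canonical.get(name, name)

    def is_uncertain_pair(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.uncertain_pairs

    @classmethod
    def empty(cls) -> "SynonymyTable":
        return cls()


def read_synonymy_table(source) -> SynonymyTable:
    rows = _read_table(source, ("name", "valid_name", "uncertain_flag"))
    canonical: dict[str, str] = {}
    uncertain: set[frozenset[str]] = set()
    for row in rows:
        name, valid, flag = row["name"], row["valid_name"], row["uncertain_flag"]
        if flag == "1":
            uncertain.add(frozenset((name, valid)))
        elif name != valid:
            canonical[name] = valid
    return SynonymyTable(canonical=canonical, uncertain_pairs=uncertain)


def write_synonymy_table(table: SynonymyTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("name\tvalid_name\tuncertain_flag\n")
        for name in sorted(table.canonical):
            fh.write(f"{name}\t{table.canonical[name]}\t0\n")
        for pair in sorted(table.uncertain_pairs, key=sorted):
            a, b = sorted(pair)
            fh.write(f"{a}\t{b}\t1\n")


# ---------------------------------------------------------------------------
# audit report


@dataclass(frozen=True)
class AuditReportRow:
    """One row of the audit report (one query specimen)."""

    query_id: str
    morphology_label: str
    majority_id: str
    #: (name, similarity %) pairs for conflicting names, best first.
    other_ids: tuple[tuple[str, float], ...]
    final_id: str
    final_rank: str
    confidence_pct: int | None
    categories: tuple[ProblemCategory, ...]
    geographic_correction: str  # "Yes" | "No" | "N/A"

    def __post_init__(self) -> None:
        if self.confidence_pct is not None and not (0 <= self.confidence_pct <= 100):
            raise ValueError(f"{self.query_id}: confidence {self.confidence_pct} outside [0, 100]")
        if self.geographic_correction not in ("Yes", "No", "N/A"):
            raise ValueError(f"{self.query_id}: bad geographic correction {self.geographic_correction!r}")
        if (
            self.geographic_correction != "N/A"
            and ProblemCategory.UNDIFFERENTIATED not in self.categories
        ):
            raise ValueError(
                f"{self.query_id}: geographic correction only applies to "
                "undifferentiated barcodes"
            )
        object.__setattr__(self, "categories", sort_categories(self.categories))


def _format_other_ids(other_ids: tuple[tuple[str, float], ...]) -> str:
    return "; ".join(f"{name} ({sim:.2f})" for name, sim in other_ids)


def _parse_other_ids(text: str) -> tuple[tuple[str, float], ...]:
    if not text:
        return ()
    out = []
    for chunk in text.split("; "):
        name, _, simpart = chunk.rpartition(" (")
        out.append((name, float(simpart.rstrip(")"))))
    return tuple(out)


def write_audit_report(rows: Sequence[AuditReportRow], path: str | Path | None = None) -> str:
    """Serialize report rows as a deterministic TSV; returns the text."""
    buf = io.StringIO()
    buf.write("\t".join(REPORT_COLUMNS) + "\n")
    for row in rows:
        buf.write(
            "\t".join(
                (
                    row.query_id,
                    row.morphology_label,
                    row.majority_id,
                    _format_other_ids(row.other_ids),
                    row.final_id,
                    row.final_rank,
                    "" if row.confidence_pct is None else str(row.confidence_pct),
                    ";".join(c.name for c in row.categories),
                    row.geographic_correction,
                )
            )
            + "\n"
        )
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def read_audit_report(source) -> list[AuditReportRow]:
    rows = _read_table(
        source if not isinstance(source, str) or "\t" not in source else io.StringIO(source),
        REPORT_COLUMNS,
    )
    out = []
    for row in rows:
        cats = tuple(
            ProblemCategory[name] for name in row["categories"].split(";") if name
        )
        out.append(
            AuditReportRow(
                query_id=row["query_id"],
                morphology_label=row["morphology_label"],
                majority_id=row["majority_id"],
                other_ids=_parse_other_ids(row["other_ids_with_similarity"]),
                final_id=row["final_id"],
                final_rank=row["final_rank"],
                confidence_pct=(
                    None if row["confidence_pct"] == "" else int(row["confidence_pct"])
                ),
                categories=cats,
                geographic_correction=row["geographic_correction"],
            )
        )
    return out


# ---------------------------------------------------------------------------
# Newick


def write_newick(tree: TreeNode, path: str | Path | None = None) -> str:
    """Serialize a tree in the package's fixed Newick dialect.

    Branch lengths to 6 decimals; leaf labels are record ids; a lone leaf
    becomes ``(label:0.000000);``.  Unlabeled leaves are an error.
    """

    def render(node: TreeNode, length: float) -> str:
        if node.is_leaf:
            if not node.label:
                raise ValueError("unlabeled leaf in tree")
            return f"{node.label}:{length:.6f}"
        inner = ",".join(render(c, l) for c, l in node.children)
        return f"({inner}):{length:.6f}"

    if tree.is_leaf:
        if not tree.label:
            raise ValueError("unlabeled leaf in tree")
        text = f"({tree.label}:0.000000);"
    else:
        inner = ",".join(render(c, l) for c, l in tree.children)
        text = f"({inner});"
    if path is not None:
        Path(path).write_text(text + "\n", encoding="utf-8")
    return text


def read_newick(source: str | Path) -> TreeNode:
    """Parse Newick (via dendropy) back into a :class:`TreeNode`."""
    import dendropy

    if isinstance(source, Path) or (isinstance(source, str) and Path(source).exists()):
        dtree = dendropy.Tree.get(path=str(source), schema="newick")
    else:
        dtree = dendropy.Tree.get(data=source, schema="newick")

    def convert(dnode) -> TreeNode:
        if dnode.is_leaf():
            return TreeNode(label=dnode.taxon.label.replace(" ", "_") if dnode.taxon else None)
        node = TreeNode()
        for child in dnode.child_nodes():
            node.children.append((convert(child), child.edge.length or 0.0))
        return node

    return convert(dtree.seed_node)


# ---------------------------------------------------------------------------
# YAML configuration


def load_config(source: str | Path | TextIO) -> dict:
    """Load an audit/simulation YAML config into a plain mapping."""
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            return yaml.safe_load(fh) or {}
    return yaml.safe_load(source) or {}
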