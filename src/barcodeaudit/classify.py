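"""Classification of problematic identifications into the six categories.

Each problematic query is explained by one or more mechanisms: a sporadic
conspecific reference deposited under a congener's name (species
mislabel), a reference mislabeled across genera or families
(contamination/label swap), genuinely shared barcodes between species
(undifferentiated), synonym or unresolved name pairs (taxonomy
uncertainty), a deeply diverged conspecific haplotype (anomalous
barcode), or the complete absence of conspecific references (database
incompleteness).  The paper trail the rules consume is the hit list, the
cluster partition, the synonymy table and the species ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .categories import ProblemCategory, sort_categories
from .cluster import ClusterSet
from .identify import Hit, IdentificationResult, is_problematic
from .io_formats import UNKNOWN_RANGE, RangeTable, SynonymyTable
from .records import BarcodeRecord


@dataclass(frozen=True)
class ClassifierSettings:
    #: a discordant name is "sporadic" unless its hit-share reaches this
    mislabel_max_fraction: float = 0.20
    #: hits needed for a discordant name to count as well-represented
    min_represented: int = 2
    #: below this best-same-name similarity, suspect anomaly/incompleteness
    conspecific_floor_pct: float = 99.0

    def __post_init__(self) -> None:
        if not (0 < self.mislabel_max_fraction < 0.5):
            raise ValueError("mislabel_max_fraction must lie in (0, 0.5)")


@dataclass(frozen=True)
class AuditRecord:
    query_id: str
    morphology_label: str
    identification: IdentificationResult
    majority_name: str
    #: conflicting (discordant) names with the best similarity of each
    conflicting: tuple[tuple[str, float], ...]
    categories: tuple[ProblemCategory, ...]
    geographic_correction: str = "N/A"

    def __post_init__(self) -> None:
        object.__setattr__(self, "categories", sort_categories(self.categories))

    @property
    def problematic(self) -> bool:
        return is_problematic(self.identification)


def _majority_name(hits: Sequence[Hit]) -> str:
    """Most frequent canonical species; ties by best similarity, then name."""
    stats: dict[str, list] = {}
    for h in hits:
        st = stats.setdefault(h.species, [0, -1.0])
        st[0] += 1
        st[1] = max(st[1], h.similarity)
    return min(stats, key=lambda s: (-stats[s][0], -stats[s][1], s))


def _census_count(census, name: str, synonymy: SynonymyTable) -> int:
    """Records in a cluster census whose displayed label resolves to name."""
    if census is None:
        return 0
    return sum(c for label, c in census.items() if label and synonymy.resolve(label) == name)


def classify(
    query: BarcodeRecord,
    hits: Sequence[Hit],
    identification: IdentificationResult,
    clusters: ClusterSet,
    synonymy: SynonymyTable,
    reference_species: Mapping[str, int],
    settings: ClassifierSettings = ClassifierSettings(),
) -> AuditRecord:
    """Assign problem categories to one query.

    ``reference_species`` maps each canonical species name to its number
    of reference records in the library (needed to tell an anomalous
    conspecific haplotype apart from a species missing from the library).
    Hit labels must already be synonym-canonicalized (``Hit.species``);
    raw deposited names are consulted for the taxonomy-uncertainty rule.
    """
    hits = tuple(hits)
    morph = synonymy.resolve(query.morphology_label)

    if not is_problematic(identification):
        return AuditRecord(
            query_id=query.record_id,
            morphology_label=query.morphology_label,
            identification=identification,
            majority_name=_majority_name(hits) if hits else "",
            conflicting=(),
            categories=(),
        )

    cats: set[ProblemCategory] = set()
    conflicting: list[tuple[str, float]] = []
    query_cluster = clusters.cluster_of(query.record_id)

    majority = _majority_name(hits) if hits else ""
    majority_hits = [h for h in hits if h.species == majority]
    majority_genus = majority_hits[0].genus if majority_hits else ""
    majority_family = majority_hits[0].family if majority_hits else ""

    # per-discordant-name statistics
    by_name: dict[str, list[Hit]] = {}
    for h in hits:
        if h.species != majority:
            by_name.setdefault(h.species, []).append(h)

    floor = settings.conspecific_floor_pct

    # R2 — cross-genus/family contamination: a conspecific-grade hit from
    # a different genus or family than the majority name.
    for h in hits:
        if h.similarity >= floor and (
            h.genus != majority_genus or h.family != majority_family
        ):
            cats.add(ProblemCategory.CROSS_GENUS_CONTAMINATION)
            break

    # R4 — taxonomy uncertainty: a discordant name forming an unresolved
    # pair with the majority name, or a raw deposited name that the
    # synonymy table collapses into the majority name.
    r4_names: set[str] = set()
    for name in by_name:
        if synonymy.is_uncertain_pair(name, majority):
            cats.add(ProblemCategory.TAXONOMY_UNCERTAINTY)
            r4_names.add(name)
    for h in hits:
        if h.raw_species != h.species and h.species == majority:
            cats.add(ProblemCategory.TAXONOMY_UNCERTAINTY)

    for name, name_hits in by_name.items():
        count = len(name_hits)
        share = count / len(hits)
        best = max(h.similarity for h in name_hits)
        conflicting.append((name, best))
        genus = name_hits[0].genus
        if genus != majority_genus:
            continue  # congeneric rules only
        well_represented = count >= settings.min_represented and share >= settings.mislabel_max_fraction
        if not well_represented:
            # R1 — sporadic congeneric mislabel sitting inside the cluster
            # dominated by the majority name.
            inside_dominated = any(
                _census_count(clusters.label_census.get(clusters.cluster_of(h.reference_id)), majority, synonymy)
                > _census_count(clusters.label_census.get(clusters.cluster_of(h.reference_id)), name, synonymy)
                for h in name_hits
            )
            if inside_dominated:
                cats.add(ProblemCategory.SPECIES_MISLABEL)
        elif name not in r4_names:
            # R3 — well-represented congeneric name sharing the query's
            # cluster: genuinely undifferentiated barcodes.
            if any(clusters.cluster_of(h.reference_id) == query_cluster for h in name_hits):
                cats.add(ProblemCategory.UNDIFFERENTIATED)

    # R5/R6 — same-name evidence in the library.
    same_name_hits = [h for h in hits if h.species == morph]
    best_same = max((h.similarity for h in same_name_hits), default=None)
    refs_exist = reference_species.get(morph, 0) > 0
    cluster_census = clusters.label_census.get(query_cluster)
    same_name_in_cluster = _census_count(cluster_census, morph, synonymy) > 0
    if refs_exist:
        if (best_same is None or best_same < floor) and not same_name_in_cluster:
            cats.add(ProblemCategory.ANOMALOUS_BARCODE)
    else:
        if best_same is None or best_same < floor:
            if not any(h.similarity >= floor for h in hits):
                cats.add(ProblemCategory.DB_INCOMPLETE)

    conflicting.sort(key=lambda t: (-t[1], t[0]))
    return AuditRecord(
        query_id=query.record_id,
        morphology_label=query.morphology_label,
        identification=identification,
        majority_name=majority,
        conflicting=tuple(conflicting),
        categories=tuple(cats),
    )


def geographic_correction(record: AuditRecord, ranges: RangeTable) -> str:
    """Footnote-style Yes/No/N/A verdict for an undifferentiated call.

    Applicable only when the problem is undifferentiated barcodes.  The
    identification is rescued ("Yes") only when *every* conflicting
    species is known to be absent from the focal region; a conflicting
    species present in the region, or with an unknown range, blocks the
    rescue ("No").
    """
    if ProblemCategory.UNDIFFERENTIATED not in record.categories:
        return "N/A"
    for name, _sim in record.conflicting:
        occurs = ranges.occurs_in_focal(name)
        if occurs is True or occurs == UNKNOWN_RANGE:
            return "No"
    return "Yes"


def apply_geographic_correction(record: AuditRecord, ranges: RangeTable) -> AuditRecord:
    return replace(record, geographic_correction=geographic_correction(record, ranges))
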