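"""BOLD-style molecular identification from a labeled reference library.

A query is compared against every reference; the up-to-``k`` most similar
references above the search depth form the hit list, and a deterministic
consensus over the hit labels yields the final identification, escalating
from species to genus, subfamily and family when the best ("co-best")
hits disagree.  The confidence is the rounded share of retained hits
supporting the returned taxon, which reproduces the familiar 96/92/100
pattern of 24/25, 23/25 and 25/25 conspecific hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

from .distance import similarity_matrix
from .io_formats import SynonymyTable
from .records import BarcodeRecord


@dataclass(frozen=True)
class SearchSettings:
    k: int = 25
    depth_pct: float = 94.0  # similarity floor of the search
    species_match_pct: float = 99.0  # conspecific-grade similarity
    delta_top_pct: float = 0.5  # window below the best hit for "co-best"

    def __post_init__(self) -> None:
        if not (0 < self.depth_pct < self.species_match_pct <= 100):
            raise ValueError("need 0 < depth_pct < species_match_pct <= 100")
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass(frozen=True)
class Hit:
    reference_id: str
    similarity: float  # unrounded percent identity
    species: str  # canonicalized name
    raw_species: str  # name as deposited, before synonym resolution
    genus: str
    subfamily: str
    family: str

    @property
    def similarity_2dp(self) -> float:
        return float(
            Decimal(repr(self.similarity)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
        )


@dataclass(frozen=True)
class IdentificationResult:
    taxon: str
    rank: str  # "species" | "genus" | "subfamily" | "family" | "none"
    confidence_pct: int | None
    hits: tuple[Hit, ...] = field(default_factory=tuple, repr=False)

    def __post_init__(self) -> None:
        if self.rank == "none":
            if self.hits and self.taxon != "unidentified":
                raise ValueError("rank none must be 'unidentified'")
        elif self.confidence_pct is not None and not (0 < self.confidence_pct <= 100):
            raise ValueError(f"confidence {self.confidence_pct} outside (0, 100]")


def _make_hit(ref: BarcodeRecord, similarity: float, synonymy: SynonymyTable) -> Hit:
    return Hit(
        reference_id=ref.record_id,
        similarity=similarity,
        species=synonymy.resolve(ref.species),
        raw_species=ref.species,
        genus=ref.genus,
        subfamily=ref.subfamily,
        family=ref.family,
    )


def top_k_search(
    query: BarcodeRecord,
    references: Sequence[BarcodeRecord],
    settings: SearchSettings = SearchSettings(),
    synonymy: SynonymyTable | None = None,
    _similarities: Sequence[float] | None = None,
) -> tuple[Hit, ...]:
    """Up to ``k`` most similar references within the search depth.

    Hits are sorted by similarity descending, ties by reference id
    ascending.  The query never matches its own record id, but exact
    sequence duplicates under other ids are legitimate hits.
    ``_similarities`` lets a caller reuse precomputed percent identities
    (same order as ``references``).
    """
    if not references:
        raise ValueError("reference library is empty")
    synonymy = synonymy or SynonymyTable.empty()
    if _similarities is None:
        sims = similarity_matrix([query], references)[0]
    else:
        sims = _similarities
    candidates = [
        (float(s), ref)
        for s, ref in zip(sims, references)
        if ref.record_id != query.record_id and float(s) >= settings.depth_pct
    ]
    candidates.sort(key=lambda t: (-t[0], t[1].record_id))
    return tuple(_make_hit(ref, s, synonymy) for s, ref in candidates[: settings.k])


_ESCALATION = (
    ("genus", lambda h: h.genus),
    ("subfamily", lambda h: h.subfamily),
    ("family", lambda h: h.family),
)


def consensus_identify(
    hits: Sequence[Hit], settings: SearchSettings = SearchSettings()
) -> IdentificationResult:
    """Deterministic consensus identification from a sorted hit list.

    Species whose best hit lies within ``delta_top_pct`` of the best
    similarity are "co-best".  A single co-best species gives a
    species-rank call; otherwise the call escalates to the lowest rank
    shared by all co-best species.  Confidence is the rounded share of
    all retained hits labeled with the returned taxon.
    """
    hits = tuple(hits)
    if not hits:
        return IdentificationResult(taxon="unidentified", rank="none", confidence_pct=None)
    best = hits[0].similarity
    co_best = [h for h in hits if h.similarity >= best - settings.delta_top_pct]
    co_species = {h.species for h in co_best}

    def conf(count: int) -> int:
        return int(Decimal(100 * count) / Decimal(len(hits)) + Decimal("0.5"))

    if len(co_species) == 1:
        taxon = next(iter(co_species))
        n = sum(1 for h in hits if h.species == taxon)
        return IdentificationResult(taxon=taxon, rank="species", confidence_pct=conf(n), hits=hits)
    for rank, key in _ESCALATION:
        labels = {key(h) for h in co_best}
        if len(labels) == 1:
            taxon = next(iter(labels))
            n = sum(1 for h in hits if key(h) == taxon)
            return IdentificationResult(taxon=taxon, rank=rank, confidence_pct=conf(n), hits=hits)
    return IdentificationResult(taxon="unidentified", rank="none", confidence_pct=None, hits=hits)


def is_problematic(result: IdentificationResult) -> bool:
    """True when the call is coarser than species or below 100% confidence."""
    if result.rank != "species":
        return True
    return (result.confidence_pct or 0) < 100
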