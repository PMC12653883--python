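"""Audit classifier: the six category rules and the geographic correction."""

from __future__ import annotations

from collections import Counter

import pytest

from barcodeaudit.categories import ProblemCategory as PC
from barcodeaudit.classify import (
    AuditRecord,
    ClassifierSettings,
    classify,
    geographic_correction,
)
from barcodeaudit.cluster import ClusterSet
from barcodeaudit.identify import Hit, SearchSettings, consensus_identify
from barcodeaudit.io_formats import RangeTable, SynonymyTable
from barcodeaudit.records import BarcodeRecord

SEQ = "ACGT" * 165  # placeholder barcode; classification never reads it


def make_query(morph="Aus bus"):
    return BarcodeRecord(record_id="q", sequence=SEQ, role="query",
                         morphology_label=morph)


def make_hit(ref_id, sim, species, genus=None, subfamily=None, family=None,
             raw=None):
    genus = genus if genus is not None else species.split()[0]
    return Hit(reference_id=ref_id, similarity=sim, species=species,
               raw_species=raw or species, genus=genus,
               subfamily=subfamily or genus + "-sub",
               family=family or genus + "-fam")


def make_clusters(assignment, labels):
    """ClusterSet from record->group mapping and reference display labels."""
    groups = {}
    for rid, slug in assignment.items():
        groups.setdefault(slug, []).append(rid)
    slugs = sorted(groups, key=lambda s: min(groups[s]))
    clusters = {i: tuple(sorted(groups[s])) for i, s in enumerate(slugs)}
    census = {
        i: Counter(labels[r] for r in members if r in labels)
        for i, members in clusters.items()
    }
    return ClusterSet(clusters=clusters,
                      nn_distance={i: float("inf") for i in clusters},
                      label_census=census)


def run_classify(query, hits, assignment, labels, synonymy=None, ref_species=None,
                 settings=ClassifierSettings()):
    hits = tuple(sorted(hits, key=lambda h: (-h.similarity, h.reference_id)))
    clusters = make_clusters(assignment, labels)
    ident = consensus_identify(hits, SearchSettings())
    if ref_species is None:
        ref_species = Counter(labels.values())
    return classify(query, hits, ident, clusters, synonymy or SynonymyTable.empty(),
                    ref_species, settings)


class TestCategoryRules:
    def test_cross_genus_contamination(self):
        # one conspecific-grade hit from a different family among 24 clean ones
        query = make_query("Erynnis tages")
        hits = [make_hit(f"r{i:02d}", 100.0, "Erynnis tages", family="Hesperiidae")
                for i in range(24)]
        hits.append(make_hit("x1", 100.0, "Colias alfacariensis", family="Pieridae"))
        assignment = {h.reference_id: "c1" for h in hits} | {"q": "c1"}
        labels = {h.reference_id: h.species for h in hits}
        rec = run_classify(query, hits, assignment, labels)
        assert rec.categories == (PC.CROSS_GENUS_CONTAMINATION,)
        assert rec.problematic

    def test_sporadic_congeneric_mislabel(self):
        # a single congeneric name inside the cluster dominated by the majority
        query = make_query("Aus bus")
        hits = [make_hit(f"r{i}", 99.5, "Aus bus") for i in range(4)]
        hits.append(make_hit("m1", 99.5, "Aus cus", genus="Aus"))
        assignment = {h.reference_id: "c1" for h in hits} | {"q": "c1"}
        labels = {h.reference_id: h.species for h in hits}
        rec = run_classify(query, hits, assignment, labels,
                           ref_species=Counter({"Aus bus": 4, "Aus cus": 5}))
        assert rec.categories == (PC.SPECIES_MISLABEL,)

    def test_undifferentiated_equal_shares(self):
        # three congeneric names with comparable frequency at 100%
        query = make_query("Carcharodus alceae")
        hits = []
        for i, name in enumerate(
            ["Carcharodus alceae", "Carcharodus floccifera", "Carcharodus stauderi"] * 8
        ):
            hits.append(make_hit(f"r{i:02d}", 100.0, name, genus="Carcharodus"))
        assignment = {h.reference_id: "c1" for h in hits} | {"q": "c1"}
        labels = {h.reference_id: h.species for h in hits}
        rec = run_classify(query, hits, assignment, labels)
        assert rec.categories == (PC.UNDIFFERENTIATED,)

    def test_taxonomy_uncertainty_from_uncertain_pair(self):
        query = make_query("Muschampia proteides")
        hits = [make_hit(f"r{i}", 100.0, "Muschampia proteides") for i in range(3)]
        hits += [make_hit(f"s{i}", 100.0, "Muschampia sovietica") for i in range(2)]
        synonymy = SynonymyTable(
            uncertain_pairs={frozenset({"Muschampia proteides", "Muschampia sovietica"})}
        )
        assignment = {h.reference_id: "c1" for h in hits} | {"q": "c1"}
        labels = {h.reference_id: h.species for h in hits}
        rec = run_classify(query, hits, assignment, labels, synonymy=synonymy)
        assert rec.categories == (PC.TAXONOMY_UNCERTAINTY,)
        assert rec.identification.rank == "genus"  # conflict escalates the call

    def test_taxonomy_uncertainty_from_canonicalized_raw_name(self):
        # a raw deposited synonym collapsing into the majority name
        query = make_query("Aus bus")
        hits = [make_hit(f"r{i}", 99.6, "Aus bus") for i in range(3)]
        hits.append(make_hit("s0", 99.6, "Aus bus", raw="Aus bussyn"))
        hits.append(make_hit("d0", 99.6, "Aus dus", genus="Aus"))
        assignment = {h.reference_id: "c1" for h in hits} | {"q": "c1"}
        labels = {h.reference_id: h.species for h in hits}
        rec = run_classify(query, hits, assignment, labels)
        assert PC.TAXONOMY_UNCERTAINTY in rec.categories

    def test_anomalous_barcode(self):
        # conspecific hits below the floor; own cluster far from conspecifics
        query = make_query("Hyponephele lycaon")
        hits = [
            make_hit("r0", 98.26, "Hyponephele lycaon", subfamily="Satyrinae"),
            make_hit("r1", 98.11, "Hyponephele lycaon", subfamily="Satyrinae"),
            make_hit("r2", 98.10, "Coenonympha pamphilus", subfamily="Satyrinae"),
        ]
        assignment = {"r0": "main", "r1": "main", "r2": "coen", "q": "apart"}
        labels = {h.reference_id: h.species for h in hits}
        rec = run_classify(query, hits, assignment, labels)
        assert rec.categories == (PC.ANOMALOUS_BARCODE,)
        assert rec.identification.rank == "subfamily"

    def test_db_incomplete(self):
        # no conspecific reference anywhere; best congener at 98.72%
        query = make_query("Polyommatus damocles")
        hits = [
            make_hit("r0", 98.72, "Polyommatus altivagans"),
            make_hit("r1", 98.72, "Polyommatus altivagans"),
            make_hit("r2", 98.27, "Polyommatus icarus"),
        ]
        assignment = {"r0": "alt", "r1": "alt", "r2": "ica", "q": "own"}
        labels = {h.reference_id: h.species for h in hits}
        rec = run_classify(query, hits, assignment, labels)
        assert rec.categories == (PC.DB_INCOMPLETE,)

    def test_clean_query_has_no_categories(self):
        query = make_query("Aus bus")
        hits = [make_hit(f"r{i}", 100.0, "Aus bus") for i in range(25)]
        assignment = {h.reference_id: "c1" for h in hits} | {"q": "c1"}
        labels = {h.reference_id: h.species for h in hits}
        rec = run_classify(query, hits, assignment, labels)
        assert rec.categories == ()
        assert not rec.problematic

    def test_classification_deterministic(self):
        query = make_query("Aus bus")
        hits = [make_hit(f"r{i}", 99.5, "Aus bus") for i in range(4)]
        hits.append(make_hit("m1", 99.5, "Aus cus"))
        assignment = {h.reference_id: "c1" for h in hits} | {"q": "c1"}
        labels = {h.reference_id: h.species for h in hits}
        recs = [run_classify(query, hits, assignment, labels) for _ in range(3)]
        assert recs[0] == recs[1] == recs[2]


class TestGeographicCorrection:
    def _record(self, cats, conflicting):
        from barcodeaudit.identify import IdentificationResult

        return AuditRecord(
            query_id="q", morphology_label="Aus bus",
            identification=IdentificationResult(taxon="Aus", rank="genus",
                                                confidence_pct=100),
            majority_name="Aus bus", conflicting=conflicting, categories=cats,
        )

    def _ranges(self):
        return RangeTable(
            ranges={
                "Colias crocea": frozenset({"VLG", "MED"}),
                "Colias erate": frozenset({"VLG"}),
                "Davidina lederi": frozenset({"MNG"}),
                "Davidina dzhulukuli": frozenset({"ALT"}),
            },
            focal_region="VLG",
        )

    def test_conflict_present_in_focal_region(self):
        rec = self._record((PC.UNDIFFERENTIATED,), (("Colias crocea", 100.0),))
        assert geographic_correction(rec, self._ranges()) == "No"

    def test_conflicts_absent_from_focal_region(self):
        rec = self._record(
            (PC.UNDIFFERENTIATED,),
            (("Davidina dzhulukuli", 100.0), ("Davidina lederi", 99.66)),
        )
        assert geographic_correction(rec, self._ranges()) == "Yes"

    def test_unknown_range_blocks_rescue(self):
        rec = self._record((PC.UNDIFFERENTIATED,), (("Aus ignotus", 100.0),))
        assert geographic_correction(rec, self._ranges()) == "No"

    def test_not_applicable_without_undifferentiated(self):
        rec = self._record((PC.SPECIES_MISLABEL,), (("Colias crocea", 100.0),))
        assert geographic_correction(rec, self._ranges()) == "N/A"
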