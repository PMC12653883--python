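"""Synthetic COI reference libraries with known, injected error processes.

The generator builds a hierarchical taxonomy (families -> subfamilies ->
genera -> species), evolves barcode sequences down that hierarchy under a
two-class substitution process (transition weight kappa vs transversions),
radiates intraspecific haplotypes from each species ancestor (star
phylogeny), and then corrupts the library with each of the six error
processes the audit is designed to detect, at configurable rates, while
recording exact per-record ground truth.

Branch substitution counts are fixed at their expected value (with
stochastic rounding of the fractional part) rather than drawn per site;
this keeps realized divergences tightly around the configured ladder so
that the search depth, the 3% cluster threshold and the conspecific floor
separate the divergence classes deterministically, as the stated world
assumes.  Queries always carry their true species as the morphology
label: in the emulated study design queries are identified independently
from morphology.

Corruptions are applied in a fixed order (synonym renames, introgression
copies, anomalous haplotypes, species mislabels, cross-genus swaps,
species deletions); a record is touched by at most one process.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np

from .categories import ProblemCategory
from .classify import AuditRecord
from .io_formats import RangeTable, SynonymyTable
from .records import BarcodeRecord

_BASES = "AGCT"  # order matters: transition partner = index ^ 1


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_families: int = 5
    n_genera_per_family: int = 2
    n_species_per_genus: int = 5
    n_refs_per_species: int = 5
    n_queries_per_species: int = 2
    barcode_length: int = 658
    titv_ratio: float = 2.0  # transition weight kappa
    intraspecific_divergence: float = 0.005  # expected pairwise, within species
    interspecific_divergence: float = 0.04  # enforced minimum between congeners
    intergeneric_divergence: float = 0.10
    cluster_threshold: float = 0.03  # the ladder's middle rung
    # error-process rates
    p_species_mislabel: float = 0.0
    p_cross_genus_swap: float = 0.0
    n_introgression_pairs: int = 0
    n_synonym_pairs: int = 0
    p_anomalous: float = 0.0
    anomaly_divergence: float = 0.07
    p_missing_species: float = 0.0
    # geography
    region_pool: tuple[str, ...] = ("FOC", "RGA", "RGB", "RGC")
    focal_region: str = "FOC"

    def __post_init__(self) -> None:
        ladder = (
            self.intraspecific_divergence,
            self.cluster_threshold,
            self.interspecific_divergence,
            self.intergeneric_divergence,
        )
        if not all(a < b for a, b in zip(ladder, ladder[1:])):
            raise ValueError(f"divergence ladder not strictly increasing: {ladder}")
        for name in ("p_species_mislabel", "p_cross_genus_swap", "p_anomalous", "p_missing_species"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.focal_region not in self.region_pool:
            raise ValueError("focal region must be in the region pool")

    def single_fault(self, process: str) -> "SimulationConfig":
        """A copy with every error rate zeroed except ``process`` at its
        standard magnitude (used for per-category recovery scoring).

        ``process`` is one of the corruption tags: species_mislabel,
        cross_genus_swap, introgressed_shared_haplotype, synonym_name,
        anomalous_haplotype, missing_species.
        """
        field_of = dict(
            species_mislabel="p_species_mislabel",
            cross_genus_swap="p_cross_genus_swap",
            introgressed_shared_haplotype="n_introgression_pairs",
            synonym_name="n_synonym_pairs",
            anomalous_haplotype="p_anomalous",
            missing_species="p_missing_species",
        )
        standard = dict(
            p_species_mislabel=0.02,
            p_cross_genus_swap=0.02,
            n_introgression_pairs=2,
            n_synonym_pairs=2,
            p_anomalous=0.10,
            p_missing_species=0.10,
        )
        if process not in field_of:
            raise ValueError(f"unknown error process {process!r}")
        rates = {f: 0 if f.startswith("n_") else 0.0 for f in field_of.values()}
        fld = field_of[process]
        rates[fld] = standard[fld]
        from dataclasses import replace

        return replace(self, **rates)


#: corruption tags recorded in ErrorTruth
CORRUPTIONS = (
    "none",
    "species_mislabel",
    "cross_genus_swap",
    "introgressed_shared_haplotype",
    "synonym_name",
    "anomalous_haplotype",
)

#: corruption process -> the audit category that should recover it
PROCESS_TO_CATEGORY = {
    "species_mislabel": ProblemCategory.SPECIES_MISLABEL,
    "cross_genus_swap": ProblemCategory.CROSS_GENUS_CONTAMINATION,
    "introgressed_shared_haplotype": ProblemCategory.UNDIFFERENTIATED,
    "synonym_name": ProblemCategory.TAXONOMY_UNCERTAINTY,
    "anomalous_haplotype": ProblemCategory.ANOMALOUS_BARCODE,
    "missing_species": ProblemCategory.DB_INCOMPLETE,
}


@dataclass
class ErrorTruth:
    """Ground-truth corruption labels for every generated record."""

    true_species: dict[str, str] = dc_field(default_factory=dict)
    displayed_species: dict[str, str] = dc_field(default_factory=dict)
    corruption: dict[str, str] = dc_field(default_factory=dict)
    present_in_reference: dict[str, bool] = dc_field(default_factory=dict)

    def record(self, record_id: str, true_sp: str, displayed: str, corruption: str) -> None:
        if corruption == "none" and displayed != true_sp:
            raise ValueError(f"{record_id}: uncorrupted record with displayed != true")
        self.true_species[record_id] = true_sp
        self.displayed_species[record_id] = displayed
        self.corruption[record_id] = corruption


# ---------------------------------------------------------------------------
# sequence evolution


def _stochastic_round(x: float, rng: np.random.Generator) -> int:
    base = math.floor(x)
    return base + (1 if rng.random() < (x - base) else 0)


def _mutate(seq: np.ndarray, rate: float, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """Apply ``round(rate * L)`` substitutions at distinct random sites.

    Each substitution is a transition with probability kappa/(kappa+2),
    otherwise one of the two transversions uniformly.  Base encoding is
    A=0, G=1, C=2, T=3, so the transition partner is ``base ^ 1`` and the
    transversion partners are ``base ^ 2`` and ``base ^ 3``.
    """
    L = seq.size
    n_sub = min(_stochastic_round(rate * L, rng), L)
    if n_sub == 0:
        return seq.copy()
    sites = rng.choice(L, size=n_sub, replace=False)
    out = seq.copy()
    p_ts = kappa / (kappa + 2.0)
    for s in sites:
        if rng.random() < p_ts:
            out[s] ^= 1
        else:
            out[s] ^= 2 if rng.random() < 0.5 else 3
    return out


def _decode(seq: np.ndarray) -> str:
    return "".join(_BASES[b] for b in seq)


# ---------------------------------------------------------------------------
# the generator


@dataclass
class SimulatedLibrary:
    references: list[BarcodeRecord]
    queries: list[BarcodeRecord]
    ranges: RangeTable
    synonymy: SynonymyTable
    truth: ErrorTruth
    config: SimulationConfig


def simulate(config: SimulationConfig) -> SimulatedLibrary:
    """Generate a reference library, query set and ground truth."""
    rng = np.random.default_rng(config.seed)
    L = config.barcode_length
    kappa = config.titv_ratio

    # branch lengths (expected substitutions/site)
    intra_branch = config.intraspecific_divergence / 2.0
    # congener separation sits just under the intergeneric scale so that
    # congeners stay safely below the identification search depth while
    # realized minima still clear the configured interspecific floor
    species_branch = 0.45 * config.intergeneric_divergence
    genus_branch = config.intergeneric_divergence / 2.0
    family_branch = config.intergeneric_divergence

    root = rng.integers(0, 4, size=L).astype(np.uint8)

    species_meta: list[dict] = []
    species_anc: dict[str, np.ndarray] = {}
    for fi in range(config.n_families):
        family = f"Family{fi:02d}"
        fam_anc = _mutate(root, family_branch, kappa, rng)
        for gi in range(config.n_genera_per_family):
            subfamily = f"{family}-{'AB'[gi % 2]}"
            genus = f"Genus{fi:02d}{chr(ord('a') + gi)}"
            gen_anc = _mutate(fam_anc, genus_branch, kappa, rng)
            for si in range(config.n_species_per_genus):
                species = f"{genus} sp{si:02d}"
                anc = _mutate(gen_anc, species_branch, kappa, rng)
                species_anc[species] = anc
                species_meta.append(
                    dict(species=species, genus=genus, subfamily=subfamily, family=family)
                )

    # geography: every species occurs somewhere; ~70% also in the focal region
    non_focal = [r for r in config.region_pool if r != config.focal_region]
    ranges: dict[str, frozenset[str]] = {}
    for meta in species_meta:
        regs = set(rng.choice(non_focal, size=int(rng.integers(1, len(non_focal) + 1)), replace=False))
        if rng.random() < 0.7:
            regs.add(config.focal_region)
        ranges[meta["species"]] = frozenset(regs)

    references: list[BarcodeRecord] = []
    queries: list[BarcodeRecord] = []
    truth = ErrorTruth()
    ref_meta: list[dict] = []  # mutable staging before corruption
    qry_meta: list[dict] = []
    rid = 0
    for meta in species_meta:
        anc = species_anc[meta["species"]]
        for _ in range(config.n_refs_per_species):
            seq = _mutate(anc, intra_branch, kappa, rng)
            ref_meta.append(
                dict(meta, record_id=f"REF{rid:04d}", seq=seq,
                     true_species=meta["species"], corruption="none")
            )
            rid += 1
        for _ in range(config.n_queries_per_species):
            seq = _mutate(anc, intra_branch, kappa, rng)
            qry_meta.append(
                dict(meta, record_id=f"QRY{rid:04d}", seq=seq,
                     true_species=meta["species"], corruption="none")
            )
            rid += 1

    synonymy = _corrupt(config, rng, species_meta, species_anc, ref_meta, qry_meta,
                        intra_branch, kappa)

    deleted = _delete_species(config, rng, species_meta, ref_meta)

    for meta in species_meta:
        truth.present_in_reference[meta["species"]] = meta["species"] not in deleted

    for m in ref_meta:
        if m["true_species"] in deleted:
            continue
        references.append(
            BarcodeRecord(
                record_id=m["record_id"], sequence=_decode(m["seq"]),
                species=m["species"], genus=m["genus"], subfamily=m["subfamily"],
                family=m["family"], regions=ranges[m["true_species"]], role="reference",
            )
        )
        truth.record(m["record_id"], m["true_species"], m["species"], m["corruption"])
    for m in qry_meta:
        queries.append(
            BarcodeRecord(
                record_id=m["record_id"], sequence=_decode(m["seq"]),
                species="", genus=m["genus"], subfamily=m["subfamily"],
                family=m["family"], regions=frozenset({config.focal_region}),
                role="query", morphology_label=m["true_species"],
            )
        )
        truth.record(m["record_id"], m["true_species"], m["true_species"], m["corruption"])

    range_table = RangeTable(ranges=ranges, focal_region=config.focal_region)
    return SimulatedLibrary(
        references=references, queries=queries, ranges=range_table,
        synonymy=synonymy, truth=truth, config=config,
    )


def _corrupt(config, rng, species_meta, species_anc, ref_meta, qry_meta,
             intra_branch, kappa) -> SynonymyTable:
    """Apply the error processes in their fixed order; returns the
    synonymy table describing the injected unresolved name pairs."""
    by_species: dict[str, list[dict]] = {}
    for m in ref_meta:
        by_species.setdefault(m["true_species"], []).append(m)
    genera: dict[str, list[str]] = {}
    for meta in species_meta:
        genera.setdefault(meta["genus"], []).append(meta["species"])
    all_species = [m["species"] for m in species_meta]
    meta_of = {m["species"]: m for m in species_meta}

    uncertain: set[frozenset[str]] = set()

    # 1. synonym renames: part of a species' references deposited under an
    #    unresolved alternative name for the same taxon
    candidates = [s for s in all_species]
    if config.n_synonym_pairs:
        chosen = rng.choice(len(candidates), size=min(config.n_synonym_pairs, len(candidates)), replace=False)
        for idx in chosen:
            species = candidates[int(idx)]
            genus = meta_of[species]["genus"]
            syn = f"{genus} {species.split()[-1]}syn"
            uncertain.add(frozenset((species, syn)))
            refs = by_species[species]
            n_rename = max(2, len(refs) // 2)
            for m in refs[:n_rename]:
                if m["corruption"] != "none":
                    continue
                m["species"] = syn
                m["corruption"] = "synonym_name"

    # 2. introgression: a recipient species' references carry fresh copies
    #    of the donor's haplotypes (shared mitochondria), label unchanged
    if config.n_introgression_pairs:
        congener_pairs = [
            (a, b)
            for members in genera.values()
            for i, a in enumerate(members)
            for b in members[i + 1 :]
        ]
        order = rng.permutation(len(congener_pairs))
        used: set[str] = set()
        done = 0
        for idx in order:
            donor, recipient = congener_pairs[int(idx)]
            if done >= config.n_introgression_pairs:
                break
            if donor in used or recipient in used:
                continue
            clean = [m for m in by_species[recipient] if m["corruption"] == "none"]
            take = clean[: max(2, len(clean) // 2)]
            if len(take) < 2:
                continue
            for m in take:
                m["seq"] = _mutate(species_anc[donor], intra_branch, kappa, rng)
                m["corruption"] = "introgressed_shared_haplotype"
            used.update((donor, recipient))
            done += 1

    # 3. anomalous haplotypes: one query per selected species carries a
    #    deeply diverged (e.g. endosymbiont-associated) haplotype
    if config.p_anomalous:
        by_species_q: dict[str, list[dict]] = {}
        for m in qry_meta:
            by_species_q.setdefault(m["true_species"], []).append(m)
        for meta in species_meta:
            if rng.random() < config.p_anomalous:
                qs = [m for m in by_species_q.get(meta["species"], []) if m["corruption"] == "none"]
                if not qs:
                    continue
                q = qs[int(rng.integers(0, len(qs)))]
                q["seq"] = _mutate(species_anc[meta["species"]], config.anomaly_divergence, kappa, rng)
                q["corruption"] = "anomalous_haplotype"

    # 4. sporadic within-genus mislabels
    if config.p_species_mislabel:
        for m in ref_meta:
            if m["corruption"] != "none":
                continue
            congeners = [s for s in genera[m["genus"]] if s != m["true_species"]]
            if congeners and rng.random() < config.p_species_mislabel:
                m["species"] = congeners[int(rng.integers(0, len(congeners)))]
                m["corruption"] = "species_mislabel"

    # 5. cross-genus/family label swaps
    if config.p_cross_genus_swap:
        for m in ref_meta:
            if m["corruption"] != "none":
                continue
            if rng.random() < config.p_cross_genus_swap:
                others = [s for s in all_species if meta_of[s]["genus"] != m["genus"]]
                target = others[int(rng.integers(0, len(others)))]
                tm = meta_of[target]
                m["species"] = target
                m["genus"] = tm["genus"]
                m["subfamily"] = tm["subfamily"]
                m["family"] = tm["family"]
                m["corruption"] = "cross_genus_swap"

    return SynonymyTable(uncertain_pairs=uncertain)


def _delete_species(config, rng, species_meta, ref_meta) -> set[str]:
    """6. species absent from the reference library (queries kept)."""
    deleted: set[str] = set()
    if config.p_missing_species:
        for meta in species_meta:
            if rng.random() < config.p_missing_species:
                deleted.add(meta["species"])
    return deleted


# ---------------------------------------------------------------------------
# recovery scoring


def truth_positive_queries(
    records: Sequence[AuditRecord], truth: ErrorTruth, process: str
) -> set[str]:
    """Queries that *should* be flagged for ``process``.

    For reference-side corruptions these are the queries whose hit lists
    contain a corrupted record; anomalous haplotypes mark the corrupted
    query itself; deleted species mark all their queries.
    """
    out: set[str] = set()
    for rec in records:
        qid = rec.query_id
        if process == "anomalous_haplotype":
            if truth.corruption.get(qid) == "anomalous_haplotype":
                out.add(qid)
        elif process == "missing_species":
            if not truth.present_in_reference.get(truth.true_species.get(qid, ""), True):
                out.add(qid)
        else:
            for hit in rec.identification.hits:
                if truth.corruption.get(hit.reference_id) == process:
                    out.add(qid)
                    break
    return out


def score_recovery(
    records: Sequence[AuditRecord], truth: ErrorTruth
) -> dict[ProblemCategory, tuple[float, float, int]]:
    """Per-category (precision, recall, n_truth) of the audit vs ground truth.

    Precision and recall default to 1.0 when there are no predictions or
    no truth positives for a category.
    """
    scores: dict[ProblemCategory, tuple[float, float, int]] = {}
    for process, category in PROCESS_TO_CATEGORY.items():
        truth_set = truth_positive_queries(records, truth, process)
        predicted = {r.query_id for r in records if category in r.categories}
        tp = len(truth_set & predicted)
        precision = tp / len(predicted) if predicted else 1.0
        recall = tp / len(truth_set) if truth_set else 1.0
        scores[category] = (precision, recall, len(truth_set))
    return scores


def realized_divergences(lib: SimulatedLibrary) -> dict[str, float]:
    """Realized divergence ladder diagnostics on a generated library.

    Returns max within-species (non-anomalous) K2P distance, min
    between-species nearest-neighbor distance, and the mean intraspecific
    distance, computed over references plus queries.
    """
    from .distance import distance_matrix

    recs = [r for r in lib.references + lib.queries
            if lib.truth.corruption.get(r.record_id) != "anomalous_haplotype"]
    dm = distance_matrix(recs, metric="k2p")
    species = np.array([lib.truth.true_species[r.record_id] for r in recs])
    same = species[:, None] == species[None, :]
    off_diag = ~np.eye(len(recs), dtype=bool)
    within = dm.values[same & off_diag]
    between = dm.values[~same]
    return {
        "max_within": float(within.max()),
        "mean_within": float(within.mean()),
        "min_between": float(between.min()),
    }
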