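# Methods

This note documents the models, rules and numerical choices behind
`barcodeaudit`, what the synthetic generator does and does not emulate,
and the design decisions taken where the procedure was genuinely open.

## Distances

Sequences are assumed co-aligned over the barcode region; unequal lengths
are an error (no internal aligner is provided). Sites where either
sequence carries a gap or any IUPAC ambiguity code are excluded pair by
pair (*pairwise* deletion, the common barcode practice), and ambiguity
codes never count as matches even when compatible — an `R` never pairs
with an `A`. With P and Q the transition (A↔G, C↔T) and transversion
proportions over the compared sites, the Kimura two-parameter distance is

    d = -1/2 · ln[(1 - 2P - Q) · sqrt(1 - 2Q)]

A non-positive log argument means saturation: the scalar routine raises,
while matrix construction flags the entry as `inf` so downstream stages
can name the offending pairs. Percent identity is 100·(1−p) with p the
raw mismatch proportion, printed to two decimals (half away from zero).

## Identification

The search keeps the up-to-`k` (default 25) most similar references at or
above the `depth_pct` similarity floor (default 94%), sorted by
similarity then reference id; the query never matches its own record id,
but exact duplicates of its sequence under other ids are legitimate hits.

The consensus rule is a deterministic reconstruction of the behavior of
nearest-sequence identification engines, whose exact formulas are
unpublished. Species whose best hit lies within `delta_top_pct` (default
0.5%) of the best similarity are *co-best*. One co-best species → a
species-rank call; several → escalation to genus, then subfamily, then
family, stopping at the first rank all co-best hits share; no shared
family → "unidentified". Confidence is the rounded share of **all**
retained hits labeled with the returned taxon, which reproduces the
96/92/100 pattern of 24/25, 23/25, 25/25 conspecific hit lists. The
published per-query confidences also include values (83, 91, 94…) that
are not multiples of 4 — those are consistent with fewer than 25 retained
hits and cannot be reproduced without the underlying hit lists, so no
attempt is made. Canonical synonyms are collapsed into their valid name
*before* consensus (a curated synonymy resolves such conflicts);
*uncertain* pairs — names flagged as unresolved taxonomy — are
deliberately **not** collapsed, so they escalate the call exactly as the
raw conflict would, and are then explained by the classifier.

A call is *problematic* iff its rank is coarser than species or its
confidence is below 100%.

## Cluster delimitation

Single-linkage connected components under `K2P < merge_threshold`
(default 0.03) over the pooled reference+query matrix. The link relation
is strict, so a pair at exactly 3.0% stays split and every cluster's
nearest-neighbor distance is > 3% by construction. Cluster numbering is
deterministic (by smallest member id). Single linkage was chosen to
operationalize the nearest-neighbor-distance criterion used to call
discrete species groups; it is intentionally the simplest partition
consistent with that criterion, not a re-implementation of any database's
proprietary binning algorithm.

## Classification rules

Categories are assigned to problematic queries only, all that match.
Writing `majority` for the most frequent canonical hit name (ties broken
by best similarity, then lexicographically), `floor` for
`conspecific_floor_pct` (default 99%), and calling a discordant name
*well-represented* when it has ≥ `min_represented` (2) hits **and** a
hit-share ≥ `mislabel_max_fraction` (0.20):

* **Cross-genus contamination** — some hit at ≥ `floor` similarity
  belongs to a different genus or family than the majority name.
* **Species mislabel** — a discordant congeneric name that is *not*
  well-represented, whose hits sit inside a cluster dominated by the
  majority name. ("Sporadic" is defined as the complement of
  well-represented so the two rules partition the congeneric conflicts;
  thresholds defined with two independent conjunctions would leave an
  uncovered gap, e.g. one hit out of five.)
* **Taxonomy uncertainty** — a discordant name forming an uncertain pair
  with the majority name, or a raw deposited name that the synonymy
  table collapses into it. Takes precedence over the undifferentiated
  rule for the same name.
* **Undifferentiated barcodes** — a well-represented discordant
  congeneric name sharing the query's cluster, not explained by
  taxonomy uncertainty.
* **Anomalous barcode** — conspecific references exist in the library,
  but the best same-name hit is below `floor` (or absent) *and* the
  query's cluster contains no same-name reference: the query carries a
  haplotype that clusters away from all its conspecifics.
* **Database incompleteness** — no conspecific reference exists at all
  and no hit reaches `floor`.

The expert-judgment steps of a manual audit (voucher photographs,
literature checks) are replaced by these thresholds plus a curated
synonymy/uncertainty table supplied as input; that is a documented
divergence, not an oversight.

**Geographic correction.** Applicable only to undifferentiated calls.
"Yes" (identification rescued) only when *every* conflicting species has
a known range excluding the focal region; a conflicting species present
in the region — or with an unknown range — gives "No". The conservative
treatment of unknown ranges reflects that species are regularly found
beyond their recorded ranges.

## Aggregation

Specimen verdicts roll up to one record per cluster containing a query; a
cluster is problematic iff any member is, and its categories are the
union of member categories. Headline percentages: the problematic/clean
split is printed to 0 decimals (their sum is forced to 100 by
complementing), the not-library-incomplete share to 1 decimal. Category
breakdowns are computed over category assignments (a multi-category
cluster counts once per category) and are reported for orientation only —
when source tables carry alternative ("and/or") reasons the counting unit
is ambiguous, so no exact breakdown is asserted anywhere.

`summarize` accepts an explicit total-cluster denominator for the case
where only the problematic rows of a published table are available and
the clean clusters are known only by count.

## The synthetic generator

The generator's defaults are the stated world of the audited study
design: 658 bp barcodes, transition:transversion weight κ = 2, expected
intraspecific pairwise divergence 0.005, a 0.03 cluster threshold, a 0.04
minimum between congeners, 0.10 between genera, 0.07 anomaly divergence,
and (for the recovery experiments) 50 species with 5 references and 2
queries each.

Taxonomy is a balanced hierarchy (families → subfamilies → genera →
species). Sequences evolve from a random root down the hierarchy; within
species, haplotypes radiate independently from the species ancestor (a
star phylogeny — simpler than a coalescent and sufficient for the
divergence structure the audit consumes). Two deliberate choices:

* **Fixed substitution counts.** Each branch receives exactly its
  expected number of substitutions (stochastically rounding the
  fractional part), placed at random distinct sites, each a transition
  with probability κ/(κ+2). Site-i.i.d. Bernoulli mutation would add
  ±1% similarity noise per pair, enough to leak congeners across the 94%
  search depth and break the clean-library guarantee stochastically;
  with fixed counts the realized divergence ladder is tight around its
  design values and the guarantee is structural.
* **Congener placement.** The interspecific parameter is a *minimum*;
  species branches are set to 0.45× the intergeneric divergence, so
  realized congener distances (~0.09 K2P, ~91.5% similarity) sit safely
  below the 94% search depth. Placing congeners at the 0.04 floor
  itself would put them at ~96% similarity — inside the hit lists of
  every clean query, capping clean confidences at ~20% and contradicting
  the intended "clean library → all species calls at 100%" behavior.
  The generator validates that realized minima still exceed the
  configured floor.

Error processes, applied in a fixed order so ground truth is unambiguous
(each record is touched by at most one): synonym renames (part of a
species' references deposited under an unresolved alternative name, which
is also added to the synonymy table as an uncertain pair), introgression
(a recipient species' references replaced by fresh haplotypes of a
congeneric donor, label unchanged — one shared-haplotype cluster carrying
both names), anomalous haplotypes (one query per selected species
replaced by a 7%-divergent haplotype), sporadic within-genus mislabels,
cross-genus/family label swaps (the displayed name *and* its higher taxa
change), and species deletions (all references removed, queries kept).
Query morphology labels are always the truth, mirroring a study design in
which queries are identified independently from morphology.

What the generator does **not** emulate: rate variation among sites and
lineages, indels and alignment error, NUMTs as a distinct process
(anomalous haplotypes stand in for both), unbalanced taxon sampling, and
the sheer scale and heterogeneity of a real public library. A green
recovery test therefore establishes that each rule detects its intended
process under clean separation of divergence classes — not that the
thresholds are optimal on real data.

Recovery scoring: for each category, precision/recall of flagged queries
against the queries whose hit lists contain records corrupted by the
corresponding process (anomalous: the corrupted query itself; missing
species: all queries of a deleted species). Conventions: empty prediction
set → precision 1, empty truth set → recall 1.

## Numerical conventions

* Similarities compared unrounded; rounding to two decimals happens only
  at print time. Confidence rounds half away from zero to an integer.
* Neighbor joining: Saitou–Nei Q-criterion, ties broken by the lowest
  (row, column) pair in current matrix order; negative branch lengths
  clamped to zero with the excess moved to the sister branch; the final
  three nodes joined by the three-point formulas into a trifurcating
  root. On additive matrices the output reproduces all pairwise path
  lengths to 1e-9.
* Newick dialect: rooted, branch lengths always printed to six decimals,
  no internal labels, single leaf as `(label:0.000000);`.
* Tables are UTF-8 TSV with `#` comments; report rows serialize
  categories in fixed enum order, so output is byte-identical across
  runs.

## Known limitations

* The consensus confidence reproduces only the k=25 pattern; published
  confidences implying other denominators are out of reach without the
  original hit lists.
* The classifier's thresholds (0.20 hit-share, 2 hits, 99% floor) are
  design constants, not fitted quantities; on real libraries with dense
  conspecific sampling the mislabel/undifferentiated boundary will
  depend on them.
* Geographic correction treats ranges as authoritative; vagrancy,
  range expansion and cryptic species all violate that assumption, which
  is why unknown ranges block the rescue rather than permitting it.
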