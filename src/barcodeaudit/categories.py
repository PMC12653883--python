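"""The six problem categories a questionable identification can fall into.

Enum declaration order is the fixed serialization order used everywhere
(report columns, multi-category joins), so it must not be reordered.
"""

from __future__ import annotations

import enum


class ProblemCategory(enum.Enum):
    # A congeneric reference was deposited under the wrong species name;
    # such mislabels appear sporadically among correct identifications.
    SPECIES_MISLABEL = "species identification errors"
    # A reference is labeled with the wrong genus or family — contamination
    # or a clerical swap at submission time.
    CROSS_GENUS_CONTAMINATION = "possible contamination/inaccurate labeling"
    # Two or more species genuinely share (near-)identical barcodes, e.g.
    # through mitochondrial introgression or incomplete lineage sorting.
    UNDIFFERENTIATED = "undifferentiated DNA barcodes"
    # The conflicting names are synonyms or an unresolved species pair.
    TAXONOMY_UNCERTAINTY = "existing taxonomy uncertainty"
    # The query carries a haplotype far outside its species' normal
    # intraspecific range and clusters apart from its conspecifics.
    ANOMALOUS_BARCODE = "anomalous DNA barcodes"
    # No conspecific reference exists in the library at all.
    DB_INCOMPLETE = "incompleteness of the reference database"

    def __str__(self) -> str:  # serialized by name, not by description
        return self.name


#: Categories in fixed serialization order.
CATEGORY_ORDER: tuple[ProblemCategory, ...] = tuple(ProblemCategory)


def sort_categories(cats) -> tuple[ProblemCategory, ...]:
    """Return categories as a tuple in fixed enum-declaration order."""
    order = {c: i for i, c in enumerate(CATEGORY_ORDER)}
    return tuple(sorted(set(cats), key=order.__getitem__))
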