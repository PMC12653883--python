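"""Core specimen record type shared by every stage of the audit.

A :class:`BarcodeRecord` is one COI barcode together with its taxonomic
labels and provenance.  Reference records carry the label under which the
sequence was deposited (which may be wrong — that is what the audit is
for); query records additionally carry an independent morphology-based
identification used as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: IUPAC nucleotide one-letter codes, plus the alignment gap character.
IUPAC_CODES = frozenset("ACGTRYSWKMBDHVN-")

#: Codes treated as unambiguous when comparing sites.
UNAMBIGUOUS = frozenset("ACGT")

MIN_SEQ_LEN = 200
MAX_SEQ_LEN = 1600


class SequenceError(ValueError):
    """Raised for sequences violating length or alphabet constraints."""


def normalize_sequence(seq: str, record_id: str = "?") -> str:
    """Uppercase, map RNA 'U' to 'T', and validate the IUPAC alphabet.

    Raises :class:`SequenceError` naming the first illegal character and
    its 1-based position, or on out-of-range length.
    """
    s = seq.upper().replace("U", "T")
    for pos, ch in enumerate(s, start=1):
        if ch not in IUPAC_CODES:
            raise SequenceError(
                f"record {record_id!r}: illegal character {ch!r} at position {pos}"
            )
    if not (MIN_SEQ_LEN <= len(s) <= MAX_SEQ_LEN):
        raise SequenceError(
            f"record {record_id!r}: sequence length {len(s)} outside "
            f"[{MIN_SEQ_LEN}, {MAX_SEQ_LEN}]"
        )
    return s


@dataclass(frozen=True)
class BarcodeRecord:
    record_id: str
    sequence: str
    species: str = ""
    genus: str = ""
    subfamily: str = ""
    family: str = ""
    regions: frozenset[str] = field(default_factory=frozenset)
    role: str = "reference"  # "reference" | "query"
    morphology_label: str = ""

    def __post_init__(self) -> None:
        if self.role not in ("reference", "query"):
            raise ValueError(f"record {self.record_id!r}: bad role {self.role!r}")
        if self.role == "query" and not self.morphology_label:
            raise ValueError(
                f"query record {self.record_id!r} lacks a morphology label"
            )
        object.__setattr__(
            self, "sequence", normalize_sequence(self.sequence, self.record_id)
        )

    @property
    def ungapped_length(self) -> int:
        """Number of non-gap characters (the sequence's true length)."""
        return len(self.sequence) - self.sequence.count("-")
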