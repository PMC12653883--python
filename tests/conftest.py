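from __future__ import annotations

import numpy as np
import pytest

from barcodeaudit import BarcodeRecord
from barcodeaudit.simulate import SimulationConfig, simulate

BASES = "ACGT"


def random_seq(rng: np.random.Generator, length: int = 658) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def make_record(record_id: str, sequence: str, *, species: str = "", genus: str = "",
                subfamily: str = "", family: str = "", role: str = "reference",
                morphology_label: str = "", regions=frozenset()) -> BarcodeRecord:
    if not genus and species:
        genus = species.split()[0]
    return BarcodeRecord(
        record_id=record_id, sequence=sequence, species=species, genus=genus,
        subfamily=subfamily or (genus + "-sub" if genus else ""),
        family=family or (genus + "-fam" if genus else ""),
        regions=frozenset(regions), role=role, morphology_label=morphology_label,
    )


def mutate_at(seq: str, positions: dict[int, str]) -> str:
    out = list(seq)
    for pos, base in positions.items():
        out[pos] = base
    return "".join(out)


@pytest.fixture(scope="session")
def clean_library():
    """A clean (corruption-free) simulated library at default settings."""
    return simulate(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def small_config():
    """A small taxonomy for fast end-to-end runs."""
    return SimulationConfig(
        seed=3, n_families=2, n_genera_per_family=2, n_species_per_genus=3,
        n_refs_per_species=4, n_queries_per_species=2,
    )
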