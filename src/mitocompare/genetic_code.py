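"""Genetic codes for codon-level statistics and models.

The default throughout the package is the vertebrate mitochondrial code
(NCBI translation table 2): 60 sense codons, four stops (TAA, TAG, AGA,
AGG), and TGA read as tryptophan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

from Bio.Data import CodonTable

NUCLEOTIDES = "TCAG"
ALL_CODONS = ["".join(c) for c in product(NUCLEOTIDES, repeat=3)]

VERTEBRATE_MITO_ID = 2


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino acid map plus start/stop codon sets."""

    table_id: int
    codon_to_aa: dict[str, str]
    stop_codons: frozenset[str]
    start_codons: frozenset[str]
    sense_codons: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        sense = tuple(c for c in ALL_CODONS if c not in self.stop_codons)
        object.__setattr__(self, "sense_codons", sense)

    @classmethod
    def from_ncbi_id(cls, table_id: int = VERTEBRATE_MITO_ID) -> "GeneticCode":
        tab = CodonTable.unambiguous_dna_by_id[table_id]
        return cls(
            table_id=table_id,
            codon_to_aa=dict(tab.forward_table),
            stop_codons=frozenset(tab.stop_codons),
            start_codons=frozenset(tab.start_codons),
        )

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons

    def aa(self, codon: str) -> str | None:
        """Amino acid for a sense codon, None for a stop."""
        return self.codon_to_aa.get(codon)

    def synonymous_family(self, codon: str) -> tuple[str, ...]:
        """All sense codons encoding the same amino acid as `codon`."""
        a = self.codon_to_aa[codon]
        return tuple(c for c in self.sense_codons if self.codon_to_aa[c] == a)

    @property
    def amino_acids(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.codon_to_aa.values())))


VERTEBRATE_MITO = GeneticCode.from_ncbi_id(VERTEBRATE_MITO_ID)
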