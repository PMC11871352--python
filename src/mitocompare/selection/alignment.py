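"""In-frame codon alignments (gap-aligned CDS blocks)."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ..genetic_code import VERTEBRATE_MITO, GeneticCode
from .gy94 import structure


@dataclass
class CodonAlignment:
    """Equal-length, frame-aligned nucleotide sequences.

    The alignment length must be a multiple of 3; gap characters are
    '-'.  Stop codons are not allowed inside the frame (strip terminal
    stops before constructing).
    """

    taxa: tuple[str, ...]
    sequences: tuple[str, ...]
    code: GeneticCode = field(default=VERTEBRATE_MITO)

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.sequences):
            raise ValueError("taxa / sequence count mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon names")
        lens = {len(s) for s in self.sequences}
        if len(lens) != 1:
            raise ValueError(f"unequal aligned lengths: {sorted(lens)}")
        (L,) = lens
        if L % 3:
            raise ValueError(f"aligned length {L} not a multiple of 3")
        self.sequences = tuple(
            s.upper().replace("U", "T") for s in self.sequences
        )

    @property
    def n_codons(self) -> int:
        return len(self.sequences[0]) // 3

    def sequence_of(self, taxon: str) -> str:
        return self.sequences[self.taxa.index(taxon)]

    @classmethod
    def from_fasta(
        cls, path: str | Path, code: GeneticCode = VERTEBRATE_MITO
    ) -> "CodonAlignment":
        recs = list(SeqIO.parse(str(path), "fasta"))
        if not recs:
            raise ValueError(f"{path}: empty FASTA")
        return cls(
            taxa=tuple(r.id for r in recs),
            sequences=tuple(str(r.seq) for r in recs),
            code=code,
        )

    def to_fasta(self, path: str | Path) -> None:
        SeqIO.write(
            [SeqRecord(Seq(s), id=t, description="")
             for t, s in zip(self.taxa, self.sequences)],
            str(path), "fasta",
        )

    def encode_complete_deletion(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Codon-state matrix after complete deletion of gapped columns.

        Returns ``(patterns, counts, column_pattern)``: distinct site
        patterns as an (n_taxa, n_patterns) int matrix of sense-codon
        indices, their multiplicities, and for every *retained* original
        codon column its pattern id (retained columns listed by a fourth
        array — see :meth:`kept_columns`).  Stop codons raise.
        """
        st = structure(self.code)
        cols = []
        kept = []
        for i in range(self.n_codons):
            states = []
            ok = True
            for taxon, s in zip(self.taxa, self.sequences):
                codon = s[3 * i: 3 * i + 3]
                if any(ch not in "ACGT" for ch in codon):
                    ok = False
                    break
                if self.code.is_stop(codon):
                    raise ValueError(
                        f"{taxon}: stop codon {codon} at codon column {i + 1}"
                    )
                states.append(st.index[codon])
            if ok:
                cols.append(states)
                kept.append(i)
        if not cols:
            raise ValueError("no ungapped codon columns to analyse")
        mat = np.asarray(cols, dtype=int)  # (n_kept, n_taxa)
        patterns, col_pattern, counts = np.unique(
            mat, axis=0, return_inverse=True, return_counts=True
        )
        self._kept_columns = np.asarray(kept, dtype=int)
        return patterns.T, counts, col_pattern

    def kept_columns(self) -> np.ndarray:
        """Original codon-column indices (0-based) retained by the last
        :meth:`encode_complete_deletion` call."""
        if not hasattr(self, "_kept_columns"):
            self.encode_complete_deletion()
        return self._kept_columns
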