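"""Codon counting, RSCU and codon-family composition statistics.

All operations default to the vertebrate mitochondrial code (NCBI table
2).  Stop codons — including the incomplete T--/TA- termini completed by
polyadenylation — are excluded from usage counts, so the pooled total
equals the number of amino acids encoded.

RSCU (relative synonymous codon usage) of codon *c* in a synonymous
family of size *k* with family total *n* is ``count(c) / (n / k)``: 1
means uniform use, >1 overrepresentation.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .genetic_code import VERTEBRATE_MITO, GeneticCode
from .mito_io import FeatureRow

#: Amino acids encoded by A+T-rich codon families vs G+C-rich families.
AT_RICH_AA = ("F", "I", "M", "Y", "N", "K")   # Phe Ile Met Tyr Asn Lys
GC_RICH_AA = ("P", "A", "R", "G")             # Pro Ala Arg Gly


class InternalStopError(ValueError):
    def __init__(self, position: int, codon: str):
        self.position = position
        self.codon = codon
        super().__init__(f"internal stop codon {codon} at nucleotide {position}")


def translate(cds: str, code: GeneticCode = VERTEBRATE_MITO) -> str:
    """Translate a coding sequence; incomplete terminal codons are dropped
    and a complete terminal stop is not translated."""
    if len(cds) < 3:
        raise ValueError("coding sequence shorter than one codon")
    s = cds.upper().replace("U", "T")
    ncod = len(s) // 3
    out = []
    for i in range(ncod):
        codon = s[3 * i: 3 * i + 3]
        if code.is_stop(codon):
            if i == ncod - 1:
                break
            raise InternalStopError(3 * i + 1, codon)
        aa = code.aa(codon)
        out.append(aa if aa is not None else "X")
    return "".join(out)


@dataclass
class CodonCountTable:
    code: GeneticCode
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_codons(self) -> int:
        return sum(self.counts.values())

    def aa_totals(self) -> dict[str, int]:
        tot: dict[str, int] = {}
        for codon, n in self.counts.items():
            aa = self.code.codon_to_aa[codon]
            tot[aa] = tot.get(aa, 0) + n
        return tot

    def top_codons(self) -> list[tuple[str, int]]:
        """All codons, most frequent first (leftmost-in-code tie-break)."""
        return sorted(
            self.counts.items(), key=lambda kv: (-kv[1], kv[0])
        )


def count_codons(
    cds_list: list[str], code: GeneticCode = VERTEBRATE_MITO
) -> CodonCountTable:
    """Pool codon counts over coding sequences.

    Terminal stop codons and incomplete (1–2 nt) termini are excluded;
    codons containing non-ACGT characters are skipped with a warning.
    """
    table = CodonCountTable(code=code, counts={c: 0 for c in code.sense_codons})
    for cds in cds_list:
        if len(cds) < 3:
            raise ValueError("coding sequence shorter than one codon")
        s = cds.upper().replace("U", "T")
        for i in range(len(s) // 3):
            codon = s[3 * i: 3 * i + 3]
            if any(ch not in "ACGT" for ch in codon):
                warnings.warn(f"skipping ambiguous codon {codon!r}", stacklevel=2)
                continue
            if code.is_stop(codon):
                continue  # stops are never usage-counted
            table.counts[codon] += 1
    return table


def rscu(table: CodonCountTable) -> dict[str, float | None]:
    """RSCU per sense codon; families with zero total get None."""
    out: dict[str, float | None] = {}
    code = table.code
    for codon in code.sense_codons:
        family = code.synonymous_family(codon)
        fam_total = sum(table.counts.get(c, 0) for c in family)
        if fam_total == 0:
            out[codon] = None
        else:
            out[codon] = table.counts.get(codon, 0) / (fam_total / len(family))
    return out


def at_gc_rich_ratio(table: CodonCountTable) -> float:
    """Total codons for the A+T-rich amino acids (Phe, Ile, Met, Tyr,
    Asn, Lys) over those for the G+C-rich ones (Pro, Ala, Arg, Gly)."""
    tot = table.aa_totals()
    num = sum(tot.get(a, 0) for a in AT_RICH_AA)
    den = sum(tot.get(a, 0) for a in GC_RICH_AA)
    if den == 0:
        raise ValueError("no codons in the G+C-rich families")
    return num / den


def amino_acid_total_from_rows(rows: list[FeatureRow]) -> int:
    """Number of encoded amino acids implied by PCG sizes and stop codons.

    Each PCG contributes floor(size/3) codons minus one when its
    annotated stop is complete (an incomplete T--/TA- stop occupies no
    whole codon).  This reproduces the pooled amino-acid count from a
    coordinate-only feature table.
    """
    total = 0
    for r in rows:
        if r.feature.element_class != "PCG":
            continue
        n = r.size // 3
        if r.stop_codon is not None and "-" not in r.stop_codon:
            n -= 1
        total += n
    return total


def write_codon_table(
    table: CodonCountTable, path: str | Path
) -> None:
    vals = rscu(table)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["codon", "amino_acid", "count", "rscu"])
        for codon in table.code.sense_codons:
            v = vals[codon]
            w.writerow([
                codon, table.code.codon_to_aa[codon],
                table.counts.get(codon, 0),
                "" if v is None else f"{v:.2f}",
            ])
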