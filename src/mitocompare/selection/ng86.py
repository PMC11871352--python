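"""Nei–Gojobori (1986) pairwise Ka/Ks by site and difference counting.

Each codon position contributes one site split between synonymous and
nonsynonymous in proportion to the fraction of its single-nucleotide
changes that are synonymous; changes into stop codons are excluded from
the denominators.  Observed differences between codons that differ at
several positions are averaged over all substitution orderings, again
excluding pathways that pass through a stop.  Proportions are corrected
for multiple hits with the Jukes–Cantor formula
d = −(3/4)·ln(1 − 4p/3).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations

from ..genetic_code import VERTEBRATE_MITO, GeneticCode

_BASES = "TCAG"
_SITE_CACHE: dict[tuple[int, str], float] = {}


def synonymous_sites(codon: str, code: GeneticCode = VERTEBRATE_MITO) -> float:
    """Synonymous site count of a sense codon (0..3); the nonsynonymous
    count is 3 minus this."""
    key = (code.table_id, codon)
    if key in _SITE_CACHE:
        return _SITE_CACHE[key]
    if code.is_stop(codon):
        raise ValueError(f"stop codon {codon} has no site decomposition")
    aa = code.codon_to_aa[codon]
    total = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if code.is_stop(mut):
                continue  # paths into stops are not counted as sites
            valid += 1
            if code.codon_to_aa[mut] == aa:
                syn += 1
        total += syn / valid if valid else 0.0
    _SITE_CACHE[key] = total
    return total


def _step_class(c_from: str, c_to: str, code: GeneticCode) -> int:
    """1 if the single-nucleotide step is synonymous, else 0."""
    return int(code.codon_to_aa[c_from] == code.codon_to_aa[c_to])


def codon_pair_differences(
    c1: str, c2: str, code: GeneticCode = VERTEBRATE_MITO
) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two sense codons,
    averaged over substitution orderings that avoid stop codons.

    If every ordering passes through a stop (possible for triple
    differences), all orderings are used with stop-crossing steps
    counted as nonsynonymous.
    """
    positions = [k for k in range(3) if c1[k] != c2[k]]
    if not positions:
        return 0.0, 0.0
    paths = []
    for order in permutations(positions):
        cur = c1
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if code.is_stop(nxt):
                blocked = True
                break
            if _step_class(cur, nxt, code):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if not blocked:
            paths.append((sd, nd))
    if not paths:  # fall back: count stop-crossing steps as nonsynonymous
        for order in permutations(positions):
            cur = c1
            sd = nd = 0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                if not code.is_stop(nxt) and not code.is_stop(cur) and \
                        _step_class(cur, nxt, code):
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            paths.append((sd, nd))
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def jukes_cantor(p: float) -> float | None:
    """JC69 distance; None when the proportion is at/beyond saturation."""
    if p < 0:
        raise ValueError("negative proportion")
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass
class PairwiseKaKs:
    """NG86 summary for one sequence pair."""

    S: float
    N: float
    Sd: float
    Nd: float
    ka: float | None
    ks: float | None
    omega: float | None
    codons: int  # codon pairs actually compared

    @property
    def ps(self) -> float | None:
        return self.Sd / self.S if self.S > 0 else None

    @property
    def pn(self) -> float | None:
        return self.Nd / self.N if self.N > 0 else None


def ng86_pairwise(
    cds1: str, cds2: str, code: GeneticCode = VERTEBRATE_MITO
) -> PairwiseKaKs:
    """NG86 Ka/Ks for a pair of aligned coding sequences.

    Codon pairs containing a gap or ambiguity in either sequence are
    dropped (pairwise deletion), as are terminal or stray stop codons.
    omega is None when Ks is 0 or either correction is undefined.
    """
    if len(cds1) != len(cds2):
        raise ValueError("aligned sequences must have equal length")
    if len(cds1) % 3:
        raise ValueError("aligned length must be a multiple of 3")
    s1 = cds1.upper().replace("U", "T")
    s2 = cds2.upper().replace("U", "T")
    S = N = Sd = Nd = 0.0
    used = 0
    for i in range(len(s1) // 3):
        a = s1[3 * i: 3 * i + 3]
        b = s2[3 * i: 3 * i + 3]
        if any(ch not in "ACGT" for ch in a + b):
            continue
        if code.is_stop(a) or code.is_stop(b):
            continue
        used += 1
        S += 0.5 * (synonymous_sites(a, code) + synonymous_sites(b, code))
        sd, nd = codon_pair_differences(a, b, code)
        Sd += sd
        Nd += nd
    N = 3.0 * used - S
    if used == 0:
        warnings.warn("no comparable codons after filtering", stacklevel=2)
        return PairwiseKaKs(0, 0, 0, 0, None, None, None, 0)
    ks = jukes_cantor(Sd / S) if S > 0 else None
    ka = jukes_cantor(Nd / N) if N > 0 else None
    omega = None
    if ka is not None and ks is not None and ks > 0:
        omega = ka / ks
    return PairwiseKaKs(S=S, N=N, Sd=Sd, Nd=Nd, ka=ka, ks=ks,
                        omega=omega, codons=used)


def kaks_profile(
    gene_alignments: dict,
    focal: str,
    others: list[str] | None = None,
    code: GeneticCode = VERTEBRATE_MITO,
):
    """Per-gene pairwise Ka/Ks of a focal taxon against comparison taxa.

    `gene_alignments` maps gene name -> CodonAlignment.  Returns a
    pandas DataFrame with one row per (gene, partner); partners missing
    from a gene's alignment are skipped with a warning.
    """
    import pandas as pd

    rows = []
    for gene, aln in gene_alignments.items():
        if focal not in aln.taxa:
            raise ValueError(f"{gene}: focal taxon {focal!r} absent")
        partners = others if others is not None else [
            t for t in aln.taxa if t != focal
        ]
        for other in partners:
            if other not in aln.taxa:
                warnings.warn(f"{gene}: taxon {other!r} absent, row skipped",
                              stacklevel=2)
                continue
            r = ng86_pairwise(
                aln.sequence_of(focal), aln.sequence_of(other), code
            )
            rows.append({
                "gene": gene, "focal": focal, "other": other,
                "S": r.S, "N": r.N, "Sd": r.Sd, "Nd": r.Nd,
                "Ka": r.ka, "Ks": r.ks, "omega": r.omega,
                "codons": r.codons,
            })
    return pd.DataFrame(rows)


def kaks_gene_summary(profile):
    """Mean Ka, Ks and omega per gene from a kaks_profile table."""
    return (
        profile.groupby("gene")[["Ka", "Ks", "omega"]]
        .mean()
        .reset_index()
    )
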