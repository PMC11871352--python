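"""Nucleotide composition and strand-asymmetry (skew) statistics.

AT skew = (A − T)/(A + T) and GC skew = (G − C)/(G + C), computed on the
strand as given; the complementary strand therefore has exactly negated
skews.  Ambiguity codes are excluded from every numerator and
denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .mito_io import MitogenomeRecord, feature_sequence, reverse_complement


@dataclass(frozen=True)
class CompositionStats:
    a: int
    c: int
    g: int
    t: int
    at_percent: float
    gc_percent: float
    at_skew: float | None
    gc_skew: float | None

    @property
    def total(self) -> int:
        return self.a + self.c + self.g + self.t


def base_composition(seq: str) -> CompositionStats:
    """Counts, AT/GC percentages and skews of a nucleotide string.

    Percentages are of unambiguous bases only; a skew whose denominator
    is zero is reported as None.
    """
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    a, c, g, t = s.count("A"), s.count("C"), s.count("G"), s.count("T")
    n = a + c + g + t
    if n == 0:
        raise ValueError("sequence contains no unambiguous A/C/G/T bases")
    return CompositionStats(
        a=a, c=c, g=g, t=t,
        at_percent=100.0 * (a + t) / n,
        gc_percent=100.0 * (g + c) / n,
        at_skew=(a - t) / (a + t) if a + t else None,
        gc_skew=(g - c) / (g + c) if g + c else None,
    )


def skew(seq: str) -> tuple[float | None, float | None]:
    """(AT skew, GC skew) of `seq` on the given strand."""
    st = base_composition(seq)
    return st.at_skew, st.gc_skew


def _row(label: str, kind: str, strand: str, seq: str) -> dict:
    st = base_composition(seq)
    return {
        "element": label, "kind": kind, "strand": strand,
        "length": st.total + sum(1 for ch in seq if ch.upper() not in "ACGT"),
        "A": st.a, "C": st.c, "G": st.g, "T": st.t,
        "at_percent": st.at_percent, "gc_percent": st.gc_percent,
        "at_skew": st.at_skew, "gc_skew": st.gc_skew,
    }


def composition_profile(record: MitogenomeRecord) -> pd.DataFrame:
    """Composition table per feature, per pooled element class, and full genome.

    Per-feature and pooled-class rows use each element's coding strand
    (matching the per-element AT% semantics of the summary table); the
    full genome is reported on both the reference strand and its
    complement, labelled with the annotation's L/H names.
    """
    if record.sequence is None:
        raise ValueError("record carries no sequence")
    rows = []
    pooled: dict[tuple[str, str], list[str]] = {}
    for feat in record.features:
        seq = feature_sequence(record, feat)
        rows.append(_row(feat.name, "element", feat.strand, seq))
        pooled.setdefault((feat.element_class, feat.strand), []).append(seq)
    for (cls, strand), seqs in sorted(pooled.items()):
        rows.append(_row(cls, "class", strand, "".join(seqs)))
    rows.append(_row("full", "full", "L", record.sequence))
    rows.append(_row("full", "full", "H", reverse_complement(record.sequence)))
    return pd.DataFrame(rows)


def round_percent(x: float | None, ndigits: int = 1) -> float | None:
    """Presentation rounding (half away from zero, as tables print)."""
    if x is None:
        return None
    q = 10 ** ndigits
    return math.floor(abs(x) * q + 0.5) / q * (1 if x >= 0 else -1)
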