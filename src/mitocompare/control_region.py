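"""Control-region (D-loop) structure: tandem repeats and conserved blocks.

The vertebrate control region carries, 5'→3' on the L-strand, a
termination-associated domain (ETAS), a central conserved domain
(CSB-F…CSB-B) and the conserved sequence blocks CSB-1/2/3 near the
origin of H-strand replication; length variation between individuals
and species is dominated by tandem-repeat copy number.

The repeat finder here is a transparent lag-correlation detector: exact
self-matches at lag *p* seed candidate arrays, nearby seeds of the same
period are bridged across substitutions or single-base indels when the
array still aligns to its tiled consensus at the identity floor, and
maximal non-nested arrays are reported longest first.  It does not
reproduce any particular published scoring scheme.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import edlib

from .mito_io import GeneFeature, MitogenomeRecord, feature_sequence

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: Domain order used when reporting block hits 5'→3' on the L-strand.
BLOCK_ORDER = (
    "ETAS1", "CSB-F", "CSB-E", "CSB-D", "CSB-C", "CSB-B",
    "CSB-1", "CSB-2", "CSB-3",
)


@dataclass
class TandemRepeat:
    """A tandem-repeat array. Coordinates are 1-based inclusive within
    the scanned sequence's own frame."""

    start: int
    end: int
    period: int
    copies: float
    consensus: str
    identity: float

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass
class MotifHit:
    name: str
    start: int
    end: int
    mismatches: int
    matched: str


def _match_runs(seq: str, p: int) -> list[tuple[int, int]]:
    """Maximal runs [i, j) with seq[i+k] == seq[i+k+p] for all k < j-i."""
    n = len(seq)
    runs = []
    i = 0
    limit = n - p
    while i < limit:
        if seq[i] == seq[i + p]:
            j = i
            while j < limit and seq[j] == seq[j + p]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs


def _phase_consensus(seq: str, start: int, end: int, p: int) -> str:
    """Majority base per phase over the array span [start, end)."""
    cons = []
    for phase in range(p):
        counts: dict[str, int] = {}
        for i in range(start + phase, end, p):
            counts[seq[i]] = counts.get(seq[i], 0) + 1
        cons.append(max(sorted(counts), key=lambda b: counts[b]))
    return "".join(cons)


def _array_identity(seq: str, start: int, end: int, consensus: str) -> float:
    """% identity of the span against its tiled consensus (edit distance,
    so a single-base indel costs one position, not a frameshift)."""
    p = len(consensus)
    span = seq[start:end]
    ncopies = max(1, round(len(span) / p))
    tile = (consensus * (ncopies + 2))[: len(span)]
    d = edlib.align(span, tile, mode="NW")["editDistance"]
    return 100.0 * (1.0 - d / len(span))


_MATCH_BONUS, _EDIT_PENALTY = 2.0, 7.0


def _array_score(seq: str, start: int, end: int, p: int) -> float:
    """Alignment-style array score: rewards matched length, penalizes
    edits against the tiled consensus (used only to decide merges)."""
    cons = _phase_consensus(seq, start, end, p)
    span = seq[start:end]
    ncopies = max(1, round(len(span) / p))
    tile = (cons * (ncopies + 2))[: len(span)]
    d = edlib.align(span, tile, mode="NW")["editDistance"]
    return _MATCH_BONUS * (len(span) - d) - _EDIT_PENALTY * d


def _extend_boundaries(
    seq: str, s: int, e: int, p: int, min_identity: float
) -> tuple[int, int]:
    """Grow an array over whole (or indel-shortened) boundary copies and
    residual partial matches, accepting a step only when it raises the
    array score and keeps identity above the floor."""
    n = len(seq)
    steps = (1, 2, 3, p - 1, p, p + 1)
    improved = True
    while improved:
        improved = False
        base = _array_score(seq, s, e, p)
        for k in steps:
            if k < 1 or s - k < 0:
                continue
            if (
                _array_score(seq, s - k, e, p) > base
                and _array_identity(
                    seq, s - k, e, _phase_consensus(seq, s - k, e, p)
                ) >= min_identity
            ):
                s -= k
                improved = True
                break
        base = _array_score(seq, s, e, p)
        for k in steps:
            if k < 1 or e + k > n:
                continue
            if (
                _array_score(seq, s, e + k, p) > base
                and _array_identity(
                    seq, s, e + k, _phase_consensus(seq, s, e + k, p)
                ) >= min_identity
            ):
                e += k
                improved = True
                break
    return s, e


def find_tandem_repeats(
    seq: str,
    min_period: int = 2,
    max_period: int = 60,
    min_copies: float = 2.0,
    min_identity: float = 80.0,
) -> list[TandemRepeat]:
    """Detect tandem-repeat arrays of period `min_period`..`max_period`.

    Returns maximal non-nested arrays (longest span first).  Arrays whose
    period is a multiple of a detected shorter period over the same span
    (harmonics) are suppressed; genuinely overlapping arrays of different
    periods are both reported.  Copy number is span/period to 1 decimal.
    """
    if min_period < 1:
        raise ValueError("min_period must be >= 1")
    if min_period > max_period:
        raise ValueError("min_period > max_period")
    seq = seq.upper()
    n = len(seq)
    candidates: list[TandemRepeat] = []
    for p in range(min_period, min(max_period, n // 2) + 1):
        runs = _match_runs(seq, p)
        # candidate spans (i, j+p); keep seeds with at least 2 aligned
        # positions to bound the bridging loop
        spans = [[i, j + p] for i, j in runs if j - i >= max(2, p // 2)]
        merged: list[list[int]] = []
        for s, e in spans:
            if merged and s - merged[-1][1] <= p + 1:
                ms, me = merged[-1][0], max(merged[-1][1], e)
                cons = _phase_consensus(seq, ms, me, p)
                # a merge must both clear the identity floor and beat the
                # better of its parts on score, so boundary junk cannot
                # ride along on a long array's high global identity
                if (
                    _array_identity(seq, ms, me, cons) >= min_identity
                    and _array_score(seq, ms, me, p)
                    > max(_array_score(seq, *merged[-1], p),
                          _array_score(seq, s, e, p))
                ):
                    merged[-1][1] = me
                    continue
            merged.append([s, e])
        for s, e in merged:
            copies = (e - s) / p
            if copies + 1e-9 < min_copies:
                continue
            s, e = _extend_boundaries(seq, s, e, p, min_identity)
            copies = (e - s) / p
            cons = _phase_consensus(seq, s, e, p)
            ident = _array_identity(seq, s, e, cons)
            if ident < min_identity:
                continue
            candidates.append(
                TandemRepeat(
                    start=s + 1, end=e, period=p,
                    copies=round(copies, 1), consensus=cons,
                    identity=ident,
                )
            )

    kept: list[TandemRepeat] = []
    for tr in sorted(candidates, key=lambda t: (-t.span, t.period, t.start)):
        nested = any(
            k.start <= tr.start and tr.end <= k.end for k in kept
        )
        if not nested:
            kept.append(tr)
    return kept


def load_block_library() -> dict[str, tuple[str, int]]:
    """The shipped (editable) vertebrate consensus-block library:
    name -> (IUPAC consensus, default max mismatches)."""
    ref = resources.files("mitocompare.data") / "conserved_blocks.json"
    payload = json.loads(ref.read_text())
    return {
        b["name"]: (b["consensus"], int(b["max_mismatch"]))
        for b in payload["blocks"]
    }


def _iupac_mismatches(window: str, consensus: str) -> int:
    m = 0
    for ch, pat in zip(window, consensus):
        allowed = IUPAC[pat]
        if ch not in allowed:
            m += 1
    return m


def scan_conserved_blocks(
    seq: str,
    library: dict[str, tuple[str, int]] | None = None,
    max_mismatch: dict[str, int] | None = None,
) -> list[MotifHit]:
    """Best hit per conserved block (fewest mismatches, leftmost ties).

    `library` maps block name -> (IUPAC consensus, default allowance);
    `max_mismatch` overrides the allowance per block.  Blocks without a
    hit within their allowance are simply absent from the result.  Hits
    are returned in sequence order.
    """
    if library is None:
        library = load_block_library()
    if not library:
        raise ValueError("empty block library")
    seq = seq.upper()
    hits: list[MotifHit] = []
    for name, (consensus, allow) in library.items():
        consensus = consensus.upper()
        bad = set(consensus) - set(IUPAC)
        if bad:
            raise ValueError(f"{name}: invalid IUPAC characters {sorted(bad)}")
        if max_mismatch is not None and name in max_mismatch:
            allow = max_mismatch[name]
        L = len(consensus)
        best: tuple[int, int] | None = None  # (mismatches, start0)
        for i in range(len(seq) - L + 1):
            m = _iupac_mismatches(seq[i: i + L], consensus)
            if best is None or m < best[0]:
                best = (m, i)
                if m == 0:
                    break
        if best is not None and best[0] <= allow:
            m, i = best
            hits.append(
                MotifHit(
                    name=name, start=i + 1, end=i + L, mismatches=m,
                    matched=seq[i: i + L],
                )
            )
    return sorted(hits, key=lambda h: h.start)


def _to_genome_frame(cr: GeneFeature, local_start: int, local_end: int) -> tuple[int, int]:
    """Map 1-based coordinates within the CR coding-strand sequence to
    genome (reference-strand) coordinates."""
    if cr.strand == "L":
        return cr.start + local_start - 1, cr.start + local_end - 1
    return cr.end - local_end + 1, cr.end - local_start + 1


def annotate_control_region(
    record: MitogenomeRecord,
    min_period: int = 2,
    max_period: int = 60,
    min_copies: float = 2.0,
    min_identity: float = 80.0,
    library: dict[str, tuple[str, int]] | None = None,
) -> dict:
    """Combined repeat/block report for the record's control region.

    Repeat arrays and block hits are reported both in CR-local and in
    genome-frame coordinates, with blocks ordered ETAS → central domain →
    CSB-1/2/3 as laid out on the L-strand.
    """
    crs = record.features_of_class("CR")
    if not crs:
        raise ValueError(f"{record.accession}: no control-region feature")
    cr = crs[0]
    seq = feature_sequence(record, cr)
    arrays = find_tandem_repeats(
        seq, min_period=min_period, max_period=max_period,
        min_copies=min_copies, min_identity=min_identity,
    )
    hits = scan_conserved_blocks(seq, library=library)
    hits.sort(key=lambda h: (BLOCK_ORDER.index(h.name) if h.name in BLOCK_ORDER else 99))
    lib = library if library is not None else load_block_library()
    found = {h.name for h in hits}
    report = {
        "accession": record.accession,
        "control_region": {
            "start": cr.start, "end": cr.end, "strand": cr.strand,
            "length": cr.size(record.length),
        },
        "tandem_repeats": [],
        "conserved_blocks": [],
        "absent_blocks": [b for b in lib if b not in found],
    }
    for tr in arrays:
        gs, ge = _to_genome_frame(cr, tr.start, tr.end)
        report["tandem_repeats"].append(
            {
                "genome_start": gs, "genome_end": ge,
                "cr_start": tr.start, "cr_end": tr.end,
                "period": tr.period, "copies": tr.copies,
                "consensus": tr.consensus,
                "identity": round(tr.identity, 1),
            }
        )
    for h in hits:
        gs, ge = _to_genome_frame(cr, h.start, h.end)
        report["conserved_blocks"].append(
            {
                "name": h.name, "genome_start": gs, "genome_end": ge,
                "cr_start": h.start, "cr_end": h.end,
                "mismatches": h.mismatches, "matched": h.matched,
            }
        )
    return report


def write_bed(report: dict, path: str | Path) -> None:
    """Arrays and blocks as BED (0-based half-open genome coordinates)."""
    lines = []
    for tr in report["tandem_repeats"]:
        lines.append(
            f"{report['accession']}\t{tr['genome_start'] - 1}\t{tr['genome_end']}"
            f"\tTR_p{tr['period']}x{tr['copies']}"
        )
    for b in report["conserved_blocks"]:
        lines.append(
            f"{report['accession']}\t{b['genome_start'] - 1}\t{b['genome_end']}"
            f"\t{b['name']}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
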