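"""Tandem-repeat detection and conserved-block scanning."""

import numpy as np
import pytest

from mitocompare.control_region import (
    annotate_control_region,
    find_tandem_repeats,
    load_block_library,
    scan_conserved_blocks,
)
from mitocompare.mito_io import GeneFeature, MitogenomeRecord
from tests.conftest import random_dna


def brute_force_perfect_arrays(seq, min_period, max_period, min_copies):
    """Exhaustive (period, phase, span) search for maximal perfect
    arrays, with the same containment filtering as the detector."""
    n = len(seq)
    found = []
    for p in range(min_period, min(max_period, n // 2) + 1):
        i = 0
        while i + 2 * p <= n:
            # extend the perfect tiling seeded at i as far as possible
            j = i
            while j + p < n and seq[j + p] == seq[j]:
                j += 1
            span = j + p - i
            if span >= p * min_copies and span >= 2 * p:
                found.append((i + 1, i + span, p))
                i = i + 1
            else:
                i += 1
    # maximality within a period, then cross-period containment
    by_period = {}
    for s, e, p in found:
        keep = True
        for s2, e2, p2 in found:
            if p2 == p and (s2, e2) != (s, e) and s2 <= s and e <= e2:
                keep = False
                break
        if keep:
            by_period.setdefault(p, []).append((s, e))
    flat = [(s, e, p) for p, spans in by_period.items()
            for s, e in set(spans)]
    kept = []
    for s, e, p in sorted(flat, key=lambda t: (-(t[1] - t[0]), t[2], t[0])):
        if not any(s2 <= s and e <= e2 for s2, e2, _ in kept):
            kept.append((s, e, p))
    return sorted(kept)


class TestTandemRepeats:
    def test_perfect_triplet_array(self):
        (tr,) = find_tandem_repeats("ACGACGACG")
        assert (tr.period, tr.copies, tr.identity) == (3, 3.0, 100.0)
        assert tr.consensus == "ACG"

    def test_tiled_motif_in_random_flanks(self, rng):
        flank1, flank2 = random_dna(rng, 200), random_dna(rng, 200)
        array = ("ATATT" * 34)[:165]
        seq = flank1 + "G" + array + "G" + flank2
        hits = [t for t in find_tandem_repeats(seq)
                if t.period == 5 and t.start <= 202 <= t.end]
        best = max(hits, key=lambda t: t.span)
        assert best.copies == 33.0
        assert (best.start, best.end) == (202, 366)

    def test_period_times_copies_equals_span_on_perfect_arrays(self):
        for motif, n in (("ACGT", 6), ("TTAGGG", 4), ("AT", 8)):
            seq = motif * n
            hits = [t for t in find_tandem_repeats(seq)
                    if t.period == len(motif)]
            best = max(hits, key=lambda t: t.span)
            assert best.span == best.period * best.copies
            assert best.identity == 100.0

    def test_shift_equivariance(self, rng):
        core = "C" + ("ATATT" * 10) + "G"
        prefix = random_dna(rng, 37)
        base = [t for t in find_tandem_repeats(core) if t.period == 5]
        shifted = [t for t in find_tandem_repeats(prefix + core)
                   if t.period == 5 and t.start > 30]
        assert base and shifted
        b, s = max(base, key=lambda t: t.span), max(shifted, key=lambda t: t.span)
        assert (s.start, s.end) == (b.start + 37, b.end + 37)

    def test_matches_brute_force_on_perfect_arrays(self, rng):
        # periods <= 20 on short sequences, identity floor 100
        for trial in range(10):
            seq = random_dna(rng, 120)
            # plant one clean array to make the comparison non-vacuous
            motif = random_dna(rng, int(rng.integers(2, 8)))
            arr = motif * int(rng.integers(3, 6))
            pos = int(rng.integers(0, 120 - len(arr)))
            seq = seq[:pos] + arr + seq[pos + len(arr):]
            got = {
                (t.start, t.end, t.period)
                for t in find_tandem_repeats(
                    seq, min_period=2, max_period=20, min_copies=2,
                    min_identity=100.0,
                )
            }
            expect = set(brute_force_perfect_arrays(seq, 2, 20, 2))
            assert got == expect, f"trial {trial}"

    def test_absence_on_repeat_free_sequence(self, rng):
        # find a seeded 200 bp sequence the oracle certifies repeat-free
        # at (copies >= 3, identity 100), then the detector at 90% floor
        # must stay empty too
        for _ in range(50):
            seq = random_dna(rng, 200)
            if brute_force_perfect_arrays(seq, 2, 60, 3):
                continue
            hits = find_tandem_repeats(
                seq, min_period=2, max_period=60, min_copies=3,
                min_identity=90.0,
            )
            perfect = [t for t in hits if t.identity == 100.0]
            assert perfect == []
            return
        pytest.skip("no repeat-free draw found")

    def test_recall_is_one_on_perfect_plants(self, rng):
        # every planted clean array of >= min_copies must be recovered
        recovered = 0
        total = 100
        for i in range(total):
            motif = random_dna(rng, int(rng.integers(3, 12)))
            copies = int(rng.integers(3, 8))
            arr = motif * copies
            cr = random_dna(rng, 120) + "G" + arr + "G" + random_dna(rng, 120)
            start = 122
            hits = [
                t for t in find_tandem_repeats(cr)
                if t.start <= start <= t.end
                and t.end - t.start + 1 >= len(arr) - t.period
            ]
            if hits:
                recovered += 1
        assert recovered == total


class TestConservedBlocks:
    def test_iupac_degeneracy_matches(self):
        lib = {"ETAS1": ("GYRCAT", 0)}
        (hit,) = scan_conserved_blocks("TTGCACATTT", library=lib)
        assert (hit.start, hit.end, hit.mismatches) == (3, 8, 0)
        assert hit.matched == "GCACAT"

    def test_iupac_non_match_counts_mismatch(self):
        lib = {"ETAS1": ("GYRCAT", 0)}
        assert scan_conserved_blocks("TTGAACATTT", library=lib) == []

    def test_invalid_iupac_character_rejected(self):
        with pytest.raises(ValueError, match="IUPAC"):
            scan_conserved_blocks("ACGT", library={"X": ("AZ", 0)})

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            scan_conserved_blocks("ACGT", library={})

    def test_planted_blocks_found_at_planted_offsets(self, synthetic_genome):
        record, truth, _ = synthetic_genome
        report = annotate_control_region(record)
        planted = {t["name"]: t for t in record_blocks(truth)}
        hits = {b["name"]: b for b in report["conserved_blocks"]}
        for name in ("ETAS1", "CSB-1", "CSB-2", "CSB-3"):
            assert name in hits
            assert hits[name]["genome_start"] == planted[name]["genome_start"]
            assert hits[name]["mismatches"] == 0

    def test_blocks_ordered_five_prime_to_three_prime(self, synthetic_genome):
        record, _, _ = synthetic_genome
        report = annotate_control_region(record)
        names = [b["name"] for b in report["conserved_blocks"]]
        order = ["ETAS1", "CSB-F", "CSB-E", "CSB-D", "CSB-C", "CSB-B",
                 "CSB-1", "CSB-2", "CSB-3"]
        assert names == sorted(names, key=order.index)


def record_blocks(truth):
    return [t for t in truth["control_region"] if t["kind"] == "block"]


class TestAnnotateControlRegion:
    def test_planted_repeats_have_genome_frame_coordinates(self, synthetic_genome):
        record, truth, _ = synthetic_genome
        report = annotate_control_region(record)
        planted = [t for t in truth["control_region"] if t["kind"] == "repeat"]
        assert len(planted) == 2
        for p in planted:
            match = [
                t for t in report["tandem_repeats"]
                if t["period"] == p["period"]
                and t["genome_start"] <= p["genome_start"]
                + p["period"] and t["genome_end"] >= p["genome_end"] - p["period"]
            ]
            assert match, f"planted array {p} not recovered"

    def test_record_without_cr_errors(self):
        rec = MitogenomeRecord(
            accession="X", length=9, sequence="ATGCATGCA",
            features=[GeneFeature("tRNA-Phe", "tRNA", "L", 1, 9)],
        )
        with pytest.raises(ValueError, match="control-region"):
            annotate_control_region(rec)

    def test_shipped_library_loads(self):
        lib = load_block_library()
        assert set(lib) >= {"ETAS1", "CSB-1", "CSB-2", "CSB-3"}
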