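"""NG86 Ka/Ks: hand examples, brute-force oracle equivalence, simulation."""

import math
from itertools import permutations

import numpy as np
import pytest

from mitocompare.genetic_code import VERTEBRATE_MITO
from mitocompare.selection import (
    CodonAlignment,
    kaks_gene_summary,
    kaks_profile,
    ng86_pairwise,
)
from mitocompare.synthetic_data import SimAlignmentSpec, simulate_codon_alignment


# -- independent oracle: literal transcription of the counting recipe -------

def oracle_sites(codon, code):
    aa = code.codon_to_aa[codon]
    s = 0.0
    for pos in range(3):
        alts = [codon[:pos] + b + codon[pos + 1:]
                for b in "ACGT" if b != codon[pos]]
        alts = [c for c in alts if c not in code.stop_codons]
        if alts:
            s += sum(code.codon_to_aa[c] == aa for c in alts) / len(alts)
    return s


def oracle_differences(c1, c2, code):
    pos = [k for k in range(3) if c1[k] != c2[k]]
    if not pos:
        return 0.0, 0.0
    results = []
    for order in permutations(pos):
        cur, sd, nd, ok = c1, 0, 0, True
        for k in order:
            nxt = cur[:k] + c2[k] + cur[k + 1:]
            if nxt in code.stop_codons:
                ok = False
                break
            if code.codon_to_aa[cur] == code.codon_to_aa[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            results.append((sd, nd))
    if not results:
        return None
    return (sum(r[0] for r in results) / len(results),
            sum(r[1] for r in results) / len(results))


def oracle_pairwise(s1, s2, code):
    S = Sd = Nd = 0.0
    used = 0
    for i in range(len(s1) // 3):
        a, b = s1[3 * i: 3 * i + 3], s2[3 * i: 3 * i + 3]
        if a in code.stop_codons or b in code.stop_codons:
            continue
        d = oracle_differences(a, b, code)
        if d is None:
            continue  # oracle skips fully blocked pairs, main code falls back
        used += 1
        S += (oracle_sites(a, code) + oracle_sites(b, code)) / 2
        Sd += d[0]
        Nd += d[1]
    return S, 3 * used - S, Sd, Nd


def test_identical_sequences_have_zero_rates():
    r = ng86_pairwise("ATGGCT", "ATGGCT")
    assert r.ka == 0.0 and r.ks == 0.0 and r.omega is None


def test_hand_counted_synonymous_example():
    # GGA->GGG is synonymous; GGA/GGG each have one fully synonymous
    # third position, so S=2 over the pair and pS=1/2
    r = ng86_pairwise("GGAGGA", "GGGGGA")
    assert r.S == pytest.approx(2.0)
    assert (r.Sd, r.Nd) == (1.0, 0.0)
    assert r.ks == pytest.approx(-0.75 * math.log(1 - 4 / 3 * 0.5), abs=1e-4)
    assert r.ka == pytest.approx(0.0)


def test_sites_sum_to_three_per_codon():
    code = VERTEBRATE_MITO
    for codon in code.sense_codons:
        s = oracle_sites(codon, code)
        assert 0.0 <= s <= 3.0


def test_unequal_lengths_rejected():
    with pytest.raises(ValueError):
        ng86_pairwise("ATGGCT", "ATG")


def test_matches_brute_force_on_random_codon_pairs(rng):
    code = VERTEBRATE_MITO
    sense = list(code.sense_codons)
    pairs = [
        (sense[i], sense[j])
        for i, j in zip(
            rng.integers(0, 60, size=1000), rng.integers(0, 60, size=1000)
        )
    ]
    # skip pairs where every substitution path crosses a stop: the oracle
    # drops them, the implementation applies its documented fallback
    pairs = [
        (a, b) for a, b in pairs if oracle_differences(a, b, code) is not None
    ]
    s1 = "".join(a for a, _ in pairs)
    s2 = "".join(b for _, b in pairs)
    S, N, Sd, Nd = oracle_pairwise(s1, s2, code)
    r = ng86_pairwise(s1, s2, code)
    assert r.S == pytest.approx(S)
    assert r.N == pytest.approx(N)
    assert r.Sd == pytest.approx(Sd)
    assert r.Nd == pytest.approx(Nd)


def test_gapped_codons_dropped_pairwise():
    r = ng86_pairwise("ATG---GCT", "ATGAAAGCA")
    assert r.codons == 2


UNIFORM = {"T": 0.25, "C": 0.25, "A": 0.25, "G": 0.25}


def test_neutral_simulation_recovers_omega_one():
    # two taxa, omega = 1, inside the estimator's model (no transition
    # bias, near-uniform frequencies, moderate divergence): the mean
    # estimate centers on 1
    estimates = []
    for seed in range(200):
        aln, _ = simulate_codon_alignment(SimAlignmentSpec(
            newick="(A:0.2,B:0.2);", n_codons=300, kappa=1.0, omega=1.0,
            seed=seed, nt_freqs=UNIFORM,
        ))
        r = ng86_pairwise(*aln.sequences)
        if r.omega is not None:
            estimates.append(r.omega)
    mean = float(np.mean(estimates))
    se = float(np.std(estimates, ddof=1) / np.sqrt(len(estimates)))
    assert abs(mean - 1.0) < 3 * se + 0.02


def test_long_neutral_pair_within_three_se():
    aln, _ = simulate_codon_alignment(SimAlignmentSpec(
        newick="(A:0.6,B:0.6);", n_codons=10000, kappa=1.0, omega=1.0,
        seed=77, nt_freqs=UNIFORM,
    ))
    r = ng86_pairwise(*aln.sequences)
    # binomial-style SE on each proportion propagates to ~0.05 here
    assert r.omega == pytest.approx(1.0, abs=0.15)


@pytest.fixture(scope="module")
def gene_alignments():
    genes = {}
    for i in range(13):
        aln, _ = simulate_codon_alignment(SimAlignmentSpec(
            newick="(F:0.15,(X:0.1,Y:0.1):0.05,Z:0.2);",
            n_codons=60, kappa=2.0, omega=0.1, seed=500 + i,
        ))
        genes[f"g{i:02d}"] = aln
    return genes


class TestProfile:
    def test_cardinality_thirteen_genes_three_partners(self, gene_alignments):
        prof = kaks_profile(gene_alignments, focal="F")
        assert len(prof) == 39
        assert set(prof["gene"]) == set(gene_alignments)

    def test_missing_partner_skipped_with_warning(self, gene_alignments):
        with pytest.warns(UserWarning, match="absent"):
            prof = kaks_profile(gene_alignments, focal="F",
                                others=["X", "NOSUCH"])
        assert len(prof) == 13

    def test_omega_ordering_recovered(self):
        def sim(omega, seed):
            aln, _ = simulate_codon_alignment(SimAlignmentSpec(
                newick="(F:0.3,O:0.3);", n_codons=400, kappa=2.0,
                omega=omega, seed=seed,
            ))
            return aln

        low = kaks_profile({"lo": sim(0.05, 1)}, focal="F")
        high = kaks_profile({"hi": sim(0.5, 2)}, focal="F")
        assert low["omega"].iloc[0] < high["omega"].iloc[0]

    def test_purifying_simulations_stay_below_one(self):
        below = 0
        total = 40
        for seed in range(total):
            aln, _ = simulate_codon_alignment(SimAlignmentSpec(
                newick="(F:0.25,O:0.25);", n_codons=300, kappa=2.0,
                omega=0.1, seed=900 + seed,
            ))
            r = ng86_pairwise(*aln.sequences)
            below += (r.omega is not None and r.omega < 1.0)
        assert below >= 0.95 * total

    def test_gene_summary_means(self, gene_alignments):
        prof = kaks_profile(gene_alignments, focal="F")
        summ = kaks_gene_summary(prof)
        assert len(summ) == 13
        g = summ.iloc[0]["gene"]
        sub = prof[prof["gene"] == g]
        assert summ.iloc[0]["Ka"] == pytest.approx(sub["Ka"].mean())
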