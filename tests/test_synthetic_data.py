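"""The synthetic-data generators: determinism, targets, bookkeeping."""

import numpy as np
import pytest

from mitocompare.codon_usage import count_codons, translate
from mitocompare.composition import base_composition
from mitocompare.mito_io import build_feature_table, feature_sequence
from mitocompare.selection import ng86_pairwise
from mitocompare.synthetic_data import (
    GenomeSpec,
    SimAlignmentSpec,
    default_control_region,
    default_gene_order,
    default_genome_spec,
    generate_mitogenome,
    perturb_annotation,
    simulate_codon_alignment,
    strand_probabilities,
)


class TestGenomeGenerator:
    def test_same_seed_same_bytes(self, tmp_path):
        p1, p2 = tmp_path / "a.gb", tmp_path / "b.gb"
        generate_mitogenome(default_genome_spec(3), p1)
        generate_mitogenome(default_genome_spec(3), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seed_different_sequence(self):
        r1, _ = generate_mitogenome(default_genome_spec(1))
        r2, _ = generate_mitogenome(default_genome_spec(2))
        assert r1.sequence != r2.sequence

    def test_composition_targets_met_at_genome_scale(self, synthetic_genome):
        record, truth, _ = synthetic_genome
        st = base_composition(record.sequence)
        t = truth["targets"]
        assert st.at_percent == pytest.approx(100 * t["at"], abs=1.0)
        assert st.at_skew == pytest.approx(t["at_skew"], abs=0.02)
        assert st.gc_skew == pytest.approx(t["gc_skew"], abs=0.04)

    def test_composition_converges_with_length(self):
        # doubling every element halves the sampling error on average
        def at_error(scale, seed):
            spec = default_genome_spec(seed)
            for g in spec.gene_order:
                g.length *= scale
                if g.element_class == "PCG":
                    g.length -= g.length % 3  # keep stop parity
                    if "-" in g.stop_codon:
                        g.length += 1 if g.stop_codon == "T--" else 2
            rec, _ = generate_mitogenome(spec)
            return abs(base_composition(rec.sequence).at_percent
                       - 100 * spec.target_at)

        errs_small = np.mean([at_error(1, s) for s in range(4)])
        errs_large = np.mean([at_error(3, s) for s in range(4)])
        assert errs_large <= errs_small + 0.3

    def test_infeasible_targets_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            strand_probabilities(1.2, 0.0, 0.0)
        # |skew| beyond 1 drives a probability negative
        with pytest.raises(ValueError):
            strand_probabilities(0.5, 1.5, 0.0)

    def test_stop_codon_bookkeeping_matches_translation(self, synthetic_genome):
        record, _, _ = synthetic_genome
        rows = build_feature_table(record)
        implied = 0
        translated = 0
        for r in rows:
            if r.feature.element_class != "PCG":
                continue
            seq = feature_sequence(record, r.feature)
            translated += len(translate(seq))
            implied += r.size // 3 - (1 if "-" not in r.stop_codon else 0)
        assert implied == translated

    def test_pooled_codon_total_matches_size_arithmetic(self, synthetic_genome):
        record, _, _ = synthetic_genome
        rows = [r for r in build_feature_table(record)
                if r.feature.element_class == "PCG"]
        table = count_codons(
            [feature_sequence(record, r.feature) for r in rows]
        )
        expect = sum(
            r.size // 3 - (1 if "-" not in r.stop_codon else 0) for r in rows
        )
        assert table.total_codons == expect

    def test_planted_microsatellite_recovered(self, synthetic_genome):
        from mitocompare.control_region import annotate_control_region

        record, truth, _ = synthetic_genome
        planted = [t for t in truth["control_region"]
                   if t["kind"] == "repeat" and t["period"] == 5][0]
        report = annotate_control_region(record)
        hits = [t for t in report["tandem_repeats"] if t["period"] == 5
                and t["genome_start"] <= planted["genome_start"]
                <= t["genome_end"]]
        assert hits
        assert max(t["copies"] for t in hits) >= planted["copies"]


class TestAlignmentSimulator:
    def test_omega_zero_preserves_the_protein(self):
        # with no nonsynonymous rate the two proteins stay identical
        # even though the nucleotide sequences diverge
        aln, _ = simulate_codon_alignment(SimAlignmentSpec(
            newick="(A:0.5,B:0.5);", n_codons=400, kappa=2.0, omega=0.0,
            seed=13,
        ))
        s1, s2 = aln.sequences
        assert s1 != s2
        assert translate(s1) == translate(s2)
        r = ng86_pairwise(s1, s2)
        assert r.Sd > 0

    def test_zero_branches_give_identical_sequences(self):
        aln, _ = simulate_codon_alignment(SimAlignmentSpec(
            newick="(A:0.0,B:0.0,C:0.0);", n_codons=100, kappa=2.0,
            omega=0.5, seed=2,
        ))
        assert len(set(aln.sequences)) == 1

    def test_deterministic_in_seed(self):
        spec = SimAlignmentSpec(newick="(A:0.2,B:0.2);", n_codons=50,
                                kappa=2.0, omega=0.3, seed=9)
        a1, _ = simulate_codon_alignment(spec)
        a2, _ = simulate_codon_alignment(spec)
        assert a1.sequences == a2.sequences

    def test_mixture_truth_records_site_classes(self):
        aln, truth = simulate_codon_alignment(SimAlignmentSpec(
            newick="(A:0.2,B:0.2);", n_codons=200, kappa=2.0,
            omega=[(0.5, 0.1), (0.5, 1.0)], seed=4,
        ))
        w = np.array(truth["site_omega"])
        assert set(np.unique(w)) == {0.1, 1.0}
        assert 40 <= (w == 0.1).sum() <= 160  # both classes realized

    def test_degenerate_specs_rejected(self):
        with pytest.raises(ValueError):
            simulate_codon_alignment(SimAlignmentSpec(
                newick="(A:0.1,B:0.1);", n_codons=0, kappa=2.0, omega=0.2,
                seed=1,
            ))
        with pytest.raises(ValueError, match="weights"):
            simulate_codon_alignment(SimAlignmentSpec(
                newick="(A:0.1,B:0.1);", n_codons=10, kappa=2.0,
                omega=[(0.5, 0.1), (0.2, 1.0)], seed=1,
            ))


class TestPerturbations:
    def test_no_defects_is_identity(self, synthetic_genome, tmp_path):
        record, _, path = synthetic_genome
        out, truth = perturb_annotation(record, [], tmp_path / "same.gb")
        assert out.read_bytes() == path.read_bytes()
        assert truth["modes"] == []

    def test_overlap_mode_shifts_a_feature(self, synthetic_genome, tmp_path):
        from mitocompare.mito_io import read_genbank

        record, _, _ = synthetic_genome
        out, truth = perturb_annotation(record, ["overlap"],
                                        tmp_path / "overlap.gb")
        rec = read_genbank(out)
        name = truth["overlap"]["feature"]
        moved = [f for f in rec.features if f.name == name][0]
        assert moved.start == truth["overlap"]["new_start"]
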