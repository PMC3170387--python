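"""Anchored genome alignment vs a from-scratch dynamic program, and
substitution/INDEL statistics against simulation truth."""
import math

import numpy as np
import pytest

from plastokit import (EvolutionParams, PairwiseAlignment, compare_genomes,
                       concatenate_coding, divergence_stats, evolve_genome,
                       evolve_sequence, exclude_irb, pairwise_genome_align,
                       simulate_plastome)
from plastokit.sequences import random_dna

from _oracles import alignment_score, gotoh_score, rc


class TestAlignment:
    def test_self_alignment_identity(self):
        seq = random_dna(3000, np.random.default_rng(60))
        aln = pairwise_genome_align(seq, seq)
        assert len(aln) == len(seq)
        st = divergence_stats(aln)
        assert st.substitutions == 0 and st.indels_length == 0

    def test_block_deletion_gap_count(self):
        seq = random_dna(5000, np.random.default_rng(61))
        deleted = seq[:2000] + seq[2100:]
        aln = pairwise_genome_align(seq, deleted)
        st = divergence_stats(aln)
        assert st.indels_length == 100
        assert aln.row_a.replace("-", "") == seq
        assert aln.row_b.replace("-", "") == deleted

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_score_matches_quadratic_dp(self, seed):
        """The stitched anchored alignment scores exactly like a
        from-scratch affine-gap global DP on small diverged pairs."""
        rng = np.random.default_rng(70 + seed)
        a = random_dna(400, rng)
        b, _ = evolve_sequence(
            a, EvolutionParams(substitution_rate=0.05, r_target=0.7,
                               indel_rate=0.002, indel_mean_length=8,
                               seed=seed))
        aln = pairwise_genome_align(a, b)
        assert alignment_score(aln.row_a, aln.row_b) == gotoh_score(a, b)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pairwise_genome_align("", "ACGT")


class TestDivergenceStats:
    def test_hand_enumerated_columns(self):
        aln = PairwiseAlignment("ACGT", "GCTT")
        st = divergence_stats(aln)
        assert st.substitutions == 2
        assert st.si == 1 and st.sv == 1  # A<->G transition, G<->T transversion
        assert st.r == 1.0
        assert st.substitution_rate == 0.5

    def test_identical_sequences_undefined_r(self):
        st = divergence_stats(PairwiseAlignment("ACGT", "ACGT"))
        assert st.substitutions == 0 and st.indel_ratio == 0.0
        assert math.isnan(st.r)

    def test_sv_zero_gives_infinite_r(self):
        st = divergence_stats(PairwiseAlignment("AAAA", "GGAA"))
        assert st.si == 2 and st.sv == 0
        assert math.isinf(st.r)

    def test_gap_and_n_columns_never_substitutions(self):
        aln = PairwiseAlignment("ANG-T", "GCGAT")
        st = divergence_stats(aln)
        # A/G substitution; N column ignored; gap column counts as indel
        assert st.substitutions == 1 and st.si == 1
        assert st.indels_length == 1
        assert st.alignment_length == 5

    def test_si_sv_conservation(self):
        rng = np.random.default_rng(62)
        a = random_dna(20_000, rng)
        b, _ = evolve_sequence(a, EvolutionParams(substitution_rate=0.08,
                                                  r_target=0.5, seed=4))
        st = divergence_stats(pairwise_genome_align(a, b))
        assert st.si + st.sv == st.substitutions

    def test_parameter_recovery_small(self):
        """Estimated substitution count and R agree with the generator's
        event log on a 30 kb single-copy sequence."""
        rng = np.random.default_rng(63)
        a = random_dna(30_000, rng)
        params = EvolutionParams.with_indel_ratio_target(
            0.073, substitution_rate=0.05, r_target=0.7, seed=5)
        b, log = evolve_sequence(a, params)
        st = divergence_stats(pairwise_genome_align(a, b))
        n = log.n_substitutions
        assert abs(st.substitutions - n) <= 3 * math.sqrt(n)
        si, sv = log.si_sv()
        assert st.r == pytest.approx(si / sv, rel=0.05)


class TestIrExclusion:
    def test_annotation_trim_round_trip(self, small_plastome):
        sc = exclude_irb(small_plastome)
        assert sc == small_plastome.single_copy
        assert len(sc) == len(small_plastome) - len(small_plastome.seq_ira)

    def test_detection_matches_annotation(self, small_plastome):
        by_annotation = exclude_irb(small_plastome.sequence,
                                    small_plastome.irb_span)
        by_detection = exclude_irb(small_plastome.sequence)
        assert by_detection == by_annotation == small_plastome.single_copy


class TestCodingConcatenation:
    def test_additivity_and_strand(self):
        rng = np.random.default_rng(64)
        genome = random_dna(3000, rng)
        from plastokit import Feature

        feats = [
            Feature("g1", 0, 300, "+", "gene"),
            Feature("g2", 500, 1100, "-", "gene"),
            Feature("g3", 1500, 2400, "+", "gene"),
        ]
        cat, n = concatenate_coding(genome, feats)
        assert n == 3 and len(cat) == 1800
        assert cat[:300] == genome[:300]
        assert cat[300:900] == rc(genome[500:1100])

    def test_overlap_warns(self):
        from plastokit import Feature

        genome = random_dna(1000, np.random.default_rng(65))
        feats = [Feature("a", 0, 400, "+", "gene"),
                 Feature("b", 300, 700, "+", "gene")]
        with pytest.warns(UserWarning, match="overlap"):
            cat, n = concatenate_coding(genome, feats)
        assert len(cat) == 800

    def test_substitution_only_evolution_gene_differences(self, small_plastome):
        """With INDEL-free evolution, gene coordinates are unchanged and
        the concatenated coding sequences differ exactly at the logged
        substitution sites inside genes."""
        params = EvolutionParams(substitution_rate=0.03, r_target=0.7, seed=6)
        derived, log = evolve_genome(small_plastome, params)
        cat_a, na = concatenate_coding(small_plastome.single_copy,
                                       small_plastome.features)
        cat_b, nb = concatenate_coding(derived.single_copy, derived.features)
        assert na == nb and len(cat_a) == len(cat_b)
        diffs = sum(1 for x, y in zip(cat_a, cat_b) if x != y)
        in_gene = sum(
            any(f.start <= e.position < f.end for f in small_plastome.features)
            for e in log.events
        )
        assert diffs == in_gene

    def test_coding_divergence_lower_than_genome_wide(self, small_plastome):
        """With a coding rate multiplier < 1, the concatenated-gene
        comparison shows a lower substitution rate than the whole
        single-copy genome, as real plastomes do."""
        params = EvolutionParams(substitution_rate=0.06, r_target=0.7,
                                 coding_rate_multiplier=0.3, seed=7)
        derived, _ = evolve_genome(small_plastome, params)
        whole = compare_genomes(small_plastome.single_copy, derived.single_copy)
        cat_a, _ = concatenate_coding(small_plastome.single_copy,
                                      small_plastome.features)
        cat_b, _ = concatenate_coding(derived.single_copy, derived.features)
        coding = compare_genomes(cat_a, cat_b)
        assert coding.substitution_rate < whole.substitution_rate
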