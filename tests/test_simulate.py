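"""Simulator ground-truth invariants: quadripartite architecture, mutation
log fidelity, controllable si/sv mix, compartment sampling."""
import numpy as np
import pytest
from scipy import stats as sps

from plastokit import (EvolutionParams, divergence_preset, evolve_genome,
                       evolve_sequence, simulate_plastome,
                       simulate_total_dna_library)
from plastokit.simulate import (log_to_alignment, map_coordinate, replay_log,
                                write_fastq_pair, read_fastq_pair)
from plastokit.sequences import random_dna

from _oracles import rc


class TestPlastomeArchitecture:
    def test_full_scale_segments(self):
        p = simulate_plastome(size_factor=1.0, gene_count=0, seed=7)
        assert len(p.seq_lsc) == 90_000
        assert len(p.seq_ira) == 31_000
        assert len(p.seq_ssc) == 10_000
        assert len(p) == 162_000

    def test_scaling(self):
        p = simulate_plastome(size_factor=0.1, gene_count=0, seed=7)
        assert (len(p.seq_lsc), len(p.seq_ira), len(p.seq_ssc)) == (9000, 3100, 1000)

    def test_irb_is_revcomp_of_ira(self, small_plastome):
        # independent base-by-base reverse-complement check
        seq = small_plastome.sequence
        ira = small_plastome.seq_ira
        assert seq[-len(ira):] == rc(ira)

    def test_tiny_size_factor_rejected(self):
        with pytest.raises(ValueError):
            simulate_plastome(size_factor=0.005)

    def test_features_in_bounds_and_disjoint(self, small_plastome):
        fs = sorted(small_plastome.features, key=lambda f: f.start)
        assert len(fs) == 20
        for f in fs:
            assert 0 <= f.start < f.end <= len(small_plastome)
        for a, b in zip(fs, fs[1:]):
            assert a.end <= b.start

    def test_deterministic_per_seed(self):
        a = simulate_plastome(0.1, 10, seed=3)
        b = simulate_plastome(0.1, 10, seed=3)
        assert a.sequence == b.sequence and a.features == b.features


class TestEvolution:
    def test_zero_rates_identity(self, rng):
        anc = random_dna(2000, rng)
        params = EvolutionParams(substitution_rate=0.0, indel_rate=0.0)
        der, log = evolve_sequence(anc, params)
        assert der == anc and len(log) == 0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_log_replay_and_column_scan(self, seed):
        """Column-by-column scan of the log-implied alignment must agree
        with the log's own substitution tallies (independent oracle)."""
        rng = np.random.default_rng(seed)
        anc = random_dna(10_000, rng)
        params = EvolutionParams(substitution_rate=0.05, r_target=0.7,
                                 indel_rate=0.001, seed=seed)
        der, log = evolve_sequence(anc, params)
        assert replay_log(anc, log) == der
        row_a, row_b = log_to_alignment(anc, log)
        assert row_a.replace("-", "") == anc
        assert row_b.replace("-", "") == der
        transitions = {frozenset("AG"), frozenset("CT")}
        si = sv = 0
        for x, y in zip(row_a, row_b):
            if "-" in (x, y) or x == y:
                continue
            if frozenset((x, y)) in transitions:
                si += 1
            else:
                sv += 1
        assert (si, sv) == log.si_sv()

    def test_no_self_substitution(self):
        _, log = evolve_sequence(random_dna(20_000, np.random.default_rng(0)),
                                 EvolutionParams(substitution_rate=0.1, seed=5))
        assert all(e.ancestral != e.derived for e in log.events
                   if e.kind == "substitution")

    def test_realized_r_matches_target(self):
        """Over >= 10,000 substitutions the realized si/sv ratio stays
        within 3 binomial standard errors of the target."""
        r_target = 0.7
        anc = random_dna(300_000, np.random.default_rng(1))
        _, log = evolve_sequence(anc, EvolutionParams(substitution_rate=0.05,
                                                      r_target=r_target, seed=2))
        si, sv = log.si_sv()
        n = si + sv
        assert n >= 10_000
        p_hat = si / n
        p0 = r_target / (1 + r_target)
        se = np.sqrt(p0 * (1 - p0) / n)
        assert abs(p_hat - p0) < 3 * se

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            EvolutionParams(substitution_rate=-0.1)
        with pytest.raises(ValueError):
            EvolutionParams(r_target=0.0)
        with pytest.raises(ValueError):
            EvolutionParams(indel_rate=0.01, indel_mean_length=0.0)
        with pytest.raises(ValueError):
            EvolutionParams(coding_rate_multiplier=0.0)

    def test_genome_evolution_preserves_ir_identity(self, small_plastome):
        derived, log = evolve_genome(small_plastome,
                                     divergence_preset("inter-tribe", seed=9))
        assert derived.seq_irb == rc(derived.seq_ira)
        assert replay_log(small_plastome.single_copy, log) == derived.single_copy
        assert len(log) > 0

    def test_coordinate_lift_consistency(self, small_plastome):
        derived, log = evolve_genome(small_plastome,
                                     divergence_preset("intra-tribe", seed=4))
        # lifted feature intervals must stay within the derived genome
        for f in derived.features:
            assert 0 <= f.start < f.end <= len(derived)
        assert map_coordinate(log, 0) == 0

    def test_coding_multiplier_slows_genes(self, small_plastome):
        params = EvolutionParams(substitution_rate=0.08, r_target=0.7,
                                 coding_rate_multiplier=0.2, seed=3)
        _, log = evolve_genome(small_plastome, params)
        gene_sites = sum(f.end - f.start for f in small_plastome.features)
        total = len(small_plastome.single_copy)
        in_gene = sum(
            any(f.start <= e.position < f.end for f in small_plastome.features)
            for e in log.events
        )
        frac_gene_events = in_gene / len(log)
        frac_gene_sites = gene_sites / total
        assert frac_gene_events < 0.6 * frac_gene_sites


class TestLibrarySimulation:
    def test_empty_library(self, small_plastome):
        lib = simulate_total_dna_library(small_plastome, n_pairs=0, seed=0)
        assert len(lib) == 0

    def test_defaults_match_platform(self, small_plastome):
        lib = simulate_total_dna_library(small_plastome, n_pairs=5, seed=0)
        assert lib.tag_length == 50 and lib.insert_mean == 1500
        for p in lib.pairs:
            for t in (p.tag_f, p.tag_r):
                assert len(t.seq) == len(t.qv) == 50

    def test_outward_tags_reconstruct_fragment(self, small_plastome):
        lib = simulate_total_dna_library(small_plastome, n_pairs=50,
                                         error_rate=0.0, seed=6)
        circle = small_plastome.sequence * 2
        nchecked = 0
        for p in lib.pairs:
            if p.origin.compartment != "chloroplast":
                continue
            frag = circle[p.origin.start : p.origin.start + p.origin.length]
            if p.origin.strand == "-":
                frag = rc(frag)
            assert rc(p.tag_f.seq) == frag[:50]
            assert p.tag_r.seq == frag[-50:]
            nchecked += 1
        assert nchecked > 10

    def test_compartment_sampling_proportional(self, small_plastome):
        """Origin frequencies match (copy x length)-proportional sampling
        (chi-square at alpha = 0.01)."""
        lib = simulate_total_dna_library(
            small_plastome, nuclear_size=100_000, mito_size=30_000,
            copy_ratio_chl_per_nuclear=100.0, mito_copies_per_nuclear=10.0,
            n_pairs=6000, seed=8,
        )
        w = {
            "chloroplast": 100.0 * len(small_plastome),
            "nuclear": 100_000.0,
            "mitochondrial": 10.0 * 30_000,
        }
        total_w = sum(w.values())
        observed = {k: 0 for k in w}
        for p in lib.pairs:
            observed[p.origin.compartment] += 1
        obs = [observed[k] for k in w]
        exp = [w[k] / total_w * len(lib) for k in w]
        assert sps.chisquare(obs, exp).pvalue > 0.01

    def test_fastq_roundtrip(self, small_plastome, tmp_path):
        lib = simulate_total_dna_library(small_plastome, n_pairs=20, seed=2)
        f1, f2 = tmp_path / "r1.fastq", tmp_path / "r2.fastq"
        write_fastq_pair(lib, f1, f2)
        back = read_fastq_pair(f1, f2)
        assert len(back) == 20
        for a, b in zip(lib.pairs, back.pairs):
            assert a.tag_f.seq == b.tag_f.seq
            assert list(a.tag_f.qv) == list(b.tag_f.qv)
            assert a.tag_r.seq == b.tag_r.seq
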