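"""Ground-truth consistency and reproducibility of the generators."""

import numpy as np
import pytest

from ervpipe.cophylogeny import (CophylogenyProblem, CostScheme, minimal_cost)
from ervpipe.mining import reverse_complement
from ervpipe.synthetic import (REGIMES, default_implant_spec, emulate_hits,
                               evolve_k2p, random_sequence,
                               simulate_cophylogeny, simulate_decay_set,
                               simulate_genome_with_ervs)


class TestGenomeGenerator:
    def test_truth_table_size_and_genome_length(self):
        spec = default_implant_spec(1, n_copies=6, genome_length=120_000)
        genome, truth = simulate_genome_with_ervs(spec)
        assert len(truth) == 6
        assert len(genome) == 1
        assert len(genome[0].residues) >= 120_000

    def test_age_zero_copy_identical_to_master(self):
        spec = default_implant_spec(2, n_copies=2, ages=(0.0, 0.0),
                                    frameshift_rate=0.0,
                                    fragmentation_prob=0.0,
                                    genome_length=60_000)
        genome, truth = simulate_genome_with_ervs(spec)
        for rec in truth:
            seq = genome[0].residues[rec.start:rec.end]
            if rec.strand == "-":
                seq = reverse_complement(seq)
            assert seq == spec.master_sequence
            assert rec.divergence_realized == 0.0

    def test_mean_realized_divergence_near_target(self):
        mu = 2.15e-9
        spec = default_implant_spec(
            3, n_copies=50, ages=tuple([0.05 / mu] * 50), mu=mu,
            frameshift_rate=0.0, fragmentation_prob=0.0,
            genome_length=800_000)
        _, truth = simulate_genome_with_ervs(spec)
        mean_div = np.mean([t.divergence_realized for t in truth])
        assert 0.045 <= mean_div <= 0.055

    def test_truth_intervals_extractable(self):
        spec = default_implant_spec(4, n_copies=5, genome_length=100_000)
        genome, truth = simulate_genome_with_ervs(spec)
        L = len(genome[0].residues)
        for t in truth:
            assert 0 <= t.start < t.end <= L
            assert t.start <= t.core_start < t.core_end <= t.end
            for f in t.fragments:
                assert t.start <= f.genome_start < f.genome_end <= t.end

    def test_capacity_check(self):
        spec = default_implant_spec(5, n_copies=30, genome_length=50_000)
        with pytest.raises(ValueError, match="capacity"):
            simulate_genome_with_ervs(spec)

    def test_bit_reproducible(self):
        a = simulate_genome_with_ervs(default_implant_spec(6, n_copies=4,
                                                           genome_length=90_000))
        b = simulate_genome_with_ervs(default_implant_spec(6, n_copies=4,
                                                           genome_length=90_000))
        assert a[0][0].residues == b[0][0].residues
        assert a[1] == b[1]


class TestEmulatedHits:
    def test_unfragmented_copy_gives_one_hit(self):
        spec = default_implant_spec(7, n_copies=4, fragmentation_prob=0.0,
                                    genome_length=90_000)
        genome, truth = simulate_genome_with_ervs(spec)
        hits = emulate_hits(truth, spec)
        assert len(hits) == 4
        pol_aa = (spec.pol_interval[1] - spec.pol_interval[0]) // 3
        for h in hits:
            assert h.query_start == 0
            assert abs(h.query_end - pol_aa) <= 2

    def test_fragmented_copy_gives_colinear_hits(self):
        spec = default_implant_spec(8, n_copies=6, fragmentation_prob=1.0,
                                    genome_length=130_000)
        genome, truth = simulate_genome_with_ervs(spec)
        hits = emulate_hits(truth, spec)
        for rec in truth:
            mine = sorted((h for h in hits
                           if rec.start <= h.subject_start < rec.end),
                          key=lambda h: h.subject_start)
            assert len(mine) == len(rec.fragments) == 2
            assert len({h.strand for h in mine}) == 1
            a, b = mine
            if rec.strand == "+":
                assert a.query_end <= b.query_start + 1
            else:
                assert b.query_end <= a.query_start + 1

    def test_evalue_decreases_with_length(self):
        spec = default_implant_spec(9, n_copies=8, genome_length=180_000)
        _, truth = simulate_genome_with_ervs(spec)
        hits = emulate_hits(truth, spec)
        by_len = sorted(hits, key=lambda h: h.query_end - h.query_start)
        same_ident = [h for h in by_len if h.pident == by_len[0].pident]
        # within one copy (same identity), longer fragment -> smaller e-value
        if len(same_ident) >= 2:
            assert same_ident[0].evalue >= same_ident[-1].evalue


class TestDecaySet:
    def test_zero_time_identical(self):
        master = random_sequence(500, 0.5, np.random.default_rng(1))
        recs = simulate_decay_set(master, n=4, t=0.0, mu=2e-9, seed=1)
        assert all(r.residues == master for r in recs)

    def test_reproducible(self):
        master = random_sequence(500, 0.5, np.random.default_rng(2))
        a = simulate_decay_set(master, n=3, t=1e7, mu=2e-9, seed=9)
        b = simulate_decay_set(master, n=3, t=1e7, mu=2e-9, seed=9)
        assert a == b

    def test_needs_one_copy(self):
        with pytest.raises(ValueError):
            simulate_decay_set("ACGT", n=0, t=0, mu=1e-9)


class TestCophylogenySimulator:
    def test_cospeciation_only_is_congruent(self):
        host, virus, assoc, truth = simulate_cophylogeny(
            10, "cospeciation", seed=1)
        assert virus.n_tips() == host.n_tips() == 10
        assert truth.cospeciations == 9
        assert truth.switches == truth.losses == 0
        problem = CophylogenyProblem(host, virus, assoc)
        assert minimal_cost(problem, CostScheme(-1, 0, 0, 0, 0)) == -9

    def test_reproducible(self):
        a = simulate_cophylogeny(8, "mixed", seed=4)
        b = simulate_cophylogeny(8, "mixed", seed=4)
        assert a[0].to_newick() == b[0].to_newick()
        assert a[1].to_newick() == b[1].to_newick()
        assert a[2] == b[2]
        assert a[3] == b[3]

    def test_unknown_regime_rejected(self):
        with pytest.raises(ValueError, match="regime"):
            simulate_cophylogeny(5, "chaos")

    def test_regimes_exposed(self):
        assert set(REGIMES) == {"cospeciation", "switch", "mixed"}


def test_evolve_k2p_transition_bias():
    rng = np.random.default_rng(12)
    master = "A" * 30_000
    mutated = evolve_k2p(master, 0.09, rng)
    ts = sum(b == "G" for b in mutated)
    tv = sum(b in "CT" for b in mutated)
    assert ts / tv == pytest.approx(2.0, rel=0.15)
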