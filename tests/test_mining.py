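"""Hit filtering, defragmentation chaining, and phylogenetic triage."""

import pytest

from ervpipe.core_io import SimilarityHit
from ervpipe.mining import (ReferenceLabelSet, classify_candidates,
                            filter_hits, merge_adjacent_hits, mine)
from ervpipe.cophylogeny import random_topology
from ervpipe.phylo import parse_newick
from ervpipe.synthetic import (classification_tree, default_implant_spec,
                               emulate_hits, simulate_genome_with_ervs)


def make_hit(qstart, qend, sstart, send, strand="+", contig="c", query="q",
             evalue=1e-30):
    return SimilarityHit(
        query_id=query, subject_id=contig, pident=90.0, length=qend - qstart,
        mismatch=0, gapopen=0, query_start=qstart, query_end=qend,
        subject_start=sstart, subject_end=send, evalue=evalue, bitscore=100.0,
        strand=strand)


class TestFilterHits:
    def test_threshold(self):
        hits = [make_hit(0, 10, 0, 30, evalue=1e-30),
                make_hit(0, 10, 100, 130, evalue=1e-3)]
        assert filter_hits(hits, 1e-5) == [hits[0]]

    def test_empty(self):
        assert filter_hits([], 1e-5) == []

    def test_boundary_is_inclusive(self):
        hits = [make_hit(0, 10, 0, 30, evalue=1e-10)]
        assert filter_hits(hits, 1e-10) == hits

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            filter_hits([], 0)


class TestMergeAdjacentHits:
    def test_single_hit(self):
        (locus,) = merge_adjacent_hits([make_hit(0, 100, 999, 1299)])
        assert (locus.start, locus.end) == (999, 1299)
        assert len(locus.segments) == 1

    def test_two_hit_chain(self):
        # genomic gap 500 nt, query gap 19 aa: both within defaults
        hits = [make_hit(0, 100, 99, 399), make_hit(119, 220, 899, 1199)]
        (locus,) = merge_adjacent_hits(hits)
        assert (locus.start, locus.end) == (99, 1199)
        assert len(locus.segments) == 2

    def test_opposite_strands_stay_apart(self):
        hits = [make_hit(0, 100, 99, 399, strand="+"),
                make_hit(119, 220, 899, 1199, strand="-")]
        assert len(merge_adjacent_hits(hits)) == 2

    def test_genomic_gap_limit(self):
        hits = [make_hit(0, 100, 99, 399), make_hit(119, 220, 5399, 5699)]
        assert len(merge_adjacent_hits(hits, max_genomic_gap=2000)) == 2

    def test_anticolinear_not_chained(self):
        # second hit earlier in the query than the first: not one insertion
        hits = [make_hit(119, 220, 99, 399), make_hit(0, 100, 899, 1199)]
        assert len(merge_adjacent_hits(hits)) == 2

    def test_minus_strand_colinearity(self):
        # on the minus strand the query must run backwards along the genome
        hits = [make_hit(119, 220, 99, 399, strand="-"),
                make_hit(0, 100, 899, 1199, strand="-")]
        (locus,) = merge_adjacent_hits(hits)
        assert (locus.start, locus.end) == (99, 1199)

    def test_overlapping_queries_unify(self):
        hits = [make_hit(0, 100, 99, 399, query="qA", evalue=1e-40),
                make_hit(0, 100, 299, 599, query="qB", evalue=1e-20)]
        (locus,) = merge_adjacent_hits(hits)
        assert (locus.start, locus.end) == (99, 599)
        assert locus.query_id == "qA"  # lower e-value seeds
        assert locus.best_evalue == 1e-40

    def test_idempotent(self, rng):
        hits = []
        pos = 0
        for i in range(20):
            q0 = rng.randrange(0, 500)
            qlen = rng.randrange(20, 200)
            slen = qlen * 3
            pos += rng.randrange(0, 4000)
            hits.append(make_hit(q0, q0 + qlen, pos, pos + slen,
                                 strand=rng.choice("+-"),
                                 query=rng.choice(["qA", "qB"])))
            pos += slen
        loci = merge_adjacent_hits(hits)
        again = merge_adjacent_hits([s for l in loci for s in l.segments])
        assert [(l.contig, l.start, l.end, l.strand) for l in loci] == \
               [(l.contig, l.start, l.end, l.strand) for l in again]

    def test_output_loci_non_overlapping_per_track(self, rng):
        hits = [make_hit(rng.randrange(0, 300), rng.randrange(300, 600),
                         s, s + rng.randrange(100, 3000),
                         query=rng.choice(["qA", "qB", "qC"]))
                for s in rng.sample(range(0, 50_000, 40), 60)]
        loci = merge_adjacent_hits(hits)
        by_track = {}
        for l in loci:
            by_track.setdefault((l.contig, l.strand), []).append(l)
        for track in by_track.values():
            track.sort(key=lambda l: l.start)
            for a, b in zip(track, track[1:]):
                assert a.end <= b.start


class TestClassifyCandidates:
    LABELS = ReferenceLabelSet({"RV1": "retrovirus", "TE1": "retrotransposon",
                                "OUT": "outgroup"})

    def test_sister_to_retrovirus(self):
        tree = parse_newick("((cand,RV1),(TE1,OUT));")
        res = classify_candidates({"cand"}, tree, self.LABELS)
        assert res == {"cand": "erv"}

    def test_sister_to_retrotransposon(self):
        tree = parse_newick("((cand,TE1),(RV1,OUT));")
        res = classify_candidates({"cand"}, tree, self.LABELS)
        assert res == {"cand": "rejected"}

    def test_mixed_reference_clade(self):
        tree = parse_newick("((cand,(RV1,TE1)),OUT);")
        res = classify_candidates({"cand"}, tree, self.LABELS)
        assert res == {"cand": "unclassified"}

    def test_nested_retrovirus_clade(self):
        tree = parse_newick("(((cand,RV1),TE1),OUT);")
        res = classify_candidates({"cand"}, tree, self.LABELS)
        assert res == {"cand": "erv"}

    def test_candidate_missing(self):
        tree = parse_newick("((RV1,TE1),OUT);")
        with pytest.raises(ValueError, match="ghost"):
            classify_candidates({"ghost"}, tree, self.LABELS)

    def test_agrees_with_exhaustive_clade_enumeration(self, rng):
        """Oracle: scan every clade for the smallest one holding the
        candidate plus a reference, instead of walking up from the tip."""
        for _ in range(20):
            cands = [f"cand{i}" for i in range(4)]
            refs = {f"RV{i}": "retrovirus" for i in range(6)}
            refs.update({f"TE{i}": "retrotransposon" for i in range(5)})
            refs["OUT"] = "outgroup"
            labels = ReferenceLabelSet(refs)
            tips = cands + list(refs)
            tree = random_topology(tips, rng)
            got = classify_candidates(set(cands), tree, labels)

            rooted = tree.rooted_on({"OUT"})
            clades = [rooted.clade_tips(n) for n in rooted.postorder()]
            for cand in cands:
                holding = [c for c in clades
                           if cand in c and c & labels.references]
                smallest = min(holding, key=len)
                found = smallest & labels.references
                if found <= labels.retroviruses:
                    expect = "erv"
                elif found <= labels.retrotransposons:
                    expect = "rejected"
                else:
                    expect = "unclassified"
                assert got[cand] == expect


class TestMineStage:
    def test_synthetic_recovery_all_erv(self):
        spec = default_implant_spec(3, n_copies=10, genome_length=200_000)
        genome, truth = simulate_genome_with_ervs(spec)
        hits = emulate_hits(truth, spec)
        loci = mine(genome, hits, None, None)
        tree, labels = classification_tree([l.locus_id for l in loci])
        loci = mine(genome, hits, tree, labels)
        assert len(loci) == 10
        assert all(l.status == "erv" for l in loci)

    def test_zero_hits(self):
        spec = default_implant_spec(3, n_copies=0)
        genome, _ = simulate_genome_with_ervs(spec)
        assert mine(genome, [], None, None) == []

    def test_retrotransposon_seeded_locus_rejected(self):
        spec = default_implant_spec(4, n_copies=5, genome_length=120_000)
        genome, truth = simulate_genome_with_ervs(spec)
        hits = emulate_hits(truth, spec)
        loci = mine(genome, hits, None, None)
        bad = loci[0].locus_id
        tree, labels = classification_tree([l.locus_id for l in loci],
                                           retrotransposon_partnered=[bad])
        loci = mine(genome, hits, tree, labels)
        statuses = {l.locus_id: l.status for l in loci}
        assert statuses.pop(bad) == "rejected"
        assert set(statuses.values()) == {"erv"}

    def test_writes_outputs(self, tmp_path):
        spec = default_implant_spec(5, n_copies=3, genome_length=80_000)
        genome, truth = simulate_genome_with_ervs(spec)
        hits = emulate_hits(truth, spec)
        prefix = str(tmp_path / "run")
        loci = mine(genome, hits, None, None, out_prefix=prefix)
        tsv = (tmp_path / "run.loci.tsv").read_text().splitlines()
        assert len(tsv) == len(loci) + 1  # header
        from ervpipe.core_io import read_fasta
        fasta = read_fasta(tmp_path / "run.loci.fasta")
        assert [r.id for r in fasta] == [l.locus_id for l in loci]
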