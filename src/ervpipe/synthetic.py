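"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate what the real workflow consumes: host genomes
carrying implanted, decayed, fragmented proviral copies (plus the similarity
hits a translated search would report against them), sets of ERV copies
decayed from a common ancestor for dating, and co-evolving host/virus tree
pairs with tunable cospeciation vs host-switch regimes.  Sequence decay uses
a Kimura two-parameter process with a 2:1 transition:transversion bias, so
the K2P estimator in :mod:`ervpipe.dating` is the matched estimator.

The emitted e-values follow a declared monotone surrogate
(``e = 10**(-0.1 * identity% * length_aa / 100)``), not a claim about real
search statistics: tests must depend only on configured thresholds, never on
this formula's absolute scale.

Everything is bit-reproducible given (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .core_io import SequenceRecord, SimilarityHit
from .mining import ErvLocus, ReferenceLabelSet, reverse_complement
from .phylo import Node, Phylogeny

_BASES = np.array(list("ACGT"))
_BASE_IDX = {b: i for i, b in enumerate("ACGT")}
# transition partner, then the two transversion partners, per base
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


# ---------------------------------------------------------------------------
# sequence-level primitives
# ---------------------------------------------------------------------------

def random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    p_at, p_gc = (1.0 - gc) / 2.0, gc / 2.0
    draws = rng.choice(_BASES, size=length, p=[p_at, p_gc, p_gc, p_at])
    return "".join(draws)


def _k2p_site_probs(d: float) -> tuple[float, float]:
    """(transition prob, total transversion prob) after branch length d.

    K2P with transition rate alpha = 4*beta (so the instantaneous
    transition:transversion ratio is 2:1) normalized to one expected
    substitution per unit branch length.
    """
    p_ts = 0.25 - 0.5 * math.exp(-5.0 * d / 3.0) + 0.25 * math.exp(-2.0 * d / 3.0)
    p_tv = 0.5 - 0.5 * math.exp(-2.0 * d / 3.0)
    return p_ts, p_tv


def evolve_k2p(seq: str, d: float, rng: np.random.Generator) -> str:
    """Evolve ``seq`` for branch length d (expected substitutions/site)."""
    if d < 0:
        raise ValueError("branch length must be >= 0")
    if d == 0:
        return seq
    p_ts, p_tv = _k2p_site_probs(d)
    u = rng.random(len(seq))
    pick = rng.random(len(seq))
    out = list(seq)
    for i, base in enumerate(seq):
        if u[i] < p_ts:
            out[i] = _TRANSITION.get(base, base)
        elif u[i] < p_ts + p_tv:
            tv = _TRANSVERSIONS.get(base)
            if tv:
                out[i] = tv[0] if pick[i] < 0.5 else tv[1]
    return "".join(out)


def _mismatch_fraction(a: str, b: str) -> float:
    return sum(x != y for x, y in zip(a, b)) / len(a)


# ---------------------------------------------------------------------------
# genomes with implanted ERVs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImplantSpec:
    """Parameters of one synthetic genome with implanted proviral copies.

    ``master_sequence`` is the proviral template; ``pol_interval`` marks its
    pol-homologous region (0-based half-open nt, in frame).  Per-copy ages
    (years) times ``mu`` (substitutions/site/year) give the decay each copy
    accumulated; ``frameshift_rate`` is the expected number of 1-2 nt indels
    per copy (Poisson); with probability ``fragmentation_prob`` a copy is
    split in two inside the pol region and the gap is filled with background
    sequence (so genomic adjacency distances stay controllable).
    """

    master_sequence: str
    pol_interval: tuple[int, int]
    n_copies: int = 20
    ages: Optional[tuple[float, ...]] = None       # years; default drawn
    mu: float = 2.15e-9
    frameshift_rate: float = 1.0
    fragmentation_prob: float = 0.5
    fragment_gap_mean: float = 400.0
    fragment_gap_max: int = 1500
    genome_length: int = 400_000
    gc_background: float = 0.41
    min_spacing: int = 3000
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.pol_interval
        if not (0 <= lo < hi <= len(self.master_sequence)):
            raise ValueError("pol interval outside master")
        if self.n_copies < 0 or self.mu < 0 or self.frameshift_rate < 0:
            raise ValueError("rates and counts must be >= 0")
        if not 0 <= self.fragmentation_prob <= 1:
            raise ValueError("fragmentation_prob must be a probability")


@dataclass(frozen=True)
class Fragment:
    genome_start: int
    genome_end: int
    master_start: int
    master_end: int


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one implanted copy."""

    copy_id: str
    contig: str
    start: int              # full implant block (incl. background-filled gaps)
    end: int
    strand: str
    age_years: float
    divergence_realized: float
    fragments: tuple[Fragment, ...]
    core_start: int         # span recoverable from pol-anchored hits
    core_end: int


def default_implant_spec(seed: int = 0, **overrides) -> ImplantSpec:
    """The default recovery scenario: 20 decayed, half-fragmented copies.

    Master is a 7.2 kb provirus with a 4.5 kb pol region; copy divergences
    are uniform on 1-20%, fragment gaps stay below the miner's default
    2 kb chaining distance.
    """
    rng = np.random.default_rng(seed)
    master = random_sequence(7200, 0.45, rng)
    spec = ImplantSpec(master_sequence=master, pol_interval=(1800, 6300),
                       seed=seed)
    return replace(spec, **overrides) if overrides else spec


def _apply_frameshifts(copy: list[str], master_idx: list[int],
                       n_indels: int, rng: np.random.Generator) -> None:
    """1-2 nt insertions/deletions, in place, keeping the master-index map."""
    for _ in range(n_indels):
        if len(copy) < 10:
            break
        pos = int(rng.integers(1, len(copy) - 1))
        size = int(rng.integers(1, 3))
        if rng.random() < 0.5:
            del copy[pos:pos + size]
            del master_idx[pos:pos + size]
        else:
            ins = [str(b) for b in rng.choice(_BASES, size=size)]
            copy[pos:pos] = ins
            master_idx[pos:pos] = [-1] * size


def simulate_genome_with_ervs(spec: ImplantSpec,
                              ) -> tuple[list[SequenceRecord], list[TruthRecord]]:
    """One synthetic contig with ``n_copies`` implanted decayed proviruses."""
    rng = np.random.default_rng(spec.seed)
    master = spec.master_sequence
    pol_lo, pol_hi = spec.pol_interval
    contig = "chr1"

    if spec.ages is not None:
        if len(spec.ages) != spec.n_copies:
            raise ValueError("need one age per copy")
        ages = list(spec.ages)
    else:
        div = rng.uniform(0.01, 0.20, size=spec.n_copies)
        ages = list(div / spec.mu) if spec.mu > 0 else [0.0] * spec.n_copies

    blocks: list[tuple[str, TruthRecord]] = []  # (block sequence, truth@origin0)
    for k in range(spec.n_copies):
        d = spec.mu * ages[k]
        decayed = evolve_k2p(master, d, rng)
        realized = _mismatch_fraction(master, decayed)
        copy = list(decayed)
        master_idx = list(range(len(master)))
        n_indels = int(rng.poisson(spec.frameshift_rate))
        _apply_frameshifts(copy, master_idx, n_indels, rng)

        # fragmentation: split once inside pol, keeping both sides anchored
        pieces: list[tuple[int, int]] = [(0, len(copy))]  # copy-coordinate
        if spec.fragmentation_prob > 0 and rng.random() < spec.fragmentation_prob:
            # breakpoint leaves >= 600 nt of pol on each side
            in_pol = [i for i, m in enumerate(master_idx)
                      if m >= 0 and pol_lo + 600 <= m < pol_hi - 600]
            if in_pol:
                cut = int(rng.choice(in_pol))
                pieces = [(0, cut), (cut, len(copy))]

        # lay out pieces with background-filled gaps
        block_parts: list[str] = []
        frags: list[Fragment] = []
        offset = 0
        for i, (c0, c1) in enumerate(pieces):
            if i > 0:
                gap = int(min(spec.fragment_gap_max,
                              max(50, rng.geometric(1.0 / spec.fragment_gap_mean))))
                block_parts.append(random_sequence(gap, spec.gc_background, rng))
                offset += gap
            seg = copy[c0:c1]
            midx = [m for m in master_idx[c0:c1] if m >= 0]
            block_parts.append("".join(seg))
            frags.append(Fragment(offset, offset + len(seg),
                                  min(midx), max(midx) + 1))
            offset += len(seg)
        block = "".join(block_parts)

        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            block = reverse_complement(block)
            frags = [Fragment(len(block) - f.genome_end,
                              len(block) - f.genome_start,
                              f.master_start, f.master_end)
                     for f in reversed(frags)]

        core = _core_span(frags, pol_lo, pol_hi, strand)
        truth = TruthRecord(
            copy_id=f"copy{k}", contig=contig, start=0, end=len(block),
            strand=strand, age_years=ages[k], divergence_realized=realized,
            fragments=tuple(frags), core_start=core[0], core_end=core[1])
        blocks.append((block, truth))

    total_blocks = sum(len(b) for b, _ in blocks)
    slack = spec.genome_length - total_blocks - spec.min_spacing * (len(blocks) + 1)
    if slack < 0:
        raise ValueError("copies exceed genome capacity")
    cuts = np.sort(rng.integers(0, slack + 1, size=len(blocks)))
    genome_parts: list[str] = []
    pos = 0
    placed: list[TruthRecord] = []
    prev_cut = 0
    for i, (block, truth) in enumerate(blocks):
        pad = spec.min_spacing + int(cuts[i] - prev_cut)
        prev_cut = int(cuts[i])
        genome_parts.append(random_sequence(pad, spec.gc_background, rng))
        pos += pad
        placed.append(replace(
            truth, start=pos, end=pos + len(block),
            fragments=tuple(replace(f, genome_start=f.genome_start + pos,
                                    genome_end=f.genome_end + pos)
                            for f in truth.fragments),
            core_start=truth.core_start + pos, core_end=truth.core_end + pos))
        genome_parts.append(block)
        pos += len(block)
    tail = spec.genome_length - pos
    genome_parts.append(random_sequence(max(tail, spec.min_spacing), spec.gc_background, rng))
    genome = [SequenceRecord(contig, "".join(genome_parts))]
    return genome, placed


def _core_span(frags: Sequence[Fragment], pol_lo: int, pol_hi: int,
               strand: str) -> tuple[int, int]:
    """Genomic span of the pol-overlapping parts of the fragments."""
    spans = []
    for f in frags:
        seg = _project_master_window(f, pol_lo, pol_hi, strand)
        if seg is not None:
            spans.append(seg)
    if not spans:
        return (0, 0)
    return min(s for s, _ in spans), max(e for _, e in spans)


def _project_master_window(f: Fragment, lo: int, hi: int, strand: str,
                           ) -> Optional[tuple[int, int]]:
    """Genome interval of the fragment's overlap with master window [lo,hi).

    On the minus strand the fragment's genome interval runs antiparallel to
    its master interval, so the projection anchors on the genome end.
    """
    ov_lo, ov_hi = max(f.master_start, lo), min(f.master_end, hi)
    if ov_lo >= ov_hi:
        return None
    mspan = f.master_end - f.master_start
    gspan = f.genome_end - f.genome_start
    a = (ov_lo - f.master_start) / mspan
    b = (ov_hi - f.master_start) / mspan
    if strand == "+":
        return (f.genome_start + round(a * gspan), f.genome_start + round(b * gspan))
    return (f.genome_end - round(b * gspan), f.genome_end - round(a * gspan))


def emulate_hits(truth: Sequence[TruthRecord], spec: ImplantSpec,
                 query_id: str = "pol_query",
                 min_overlap_nt: int = 60) -> list[SimilarityHit]:
    """Stand-in for a translated similarity search against the genome.

    One hit per implanted fragment overlapping the pol region, with correct
    genomic/query coordinates and strand, and the declared surrogate
    e-value (decreasing in fragment length and identity).
    """
    pol_lo, pol_hi = spec.pol_interval
    hits: list[SimilarityHit] = []
    for rec in truth:
        identity = 100.0 * (1.0 - rec.divergence_realized)
        for f in rec.fragments:
            ov_lo, ov_hi = max(f.master_start, pol_lo), min(f.master_end, pol_hi)
            if ov_hi - ov_lo < min_overlap_nt:
                continue
            q0 = (ov_lo - pol_lo) // 3
            q1 = (ov_hi - pol_lo + 2) // 3
            proj = _project_master_window(f, pol_lo, pol_hi, rec.strand)
            assert proj is not None
            g0, g1 = proj
            # on the minus strand, query order runs backwards along the genome
            len_aa = q1 - q0
            evalue = 10.0 ** (-0.1 * identity * len_aa / 100.0)
            frame = 1 if rec.strand == "+" else -1
            hits.append(SimilarityHit(
                query_id=query_id, subject_id=rec.contig, pident=identity,
                length=len_aa, mismatch=int(len_aa * (1 - identity / 100)),
                gapopen=0, query_start=q0, query_end=q1,
                subject_start=g0, subject_end=g1,
                evalue=evalue, bitscore=2.0 * len_aa * identity / 100.0,
                strand=rec.strand, frame=frame))
    hits.sort(key=lambda h: (h.subject_id, h.subject_start))
    return hits


def score_recovery(loci: Sequence[ErvLocus], truth: Sequence[TruthRecord],
                   tolerance_nt: int = 50) -> tuple[float, float]:
    """(recall, precision) of mined loci against the recoverable truth spans.

    A truth copy is recovered if some locus on the same contig and strand has
    both boundaries within ``tolerance_nt`` of the copy's pol-anchored core
    span; a locus is a true positive if it recovers some copy.
    """
    def match(l: ErvLocus, t: TruthRecord) -> bool:
        return (l.contig == t.contig and l.strand == t.strand
                and abs(l.start - t.core_start) <= tolerance_nt
                and abs(l.end - t.core_end) <= tolerance_nt)

    recovered = sum(any(match(l, t) for l in loci) for t in truth)
    true_pos = sum(any(match(l, t) for t in truth) for l in loci)
    recall = recovered / len(truth) if truth else 1.0
    precision = true_pos / len(loci) if loci else 1.0
    return recall, precision


# ---------------------------------------------------------------------------
# classification-tree fixture
# ---------------------------------------------------------------------------

def classification_tree(candidates: Sequence[str],
                        retrotransposon_partnered: Sequence[str] = (),
                        ) -> tuple[Phylogeny, ReferenceLabelSet]:
    """A reference tree placing each candidate sister to a labeled reference.

    Candidates in ``retrotransposon_partnered`` get a retrotransposon sister
    (and will classify as ``rejected``); all others sit next to a retrovirus
    reference.  Two retrotransposons and one outgroup taxon complete the
    tree, which is rooted on the outgroup by the classifier.
    """
    te_set = set(retrotransposon_partnered)
    labels: dict[str, str] = {"TE_ref1": "retrotransposon",
                              "TE_ref2": "retrotransposon",
                              "OUT_cer": "outgroup"}
    core: Optional[Node] = None
    for i, cand in enumerate(candidates):
        if cand in te_set:
            partner, kind = f"TE_p{i}", "retrotransposon"
        else:
            partner, kind = f"RV_p{i}", "retrovirus"
        labels[partner] = kind
        cherry = Node()
        cherry.add_child(Node(cand))
        cherry.add_child(Node(partner))
        if core is None:
            core = cherry
        else:
            top = Node()
            top.add_child(core)
            top.add_child(cherry)
            core = top
    if core is None:
        raise ValueError("no candidates")
    if "RV_p0" not in labels and not any(k == "retrovirus" for k in labels.values()):
        labels["RV_ref"] = "retrovirus"
        extra = Node()
        extra.add_child(core)
        extra.add_child(Node("RV_ref"))
        core = extra
    te = Node()
    te.add_child(Node("TE_ref1"))
    te.add_child(Node("TE_ref2"))
    mid = Node()
    mid.add_child(core)
    mid.add_child(te)
    root = Node()
    root.add_child(mid)
    root.add_child(Node("OUT_cer"))
    return Phylogeny(root), ReferenceLabelSet(labels)


# ---------------------------------------------------------------------------
# dating fixtures
# ---------------------------------------------------------------------------

def simulate_decay_set(master: str, n: int, t: float, mu: float,
                       seed: int = 0) -> list[SequenceRecord]:
    """n copies independently decayed from a common ancestor for t years.

    Each copy accumulates an expected mu*t substitutions/site under the 2:1
    K2P process, so pairwise K2P distances concentrate around 2*mu*t.  The
    output is a gap-free alignment (indel-free decay).
    """
    if n < 1:
        raise ValueError("need n >= 1 copies")
    rng = np.random.default_rng(seed)
    d = mu * t
    return [SequenceRecord(f"erv{i}", evolve_k2p(master, d, rng))
            for i in range(n)]


# ---------------------------------------------------------------------------
# co-evolving host/virus trees
# ---------------------------------------------------------------------------

REGIMES = {
    # (p_cospeciate at a host speciation, p_switch on a host branch)
    "cospeciation": (1.0, 0.0),
    "switch": (0.2, 0.5),
    "mixed": (0.8, 0.15),
}


@dataclass
class CophylogenyTruth:
    cospeciations: int = 0
    losses: int = 0
    switches: int = 0


def _yule_topology(n: int, rng: np.random.Generator, prefix: str) -> Phylogeny:
    tips = [Node(f"{prefix}1")]
    root = tips[0]
    for k in range(2, n + 1):
        target = tips[int(rng.integers(0, len(tips)))]
        left = Node(target.label)
        right = Node(f"{prefix}{k}")
        target.label = None
        target.add_child(left)
        target.add_child(right)
        tips.remove(target)
        tips.extend([left, right])
    return Phylogeny(root)


def simulate_cophylogeny(n_hosts: int, regime: str = "mixed", seed: int = 0,
                         ) -> tuple[Phylogeny, Phylogeny, dict[str, set[str]],
                                    CophylogenyTruth]:
    """Co-evolve a virus tree down a Yule host tree.

    At each host speciation the virus cospeciates with probability p_c or
    persists down one side (a loss on the other); on each host branch a
    duplication & host switch occurs with probability p_s, the switching
    daughter landing on a uniformly chosen non-ancestral, non-descendant
    host branch.  Simulation is conditioned on >= 3 surviving virus tips.
    """
    if n_hosts < 2:
        raise ValueError("need >= 2 hosts")
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}; choose from {sorted(REGIMES)}")
    p_c, p_s = REGIMES[regime]
    rng = np.random.default_rng(seed)

    for _ in range(200):
        host = _yule_topology(n_hosts, rng, "H")
        host_nodes = list(host.postorder())
        parent = {}
        for n in host_nodes:
            for c in n.children:
                parent[id(c)] = n
        def comparable(a: Node, b: Node) -> bool:
            x = a
            while x is not None:
                if x is b:
                    return True
                x = parent.get(id(x))
            x = b
            while x is not None:
                if x is a:
                    return True
                x = parent.get(id(x))
            return False

        truth = CophylogenyTruth()
        tip_counter = [0]
        assoc: dict[str, set[str]] = {}

        def evolve(h: Node, depth: int) -> Node:
            if depth > 500:
                raise RecursionError
            # a switch may fire on the branch into h
            if p_s > 0 and rng.random() < p_s:
                targets = [x for x in host_nodes if not comparable(x, h)]
                if targets:
                    truth.switches += 1
                    tgt = targets[int(rng.integers(0, len(targets)))]
                    v = Node()
                    v.add_child(_evolve_below(h, depth + 1))
                    v.add_child(evolve(tgt, depth + 1))
                    return v
            return _evolve_below(h, depth)

        def _evolve_below(h: Node, depth: int) -> Node:
            if h.is_leaf:
                tip_counter[0] += 1
                name = f"v{tip_counter[0]}"
                assoc[name] = {h.label}
                return Node(name)
            if rng.random() < p_c:
                truth.cospeciations += 1
                v = Node()
                v.add_child(evolve(h.children[0], depth + 1))
                v.add_child(evolve(h.children[1], depth + 1))
                return v
            truth.losses += 1
            side = int(rng.integers(0, 2))
            return evolve(h.children[side], depth + 1)

        try:
            virus_root = evolve(host.root, 0)
        except RecursionError:
            continue
        virus = Phylogeny(virus_root)
        if virus.n_tips() >= 3:
            return host, virus, assoc, truth
    raise RuntimeError("failed to simulate a surviving virus tree")


# ---------------------------------------------------------------------------
# whole-pipeline fixture
# ---------------------------------------------------------------------------

def write_pipeline_fixture(out_dir, seed: int = 0) -> dict:
    """Write a coherent set of inputs for every pipeline stage plus a config.

    The mining inputs come from one implanted genome; the consensus cluster
    groups all implanted copies (they share one master, so they form one
    family); the dating alignment is an indel-free decay set from the
    master's pol region; the cophylogeny and transmission inputs come from
    the co-evolution simulator.  Returns the config mapping (also written to
    ``config.yaml``).
    """
    import random as _random

    import yaml as _yaml

    from .cophylogeny import random_topology
    from .core_io import (write_association_table, write_fasta,
                          write_group_table, write_hits_table)
    from .mining import mine as _mine

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    spec = default_implant_spec(seed, n_copies=8, genome_length=150_000)
    genome, truth = simulate_genome_with_ervs(spec)
    hits = emulate_hits(truth, spec)
    write_fasta(genome, out / "genome.fasta")
    write_hits_table(hits, out / "hits.tsv")

    loci = _mine(genome, hits, None, None, species="synthspecies")
    tree, labels = classification_tree([l.locus_id for l in loci])
    (out / "tree.newick").write_text(tree.to_newick() + "\n")
    write_group_table(dict(labels.labels), out / "labels.tsv")

    with open(out / "clusters.tsv", "w") as fh:
        for l in loci:
            fh.write(f"cl1\t{l.locus_id}\n")
    rep = max(loci, key=lambda l: (l.span, l.contig, -l.start))
    paralog_hits = []
    for l in loci:
        if l is rep:
            continue
        L = min(rep.span, l.span)
        if l.strand == "+":
            s0, s1 = l.start, l.start + L
        else:
            s0, s1 = l.end - L, l.end
        paralog_hits.append(SimilarityHit(
            query_id="cl1", subject_id=l.contig, pident=85.0, length=L,
            mismatch=int(L * 0.15), gapopen=0, query_start=0, query_end=L,
            subject_start=s0, subject_end=s1, evalue=1e-30,
            bitscore=1.5 * L, strand=l.strand))
    write_hits_table(paralog_hits, out / "paralog_hits.tsv")

    pol_lo, pol_hi = spec.pol_interval
    aln = simulate_decay_set(spec.master_sequence[pol_lo:pol_hi], n=8,
                             t=3.0e7, mu=2.15e-9, seed=seed + 1)
    write_fasta(aln, out / "alignment.fasta")

    host, virus, assoc, _ = simulate_cophylogeny(8, "mixed", seed=seed)
    (out / "host.newick").write_text(host.to_newick() + "\n")
    (out / "virus.newick").write_text(virus.to_newick() + "\n")
    write_association_table(assoc, out / "associations.tsv")

    rng = _random.Random(seed)
    erv_tree = random_topology([f"erv{i}" for i in range(1, 13)], rng)
    (out / "class_tree.newick").write_text(erv_tree.to_newick() + "\n")
    group_cycle = ["Actinopterygii", "Amphibia", "Testudines", "Squamata"]
    habitat_of = {"Actinopterygii": "aquatic", "Amphibia": "both",
                  "Testudines": "aquatic", "Squamata": "terrestrial"}
    groups = {f"erv{i}": group_cycle[(i - 1) % 4] for i in range(1, 13)}
    habitats = {tip: habitat_of[g] for tip, g in groups.items()}
    write_group_table(groups, out / "groups.tsv", habitats)

    config = {
        "output_dir": str(out / "results"),
        "seed": seed,
        "mine": {
            "genome": str(out / "genome.fasta"),
            "hits": str(out / "hits.tsv"),
            "tree": str(out / "tree.newick"),
            "labels": str(out / "labels.tsv"),
            "evalue_max": 1e-5,
            "max_genomic_gap": 2000,
            "max_query_gap": 50,
            "species": "synthspecies",
        },
        "consensus": {
            "clusters": str(out / "clusters.tsv"),
            "paralog_hits": str(out / "paralog_hits.tsv"),
            "flank": 5000,
            "evalue_max": 1e-10,
        },
        "dating": {
            "alignment": str(out / "alignment.fasta"),
            "mu_low": 1.9e-9,
            "mu_high": 2.4e-9,
        },
        "cophylogeny": {
            "host": str(out / "host.newick"),
            "virus": str(out / "virus.newick"),
            "associations": str(out / "associations.tsv"),
            "schemes": ["0,1,2,1,1", "-1,0,0,0,0", "0,1,1,2,0"],
            "n_random": 100,
            "seed": seed,
        },
        "transmission": {
            "tree": str(out / "class_tree.newick"),
            "groups": str(out / "groups.tsv"),
        },
    }
    with open(out / "config.yaml", "w") as fh:
        _yaml.safe_dump(config, fh, sort_keys=True)
    return config
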