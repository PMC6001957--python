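"""Defragmentation of similarity hits into ERV loci, and phylogenetic triage.

Ancient proviruses decay: frameshifts and indels break one insertion into
several partial similarity hits against the retroviral Pol query.  The miner
re-assembles ("defragments") such hits into candidate loci by chaining hits
that are adjacent both in the genome and in the query protein, then keeps
only candidates that cluster with retrovirus references — rather than with
other retrotransposons — on an externally built phylogeny.  No LTR detection
is involved, which is what makes the approach sensitive to degraded copies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .core_io import (SequenceRecord, SimilarityHit, write_fasta)
from .phylo import Node, Phylogeny

logger = logging.getLogger("ervpipe.mining")

DEFAULT_EVALUE_MAX = 1e-5
DEFAULT_MAX_GENOMIC_GAP = 2000
DEFAULT_MAX_QUERY_GAP = 50

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ErvLocus:
    """A merged genomic interval representing one (candidate) ERV insertion."""

    species: str
    contig: str
    start: int          # 0-based half-open genomic interval
    end: int
    strand: str
    segments: list[SimilarityHit] = field(default_factory=list)
    best_evalue: float = float("inf")
    query_id: str = ""
    status: str = "candidate"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"bad locus interval {self.start}..{self.end}")
        if any(s.subject_id != self.contig or s.strand != self.strand
               for s in self.segments):
            raise ValueError("segments must share the locus contig and strand")

    @property
    def locus_id(self) -> str:
        s = "p" if self.strand == "+" else "m"
        return f"{self.species}__{self.contig}__{self.start}_{self.end}_{s}"

    @property
    def span(self) -> int:
        return self.end - self.start

    def sequence(self, genome: Mapping[str, str]) -> str:
        """Strand-corrected nucleotide sequence of the locus."""
        raw = genome[self.contig][self.start:self.end]
        return reverse_complement(raw) if self.strand == "-" else raw


@dataclass(frozen=True)
class ReferenceLabelSet:
    """Reference-tip labels: retrovirus / retrotransposon / outgroup."""

    labels: Mapping[str, str]

    def __post_init__(self) -> None:
        kinds = set(self.labels.values())
        bad = kinds - {"retrovirus", "retrotransposon", "outgroup"}
        if bad:
            raise ValueError(f"unknown reference labels: {sorted(bad)}")
        if "retrovirus" not in kinds or "retrotransposon" not in kinds:
            raise ValueError(
                "need at least one retrovirus and one retrotransposon reference")

    @property
    def retroviruses(self) -> set[str]:
        return {t for t, k in self.labels.items() if k == "retrovirus"}

    @property
    def retrotransposons(self) -> set[str]:
        return {t for t, k in self.labels.items() if k == "retrotransposon"}

    @property
    def outgroups(self) -> set[str]:
        return {t for t, k in self.labels.items() if k == "outgroup"}

    @property
    def references(self) -> set[str]:
        """Classifying references (outgroups only place the root)."""
        return self.retroviruses | self.retrotransposons


# ---------------------------------------------------------------------------
# hit filtering and chaining
# ---------------------------------------------------------------------------

def filter_hits(hits: Sequence[SimilarityHit],
                evalue_max: float) -> list[SimilarityHit]:
    """Keep hits with e-value <= threshold, preserving input order."""
    if evalue_max <= 0:
        raise ValueError("evalue_max must be positive")
    kept = [h for h in hits if h.evalue <= evalue_max]
    logger.info("e-value filter %.3g: %d -> %d hits", evalue_max, len(hits),
                len(kept))
    return kept


def _chainable(a: SimilarityHit, b: SimilarityHit,
               max_genomic_gap: int, max_query_gap: int) -> bool:
    """Can genomically-ordered hits a, b (a first) extend one chain?

    Adjacency must hold in both the genome and the query, and query order
    must be colinear with genomic order given the strand (on the minus
    strand the query runs backwards along the genome).
    """
    if a.subject_id != b.subject_id or a.strand != b.strand:
        return False
    if b.subject_start - a.subject_end > max_genomic_gap:
        return False
    if a.strand == "+":
        colinear = b.query_start >= a.query_start and b.query_end >= a.query_end
        gap = b.query_start - a.query_end
    else:
        colinear = a.query_start >= b.query_start and a.query_end >= b.query_end
        gap = a.query_start - b.query_end
    return colinear and gap <= max_query_gap


def merge_adjacent_hits(hits: Sequence[SimilarityHit],
                        max_genomic_gap: int = DEFAULT_MAX_GENOMIC_GAP,
                        max_query_gap: int = DEFAULT_MAX_QUERY_GAP,
                        species: str = "",
                        genome: Optional[Mapping[str, str]] = None,
                        ) -> list[ErvLocus]:
    """Chain adjacent hits into loci; unify genomically overlapping loci.

    Chaining is transitive within one (contig, strand, query) group; loci
    seeded by different query proteins that overlap by >= 1 bp on the same
    contig and strand are unified into one locus (one insertion found by many
    queries), keeping the lower-e-value query as seed.
    """
    if max_genomic_gap < 0 or max_query_gap < 0:
        raise ValueError("gaps must be >= 0")
    if genome is not None:
        unknown = {h.subject_id for h in hits} - set(genome)
        if unknown:
            raise ValueError(f"hits on unknown contigs: {sorted(unknown)}")

    groups: dict[tuple[str, str, str], list[SimilarityHit]] = {}
    for h in hits:
        groups.setdefault((h.subject_id, h.strand, h.query_id), []).append(h)

    loci: list[ErvLocus] = []
    for (contig, strand, query), members in groups.items():
        members = sorted(members, key=lambda h: (h.subject_start, h.subject_end))
        # transitive closure via union-find over all ordered pairs
        parent = list(range(len(members)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if _chainable(members[i], members[j],
                              max_genomic_gap, max_query_gap):
                    parent[find(j)] = find(i)
        chains: dict[int, list[SimilarityHit]] = {}
        for i, h in enumerate(members):
            chains.setdefault(find(i), []).append(h)
        for chain in chains.values():
            loci.append(ErvLocus(
                species=species, contig=contig,
                start=min(h.subject_start for h in chain),
                end=max(h.subject_end for h in chain),
                strand=strand, segments=chain,
                best_evalue=min(h.evalue for h in chain),
                query_id=query,
            ))

    merged = _unify_overlapping(loci)
    logger.info("merged %d hits into %d loci", len(hits), len(merged))
    return merged


def _unify_overlapping(loci: list[ErvLocus]) -> list[ErvLocus]:
    out: list[ErvLocus] = []
    by_track: dict[tuple[str, str], list[ErvLocus]] = {}
    for loc in loci:
        by_track.setdefault((loc.contig, loc.strand), []).append(loc)
    for track in by_track.values():
        track.sort(key=lambda l: (l.start, l.end))
        current = track[0]
        for nxt in track[1:]:
            if nxt.start < current.end:  # >= 1 bp genomic overlap
                seed = min([current, nxt], key=lambda l: (l.best_evalue, l.query_id))
                current = ErvLocus(
                    species=current.species, contig=current.contig,
                    start=min(current.start, nxt.start),
                    end=max(current.end, nxt.end),
                    strand=current.strand,
                    segments=sorted(current.segments + nxt.segments,
                                    key=lambda h: h.subject_start),
                    best_evalue=min(current.best_evalue, nxt.best_evalue),
                    query_id=seed.query_id,
                )
            else:
                out.append(current)
                current = nxt
        out.append(current)
    out.sort(key=lambda l: (l.contig, l.start, l.strand))
    return out


# ---------------------------------------------------------------------------
# phylogenetic classification
# ---------------------------------------------------------------------------

def classify_candidates(candidate_tips: set[str], tree: Phylogeny,
                        labels: ReferenceLabelSet) -> dict[str, str]:
    """Classify candidates by the smallest enclosing reference clade.

    The tree is rooted on the branch separating the outgroup references from
    everything else; for each candidate, the smallest clade containing it and
    at least one classifying reference decides: all-retrovirus references
    -> ``erv``, all-retrotransposon -> ``rejected``, mixed -> ``unclassified``.
    """
    refs = labels.references
    if not refs:
        raise ValueError("no reference tips")
    tips = set(tree.tip_labels())
    missing = candidate_tips - tips
    if missing:
        raise ValueError(f"candidate tips absent from tree: {sorted(missing)}")
    missing_refs = (refs | labels.outgroups) - tips
    if missing_refs:
        raise ValueError(f"reference tips absent from tree: {sorted(missing_refs)}")
    if labels.outgroups:
        tree = tree.rooted_on(labels.outgroups)

    parent: dict[Node, Optional[Node]] = {tree.root: None}
    clade: dict[Node, frozenset[str]] = {}
    for node in tree.postorder():
        for ch in node.children:
            parent[ch] = node
        clade[node] = (frozenset([node.label]) if node.is_leaf else
                       frozenset().union(*(clade[c] for c in node.children)))
    by_label = {n.label: n for n in tree.tips()}

    result: dict[str, str] = {}
    for cand in sorted(candidate_tips):
        node: Optional[Node] = by_label[cand]
        while node is not None and not (clade[node] & refs):
            node = parent[node]
        if node is None:
            result[cand] = "unclassified"
            continue
        found = clade[node] & refs
        if found <= labels.retroviruses:
            result[cand] = "erv"
        elif found <= labels.retrotransposons:
            result[cand] = "rejected"
        else:
            result[cand] = "unclassified"
    return result


# ---------------------------------------------------------------------------
# full stage
# ---------------------------------------------------------------------------

def mine(genome: Sequence[SequenceRecord], hits: Sequence[SimilarityHit],
         tree: Optional[Phylogeny], labels: Optional[ReferenceLabelSet],
         evalue_max: float = DEFAULT_EVALUE_MAX,
         max_genomic_gap: int = DEFAULT_MAX_GENOMIC_GAP,
         max_query_gap: int = DEFAULT_MAX_QUERY_GAP,
         species: str = "",
         out_prefix: Optional[str] = None) -> list[ErvLocus]:
    """Filter -> merge -> classify; optionally write locus TSV and FASTA.

    With ``tree=None`` the loci are returned with status ``candidate``
    (classification deferred — the tree is normally built on the candidates).
    """
    seqs = {r.id: r.residues for r in genome}
    kept = filter_hits(hits, evalue_max)
    loci = merge_adjacent_hits(kept, max_genomic_gap, max_query_gap,
                               species=species, genome=seqs if genome else None)
    if tree is not None and labels is not None:
        statuses = classify_candidates({l.locus_id for l in loci}, tree, labels)
        for loc in loci:
            loc.status = statuses[loc.locus_id]
    n_erv = sum(l.status == "erv" for l in loci)
    logger.info("mine: %d loci (%d classified erv)", len(loci), n_erv)
    if out_prefix is not None:
        write_loci(loci, seqs, out_prefix)
    return loci


def write_loci(loci: Sequence[ErvLocus], genome: Mapping[str, str],
               out_prefix: str) -> None:
    tsv = Path(f"{out_prefix}.loci.tsv")
    with open(tsv, "w") as fh:
        fh.write("species\tcontig\tstart\tend\tstrand\tn_segments\t"
                 "best_evalue\tseed_query\tstatus\n")
        for l in loci:
            fh.write(f"{l.species}\t{l.contig}\t{l.start}\t{l.end}\t{l.strand}"
                     f"\t{len(l.segments)}\t{l.best_evalue:.3g}\t{l.query_id}"
                     f"\t{l.status}\n")
    records = [SequenceRecord(l.locus_id, l.sequence(genome)) for l in loci]
    write_fasta(records, f"{out_prefix}.loci.fasta")
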