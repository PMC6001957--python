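"""Consensus ERV genome reconstruction from genomic paralogs.

A retroviral cluster's members are decayed copies of the same ancestral
provirus.  Because the copies decayed independently, a per-column majority
vote across the representative (the longest member) and its paralogs cancels
most lineage-specific substitutions and recovers a close approximation of
the ancestral sequence.  Paralogs enter the vote through their similarity-hit
coordinates projected onto the representative — no multiple alignment is
re-inferred, which keeps the procedure deterministic and fast; indels inside
a hit segment are absorbed by proportional coordinate projection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .core_io import SimilarityHit
from .mining import ErvLocus, reverse_complement

logger = logging.getLogger("ervpipe.consensus")

PARALOG_EVALUE_MAX = 1e-10
DEFAULT_FLANK = 5000

# IUPAC code for every non-empty nucleotide set
_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H",
    frozenset("ACG"): "V", frozenset("ACGT"): "N",
}


@dataclass
class ErvCluster:
    """A phylogenetic cluster of ERV loci from one or two species."""

    cluster_id: str
    members: list[ErvLocus]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"cluster {self.cluster_id} is empty")

    @property
    def species_set(self) -> set[str]:
        return {m.species for m in self.members}


@dataclass
class ConsensusRecord:
    cluster_id: str
    species: str
    residues: str
    depth_profile: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.depth_profile and min(self.depth_profile) < 1:
            raise ValueError("consensus depth must be >= 1 everywhere")


@dataclass(frozen=True)
class ProjectedSegment:
    """A paralog segment mapped onto representative coordinates.

    ``start``/``end`` are 0-based half-open positions on the representative;
    ``residues`` is the strand-corrected paralog sequence for that window.
    """

    start: int
    end: int
    residues: str


def select_representative(cluster: ErvCluster) -> ErvLocus:
    """The longest member; ties broken by smallest (contig, start)."""
    return min(cluster.members,
               key=lambda m: (-(m.end - m.start), m.contig, m.start))


def gather_paralogs(paralog_hits: Sequence[SimilarityHit],
                    evalue_max: float = PARALOG_EVALUE_MAX,
                    ) -> list[SimilarityHit]:
    """Keep paralog hits at or below the e-value cutoff (default 1e-10)."""
    return [h for h in paralog_hits if h.evalue <= evalue_max]


def window_filter(paralog_hits: Sequence[SimilarityHit],
                  pol_interval: tuple[int, int],
                  flank: int = DEFAULT_FLANK,
                  representative_length: Optional[int] = None,
                  ) -> list[SimilarityHit]:
    """Keep hits overlapping the pol interval extended by ``flank`` nt.

    The window is anchored on the representative's pol-homologous region
    (query coordinates) and clipped to the representative.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    lo = max(0, pol_interval[0] - flank)
    hi = pol_interval[1] + flank
    if representative_length is not None:
        hi = min(hi, representative_length)
    return [h for h in paralog_hits
            if h.query_start < hi and h.query_end > lo]


def segments_from_hits(hits: Sequence[SimilarityHit],
                       genome: Mapping[str, str]) -> list[ProjectedSegment]:
    """Extract strand-corrected paralog residues for each hit.

    The query interval of each hit lives on the representative; the subject
    interval addresses the paralog in the genome.
    """
    segs = []
    for h in hits:
        seq = genome[h.subject_id][h.subject_start:h.subject_end]
        if h.strand == "-":
            seq = reverse_complement(seq)
        segs.append(ProjectedSegment(h.query_start, h.query_end, seq))
    return segs


def build_consensus(representative: str,
                    segments: Sequence[ProjectedSegment],
                    cluster_id: str = "",
                    species: str = "") -> ConsensusRecord:
    """Majority-vote consensus over representative coordinates.

    Each admitted segment votes its residue at every representative position
    it covers (proportional projection if segment and window lengths differ);
    the representative itself casts one vote per column.  Strict majority
    wins; ties produce the IUPAC ambiguity code of the tied residue set.
    """
    n = len(representative)
    votes: list[dict[str, int]] = [{} for _ in range(n)]
    depth = [1] * n
    for base, pos in zip(representative, range(n)):
        votes[pos][base] = 1
    for seg in segments:
        if seg.start < 0 or seg.end > n:
            raise ValueError(
                f"segment {seg.start}..{seg.end} outside representative (len {n})")
        span = seg.end - seg.start
        m = len(seg.residues)
        for i in range(span):
            # proportional projection absorbs within-segment indels
            j = i if m == span else (i * m) // span
            base = seg.residues[j]
            pos = seg.start + i
            votes[pos][base] = votes[pos].get(base, 0) + 1
            depth[pos] += 1

    out = []
    for col in votes:
        best = max(col.values())
        top = frozenset(b for b, c in col.items() if c == best)
        if len(top) == 1:
            out.append(next(iter(top)))
        else:
            out.append(_IUPAC.get(frozenset().union(*[set(b) for b in top]), "N"))
    return ConsensusRecord(cluster_id, species, "".join(out), depth)


def consensus_for_cluster(cluster: ErvCluster,
                          genome: Mapping[str, str],
                          paralog_hits: Sequence[SimilarityHit],
                          pol_interval: Optional[tuple[int, int]] = None,
                          flank: int = DEFAULT_FLANK,
                          evalue_max: float = PARALOG_EVALUE_MAX,
                          species: Optional[str] = None) -> ConsensusRecord:
    """Full single-species consensus: representative + filtered paralogs."""
    rep = select_representative(cluster)
    rep_seq = rep.sequence(genome)
    admitted = gather_paralogs(paralog_hits, evalue_max)
    if pol_interval is not None:
        admitted = window_filter(admitted, pol_interval, flank, len(rep_seq))
    segments = segments_from_hits(admitted, genome)
    rec = build_consensus(rep_seq, segments, cluster.cluster_id,
                          species if species is not None else rep.species)
    logger.info("cluster %s: consensus over %d paralog segments, length %d",
                cluster.cluster_id, len(segments), len(rec.residues))
    return rec


def consensus_per_species(cluster: ErvCluster,
                          genomes: Mapping[str, Mapping[str, str]],
                          paralog_hits: Mapping[str, Sequence[SimilarityHit]],
                          pol_interval: Optional[tuple[int, int]] = None,
                          flank: int = DEFAULT_FLANK,
                          evalue_max: float = PARALOG_EVALUE_MAX,
                          ) -> list[ConsensusRecord]:
    """Two-species cluster: run the procedure independently per species."""
    species = sorted(cluster.species_set)
    if len(species) > 2:
        raise ValueError(
            f"cluster {cluster.cluster_id} spans {len(species)} species; "
            "only 1- and 2-species clusters are defined")
    records = []
    for sp in species:
        sub = ErvCluster(cluster.cluster_id,
                         [m for m in cluster.members if m.species == sp])
        records.append(consensus_for_cluster(
            sub, genomes[sp], paralog_hits.get(sp, []), pol_interval, flank,
            evalue_max, species=sp))
    return records
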