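"""Readers and writers for every standard format the pipeline touches.

Conventions fixed here and relied on everywhere else:

* Sequences travel as :class:`SequenceRecord` (FASTA via Biopython).
* Similarity hits come from 12-column tab-separated search output
  (qseqid sseqid pident length mismatch gapopen qstart qend sstart send
  evalue bitscore).  File coordinates are 1-based inclusive and a subject
  start greater than the subject end marks the minus strand; internally every
  interval is 0-based half-open on the plus strand with an explicit strand
  flag, so interval arithmetic downstream has no off-by-one traps.  An
  optional 13th column is read as the tblastn frame.
* Trees are newick (see :mod:`ervpipe.phylo`).
* Associations and group maps are 2/3-column TSV.
* Run configuration is YAML with one section per stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .phylo import Phylogeny, parse_newick, write_newick  # noqa: F401  (re-export)

logger = logging.getLogger("ervpipe")

PathLike = Union[str, Path]

HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA record; residues uppercased IUPAC letters."""

    id: str
    residues: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class SimilarityHit:
    """One row of tabular similarity output, normalized.

    ``query_start/query_end`` and ``subject_start/subject_end`` are 0-based
    half-open; subject coordinates are always on the plus strand with
    ``strand`` recording the original orientation.  ``frame`` is in
    {-3..-1, 1..3} for translated searches and 0 for nucleotide ones.
    """

    query_id: str
    subject_id: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    evalue: float
    bitscore: float
    strand: str = "+"
    frame: int = 0

    def __post_init__(self) -> None:
        if self.query_start >= self.query_end:
            raise ValueError(f"bad query interval {self.query_start}..{self.query_end}")
        if self.subject_start >= self.subject_end:
            raise ValueError(
                f"bad subject interval {self.subject_start}..{self.subject_end}")
        if self.evalue < 0:
            raise ValueError("negative e-value")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def subject_span(self) -> int:
        return self.subject_end - self.subject_start


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: PathLike) -> list[SequenceRecord]:
    """Read FASTA into records (order preserved, residues uppercased).

    An empty file yields an empty list with a warning; duplicated ids raise.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(rec.id, str(rec.seq).upper(), desc))
    if not records:
        logger.warning("no FASTA records read from %s", path)
    return records


def write_fasta(records: list[SequenceRecord], path: PathLike) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


# ---------------------------------------------------------------------------
# tabular similarity hits
# ---------------------------------------------------------------------------

def _hit_from_fields(fields: list[str], lineno: int) -> SimilarityHit:
    if len(fields) not in (12, 13):
        raise ValueError(
            f"line {lineno}: expected 12 (or 13) tab-separated columns, "
            f"got {len(fields)}")
    try:
        pident = float(fields[2])
        length = int(fields[3])
        mismatch = int(fields[4])
        gapopen = int(fields[5])
        qstart, qend = int(fields[6]), int(fields[7])
        sstart, send = int(fields[8]), int(fields[9])
        evalue = float(fields[10])
        bitscore = float(fields[11])
        frame = int(fields[12]) if len(fields) == 13 else 0
    except ValueError as exc:
        raise ValueError(f"line {lineno}: non-numeric field ({exc})") from exc
    if qstart > qend:
        raise ValueError(f"line {lineno}: query start {qstart} > end {qend}")
    strand = "+" if sstart <= send else "-"
    lo, hi = (sstart, send) if strand == "+" else (send, sstart)
    return SimilarityHit(
        query_id=fields[0], subject_id=fields[1], pident=pident, length=length,
        mismatch=mismatch, gapopen=gapopen,
        query_start=qstart - 1, query_end=qend,
        subject_start=lo - 1, subject_end=hi,
        evalue=evalue, bitscore=bitscore, strand=strand, frame=frame,
    )


def read_hits_table(path: PathLike) -> list[SimilarityHit]:
    """Read 12-column tabular similarity output (empty file -> empty list)."""
    hits: list[SimilarityHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            hits.append(_hit_from_fields(line.split("\t"), lineno))
    logger.info("read %d similarity hits from %s", len(hits), path)
    return hits


def hit_to_row(hit: SimilarityHit) -> list[str]:
    """Back-convert one hit to the 12 (13 with frame) file columns."""
    sstart, send = hit.subject_start + 1, hit.subject_end
    if hit.strand == "-":
        sstart, send = send, sstart
    row = [
        hit.query_id, hit.subject_id, f"{hit.pident:.2f}", str(hit.length),
        str(hit.mismatch), str(hit.gapopen),
        str(hit.query_start + 1), str(hit.query_end),
        str(sstart), str(send), f"{hit.evalue:.2e}", f"{hit.bitscore:.1f}",
    ]
    if hit.frame:
        row.append(str(hit.frame))
    return row


def write_hits_table(hits: list[SimilarityHit], path: PathLike) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write("\t".join(hit_to_row(h)) + "\n")


# ---------------------------------------------------------------------------
# association and group tables
# ---------------------------------------------------------------------------

def read_association_table(path: PathLike,
                           virus_tree: Optional[Phylogeny] = None,
                           ) -> dict[str, set[str]]:
    """Read virus-tip -> host-tip associations from 2-column TSV.

    A virus tip on several rows is associated to several hosts (the input of
    a failure-to-diverge event).  When a virus tree is supplied, every virus
    tip in the table must be one of its tips.
    """
    assoc: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"line {lineno}: expected 2 columns")
            v, h = parts
            assoc.setdefault(v, set()).add(h)
    if not assoc:
        raise ValueError(f"no associations in {path}")
    if virus_tree is not None:
        tips = set(virus_tree.tip_labels())
        unknown = set(assoc) - tips
        if unknown:
            raise ValueError(
                f"virus tips absent from virus tree: {sorted(unknown)}")
    return assoc


def write_association_table(assoc: dict[str, set[str]], path: PathLike) -> None:
    with open(path, "w") as fh:
        for v in sorted(assoc):
            for h in sorted(assoc[v]):
                fh.write(f"{v}\t{h}\n")


def read_group_table(path: PathLike) -> tuple[dict[str, str], dict[str, str]]:
    """Read tip -> group (and optional tip -> habitat) from 2/3-column TSV."""
    groups: dict[str, str] = {}
    habitats: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (2, 3):
                raise ValueError(f"line {lineno}: expected 2 or 3 columns")
            if not parts[1]:
                raise ValueError(f"line {lineno}: empty group name")
            groups[parts[0]] = parts[1]
            if len(parts) == 3 and parts[2]:
                habitats[parts[0]] = parts[2]
    return groups, habitats


def write_group_table(groups: dict[str, str], path: PathLike,
                      habitats: Optional[dict[str, str]] = None) -> None:
    with open(path, "w") as fh:
        for tip in sorted(groups):
            if habitats:
                fh.write(f"{tip}\t{groups[tip]}\t{habitats.get(tip, '')}\n")
            else:
                fh.write(f"{tip}\t{groups[tip]}\n")


# ---------------------------------------------------------------------------
# configuration and logging
# ---------------------------------------------------------------------------

def load_config(path: PathLike) -> dict:
    """Load the per-stage YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping of stage sections")
    return cfg


def setup_logging(logfile: Optional[PathLike] = None,
                  level: int = logging.INFO) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(str(logfile)))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )
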