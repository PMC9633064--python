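"""Reference genome and annotation model.

Loads a genome (FASTA) and a CDS-level gene annotation (GFF3), and provides
the strand-aware coding-sequence extraction and translation that consequence
prediction is built on. Coordinates are 1-based inclusive throughout, matching
GFF3; conversion to 0-based happens only at string-indexing boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Data import CodonTable as _BioCodonTable

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_BASES = frozenset("ACGTN")
# degeneracy codes normalised to N on input
_DEGENERATE = frozenset("RYSWKMBDHV")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the A,C,G,T,N alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Genome:
    """Chromosome id -> uppercase nucleotide string (alphabet A,C,G,T,N)."""

    records: dict[str, str]

    def __post_init__(self) -> None:
        for cid, seq in self.records.items():
            if not cid:
                raise ValueError("empty chromosome id")
            bad = set(seq) - _VALID_BASES
            if bad:
                raise ValueError(f"invalid bases {sorted(bad)} in {cid!r}")

    def __getitem__(self, chrom: str) -> str:
        return self.records[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.records

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of [start, end], 1-based inclusive."""
        seq = self.records[chrom]
        if start < 1 or end > len(seq) or start > end:
            raise ValueError(f"interval ({start},{end}) outside {chrom} (len {len(seq)})")
        return seq[start - 1 : end]


@dataclass
class GeneAnnotation:
    """One gene's CDS structure on a chromosome.

    ``cds_intervals`` are 1-based inclusive, sorted, non-overlapping; spliced
    CDS length must be a multiple of 3.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_intervals: list[tuple[int, int]] = field(default_factory=list)
    essential: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        self.cds_intervals = sorted(self.cds_intervals)
        for (s1, e1), (s2, e2) in zip(self.cds_intervals, self.cds_intervals[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping CDS intervals in {self.gene_id}")

    @property
    def span(self) -> tuple[int, int]:
        return self.cds_intervals[0][0], self.cds_intervals[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_intervals)


def standard_codon_table() -> dict[str, str]:
    """Standard nuclear codon table as codon -> amino acid ('*' for stop)."""
    bio = _BioCodonTable.unambiguous_dna_by_id[1]
    table = dict(bio.forward_table)
    for stop in bio.stop_codons:
        table[stop] = "*"
    assert len(table) == 64
    return table


def read_fasta(path: str | Path) -> Genome:
    """Read a FASTA file into a :class:`Genome`.

    Record ids are the first whitespace token of each header; sequences are
    uppercased and IUPAC degeneracy codes are normalised to N. A duplicate id
    or a non-IUPAC character is a hard error.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate chromosome id {rec.id!r}")
        seq = str(rec.seq).upper()
        cleaned = []
        for ch in seq:
            if ch in _VALID_BASES:
                cleaned.append(ch)
            elif ch in _DEGENERATE:
                cleaned.append("N")
            else:
                raise ValueError(f"non-IUPAC character {ch!r} in record {rec.id!r}")
        records[rec.id] = "".join(cleaned)
    return Genome(records)


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for cid, seq in genome.records.items():
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _gff_attributes(col9: str) -> dict[str, str]:
    out = {}
    for part in col9.strip().split(";"):
        part = part.strip()
        if not part or "=" not in part:
            continue
        key, val = part.split("=", 1)
        out[key] = val
    return out


def read_gff(path: str | Path, essential_ids: set[str] | None = None) -> list[GeneAnnotation]:
    """Read CDS features from a GFF3 file and group them per gene.

    The gene id of a CDS line is its ``Parent`` attribute (first value) or,
    failing that, its ``ID``. Genes whose spliced CDS length is not a multiple
    of 3 are excluded with a logged warning rather than truncated.
    """
    essential_ids = essential_ids or set()
    grouped: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9 or cols[2] != "CDS":
                continue
            chrom, _, _, start, end, _, strand, _, attrs = cols[:9]
            a = _gff_attributes(attrs)
            gid = a.get("Parent", a.get("ID", "")).split(",")[0]
            if not gid:
                raise ValueError(f"CDS feature without Parent/ID in {path}")
            g = grouped.setdefault(gid, {"chrom": chrom, "strand": strand, "ivals": []})
            g["ivals"].append((int(start), int(end)))
    out = []
    for gid, g in grouped.items():
        ann = GeneAnnotation(
            gene_id=gid,
            chrom=g["chrom"],
            strand=g["strand"],
            cds_intervals=g["ivals"],
            essential=gid in essential_ids,
        )
        if ann.cds_length % 3 != 0:
            logger.warning(
                "excluding gene %s: spliced CDS length %d not a multiple of 3",
                gid, ann.cds_length,
            )
            continue
        out.append(ann)
    return out


def write_gff(annotations: Iterable[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for ann in annotations:
            for s, e in ann.cds_intervals:
                fh.write(
                    f"{ann.chrom}\ttoy\tCDS\t{s}\t{e}\t.\t{ann.strand}\t0\t"
                    f"Parent={ann.gene_id}\n"
                )


def coding_sequence(genome: Genome, gene: GeneAnnotation) -> str:
    """Spliced coding sequence in transcription order (revcomp on '-')."""
    parts = [genome.fetch(gene.chrom, s, e) for s, e in gene.cds_intervals]
    cds = "".join(parts)
    if gene.strand == "-":
        cds = reverse_complement(cds)
    return cds


def translate_cds(cds: str, table: dict[str, str] | None = None) -> str:
    """Translate a CDS codon by codon.

    Internal stops are rendered '*' and retained (nonsense edits must remain
    visible); codons containing N translate to 'X'.
    """
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not a multiple of 3")
    table = table if table is not None else standard_codon_table()
    out = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        out.append("X" if "N" in codon else table[codon])
    return "".join(out)


def genes_overlapping(
    annotations: list[GeneAnnotation], chrom: str, interval: tuple[int, int]
) -> list[str]:
    """Gene ids whose CDS span intersects ``interval`` on ``chrom``."""
    known = {a.chrom for a in annotations}
    if chrom not in known:
        raise ValueError(f"unknown chromosome {chrom!r}")
    start, end = interval
    if start > end:
        raise ValueError(f"invalid interval ({start},{end})")
    hits = []
    for ann in annotations:
        if ann.chrom != chrom:
            continue
        s, e = ann.span
        if s <= end and start <= e:
            hits.append(ann.gene_id)
    return hits
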