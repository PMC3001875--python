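"""Readers/writers for FASTA, GTF, a SAM subset, and CIGAR arithmetic.

Internal coordinates are 0-based half-open throughout; GTF on disk is
1-based inclusive. Conversion happens only here. The alignment file is a
SAM-like tab format restricted to single-end reads with a scalar read
quality and an explicit uniqueness status (it is not valid SAM).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CIGAR_RE = re.compile(r"(\d+)([MIDNS])")

# uniqueness states for alignments
UNIQUE = "unique"
MULTI = "multi"
PARTIAL = "partial"
UNMAPPED = "unmapped"


class CigarError(ValueError):
    pass


def parse_cigar(cigar: str, pos: int) -> tuple[list[tuple[int, int]], int, int]:
    """Project a CIGAR string onto the reference.

    Returns ``(blocks, left_clip, right_clip)`` where *blocks* is the list of
    half-open reference intervals covered by M runs (adjacent M runs merged,
    D extends the current block, N opens a new one), and the clips are soft-
    clipped read lengths at either end.
    """
    if cigar in ("", "*"):
        return [], 0, 0
    blocks: list[tuple[int, int]] = []
    left_clip = right_clip = 0
    ref = pos
    consumed = 0
    seen_m = False
    for m in CIGAR_RE.finditer(cigar):
        if m.start() != consumed:
            raise CigarError(f"malformed cigar {cigar!r} at offset {consumed}")
        consumed = m.end()
        n, op = int(m.group(1)), m.group(2)
        if op == "S":
            if seen_m:
                right_clip += n
            else:
                left_clip += n
        elif op == "M":
            seen_m = True
            if blocks and blocks[-1][1] == ref:
                blocks[-1] = (blocks[-1][0], ref + n)
            else:
                blocks.append((ref, ref + n))
            ref += n
        elif op == "D":
            if blocks and blocks[-1][1] == ref:
                blocks[-1] = (blocks[-1][0], ref + n)
            ref += n
        elif op == "N":
            ref += n
        elif op == "I":
            pass
    if consumed != len(cigar):
        raise CigarError(f"malformed cigar {cigar!r} at offset {consumed}")
    return [tuple(b) for b in blocks], left_clip, right_clip


def cigar_read_length(cigar: str) -> int:
    """Read bases consumed by a CIGAR (sum of M, I and S runs)."""
    return sum(
        int(m.group(1)) for m in CIGAR_RE.finditer(cigar) if m.group(2) in "MIS"
    )


@dataclass
class SamRecord:
    """One single-end read placement (or an unmapped read)."""

    read_id: str
    mapped: bool
    strand: bool  # True = forward
    contig_id: str | None
    pos: int | None  # 0-based leftmost
    mapping_score: int
    cigar: str | None
    sequence: str
    read_quality: float

    def blocks(self) -> list[tuple[int, int]]:
        if not self.mapped or not self.cigar:
            return []
        return parse_cigar(self.cigar, self.pos)[0]

    @property
    def is_split(self) -> bool:
        return self.mapped and self.cigar is not None and "N" in self.cigar


@dataclass
class TranscriptModel:
    """Ordered exon chain on one contig strand.

    Exons are 0-based half-open genomic intervals, sorted by genomic start,
    non-overlapping. ``provenance`` records which platform called the model.
    """

    transcript_id: str
    contig_id: str
    strand: bool
    exons: list[tuple[int, int]]
    gene_id: str = ""
    support: int = 0
    provenance: str = "shortread"

    def __post_init__(self) -> None:
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        if not self.gene_id:
            self.gene_id = self.transcript_id

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def is_multi_exon(self) -> bool:
        return self.n_exons >= 2

    @property
    def spliced_length(self) -> int:
        return sum(b - a for a, b in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def junctions(self) -> list[tuple[int, int]]:
        """(donor_end, acceptor_start) pairs between consecutive exons."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    def spliced_sequence(self, genome: dict[str, str]) -> str:
        seq = "".join(genome[self.contig_id][a:b] for a, b in self.exons)
        if not self.strand:
            seq = reverse_complement(seq)
        return seq

    def genome_position(self, offset: int) -> int:
        """Map a cDNA offset (transcription order) to a genomic position."""
        if not 0 <= offset < self.spliced_length:
            raise IndexError(offset)
        if not self.strand:
            offset = self.spliced_length - 1 - offset
        for a, b in self.exons:
            if offset < b - a:
                return a + offset
            offset -= b - a
        raise AssertionError("unreachable")


_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seqs[rec.id] = str(rec.seq)
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GTF (dialect: transcript + exon features, gene_id/transcript_id attributes)

def write_gtf(models: Iterable[TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in models:
            strand = "+" if m.strand else "-"
            s, e = m.span
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            fh.write(
                f"{m.contig_id}\tfragtx\ttranscript\t{s + 1}\t{e}\t.\t{strand}\t.\t{attrs}\n"
            )
            for a, b in m.exons:
                fh.write(
                    f"{m.contig_id}\tfragtx\texon\t{a + 1}\t{b}\t.\t{strand}\t.\t{attrs}\n"
                )


_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    spans: dict[str, tuple[str, bool, int, int, str]] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF columns")
            contig, _src, feature, start, end, _score, strand, _frame, attr = f[:9]
            start_i, end_i = int(start) - 1, int(end)
            if start_i >= end_i:
                raise ValueError(f"{path}:{lineno}: start > end")
            attrs = dict(_ATTR_RE.findall(attr))
            tid = attrs.get("transcript_id", "")
            gid = attrs.get("gene_id", tid)
            fwd = strand != "-"
            if feature == "transcript":
                spans[tid] = (contig, fwd, start_i, end_i, gid)
                order.append(tid)
            elif feature == "exon":
                if tid not in exons:
                    exons[tid] = []
                    if tid not in spans:
                        order.append(tid)
                exons[tid].append((start_i, end_i))
                if tid in spans:
                    c, _, s, e, _ = spans[tid]
                    if start_i < s or end_i > e or contig != c:
                        raise ValueError(
                            f"{path}:{lineno}: exon outside transcript span of {tid}"
                        )
    models = []
    for tid in order:
        ex = sorted(exons.get(tid, []))
        if tid in spans:
            contig, fwd, s, e, gid = spans[tid]
        else:
            # exon-only transcript: infer span/strand from the exon lines
            raise ValueError(f"transcript {tid} has exon records but no transcript record")
        models.append(
            TranscriptModel(tid, contig, fwd, ex if ex else [(s, e)], gene_id=gid)
        )
    return models


# ---------------------------------------------------------------------------
# SAM-like alignment tables

_SAM_HEADER = "read_id\tmapped\tstrand\tcontig\tpos\tscore\tcigar\tsequence\tquality\tstatus\n"


def write_sam_like(records: Sequence[tuple[SamRecord, str]], path: str | Path) -> None:
    """Write (record, uniqueness_status) pairs as a tab table."""
    with open(path, "w") as fh:
        fh.write(_SAM_HEADER)
        for rec, status in records:
            fh.write(
                "\t".join(
                    [
                        rec.read_id,
                        "1" if rec.mapped else "0",
                        "+" if rec.strand else "-",
                        rec.contig_id or "*",
                        str(rec.pos) if rec.pos is not None else "*",
                        str(rec.mapping_score),
                        rec.cigar or "*",
                        rec.sequence,
                        f"{rec.read_quality:g}",
                        status,
                    ]
                )
                + "\n"
            )


def read_sam_like(path: str | Path) -> list[tuple[SamRecord, str]]:
    out: list[tuple[SamRecord, str]] = []
    with open(path) as fh:
        header = fh.readline()
        if header != _SAM_HEADER:
            raise ValueError(f"{path}: unexpected alignment-table header")
        for line in fh:
            (
                rid, mapped, strand, contig, pos, score, cigar, seq, qual, status,
            ) = line.rstrip("\n").split("\t")
            rec = SamRecord(
                read_id=rid,
                mapped=mapped == "1",
                strand=strand == "+",
                contig_id=None if contig == "*" else contig,
                pos=None if pos == "*" else int(pos),
                mapping_score=int(score),
                cigar=None if cigar == "*" else cigar,
                sequence=seq,
                read_quality=float(qual),
            )
            out.append((rec, status))
    return out


def write_tsv(rows: Iterable[Sequence], header: Sequence[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
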