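"""Seed-and-extend mapping of 50 bp reads to contigs and annotated cDNAs.

A read is first tried as a contiguous genome placement; failing that, as a
placement on annotated transcript (cDNA) sequences, which is projected back
to genome coordinates as a split (N-gapped) alignment; failing that it is
reported partial (>=30% of the read clipped) or unmapped. Partial and
unmapped reads form the candidate pool for super-gene rescue.

Scoring: +1 per match, -2 per mismatch, clipped bases 0. Uniqueness is
decided by counting distinct best-scoring loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_utils import (
    MULTI,
    PARTIAL,
    UNIQUE,
    UNMAPPED,
    SamRecord,
    TranscriptModel,
    reverse_complement,
)
from .synthetic import SimRead


@dataclass
class MappingParams:
    k: int = 16
    max_mismatches: int = 3
    min_mapping_score: int = 40
    min_read_quality: float = 0.5
    max_intron: int = 100_000
    partial_clip_fraction: float = 0.3
    min_anchor: int = 10  # matched bases required on each side of a junction


@dataclass
class SeedIndex:
    k: int
    seqs: dict[str, str]
    kmers: dict[str, list[tuple[str, int]]] = field(repr=False, default_factory=dict)


def build_index(seqs: dict[str, str], k: int) -> SeedIndex:
    """Exact k-mer position index over a set of sequences."""
    if k < 8:
        raise ValueError("k must be >= 8")
    if seqs and k > min(len(s) for s in seqs.values()):
        raise ValueError("k exceeds the shortest indexed sequence")
    kmers: dict[str, list[tuple[str, int]]] = {}
    for sid, seq in seqs.items():
        for i in range(len(seq) - k + 1):
            kmers.setdefault(seq[i : i + k], []).append((sid, i))
    return SeedIndex(k=k, seqs=seqs, kmers=kmers)


def _candidates(seq: str, index: SeedIndex) -> set[tuple[str, int]]:
    """Candidate (target_id, diagonal_start) pairs from 3 sampled seeds."""
    k = index.k
    L = len(seq)
    offsets = {0, max(0, (L - k) // 2), max(0, L - k)}
    cands: set[tuple[str, int]] = set()
    for off in offsets:
        for sid, pos in index.kmers.get(seq[off : off + k], ()):
            cands.add((sid, pos - off))
    return cands


def _score(matches: int, mismatches: int) -> int:
    return matches - 2 * mismatches


def _best_segment(
    mism: list[int], lo: int, hi: int, max_mm: int
) -> tuple[int, int, int, int] | None:
    """Maximal-scoring read segment within [lo, hi) holding <= max_mm
    mismatches; segment ends are trimmed to matching bases.

    Returns (l, r, mm, score) under +1 match / -2 mismatch scoring.
    """
    n = len(mism)
    best = None
    for i in range(0, n + 1):
        l = lo if i == 0 else mism[i - 1] + 1
        for j in range(i, min(i + max_mm, n) + 1):
            r = hi if j == n else mism[j]
            if r <= l:
                continue
            mm = j - i
            score = (r - l) - 3 * mm
            if best is None or score > best[3]:
                best = (l, r, mm, score)
    return best


def _placements(seq: str, index: SeedIndex, max_mm: int):
    """Best trimmed placement per candidate diagonal.

    Yields (score, sid, tstart, l, r, mm): read segment [l, r) aligned to
    the target starting at tstart, with mm interior mismatches.
    """
    L = len(seq)
    out = []
    for sid, diag in _candidates(seq, index):
        target = index.seqs[sid]
        lo = max(0, -diag)
        hi = min(L, len(target) - diag)
        if hi - lo < index.k:
            continue
        mism = [i for i in range(lo, hi) if seq[i] != target[diag + i]]
        seg = _best_segment(mism, lo, hi, max_mm)
        if seg is None:
            continue
        l, r, mm, score = seg
        out.append((score, sid, diag + l, l, r, mm))
    return out


def _full_placements(seq: str, index: SeedIndex, max_mm: int):
    """Placements covering the entire read (no clipping)."""
    L = len(seq)
    return [
        (sid, tstart, mm, score)
        for score, sid, tstart, l, r, mm in _placements(seq, index, max_mm)
        if l == 0 and r == L
    ]


def project_to_genome(
    model: TranscriptModel,
    cdna_start: int,
    cdna_end: int,
    read_id: str,
    sequence: str,
    mapping_score: int,
    read_quality: float,
    read_forward_on_cdna: bool = True,
) -> SamRecord:
    """Project a contiguous cDNA interval onto genome coordinates.

    The emitted record is on genome forward coordinates; M runs are split at
    exon boundaries with N gaps of the exact intron lengths. On a minus-
    strand transcript the genomic blocks are identical but the read strand
    flips.
    """
    if cdna_start < 0 or cdna_end > model.spliced_length or cdna_start >= cdna_end:
        raise ValueError("alignment crosses transcript end")
    positions = [model.genome_position(c) for c in range(cdna_start, cdna_end)]
    if not model.strand:
        positions.reverse()
    blocks: list[tuple[int, int]] = []
    for p in positions:
        if blocks and blocks[-1][1] == p:
            blocks[-1] = (blocks[-1][0], p + 1)
        else:
            blocks.append((p, p + 1))
    blocks = [tuple(b) for b in blocks]
    cig = []
    for i, (a, b) in enumerate(blocks):
        if i > 0:
            cig.append(f"{a - blocks[i - 1][1]}N")
        cig.append(f"{b - a}M")
    strand = model.strand if read_forward_on_cdna else not model.strand
    return SamRecord(
        read_id=read_id,
        mapped=True,
        strand=strand,
        contig_id=model.contig_id,
        pos=blocks[0][0],
        mapping_score=mapping_score,
        cigar="".join(cig),
        sequence=sequence,
        read_quality=read_quality,
    )


def map_read(
    read: SimRead,
    genome_index: SeedIndex,
    transcript_index: SeedIndex | None,
    transcript_models: dict[str, TranscriptModel] | None,
    params: MappingParams,
) -> tuple[SamRecord, str]:
    """Map one read; always returns a record with a uniqueness status."""
    seq = read.sequence
    L = len(seq)
    rc = reverse_complement(seq)
    max_clip = params.partial_clip_fraction * L

    # 1. genome placements (clip below the partial threshold counts as mapped)
    mapped = []  # (score, contig, tstart, l, r, fwd)
    partial = []
    for s, fwd in ((seq, True), (rc, False)):
        for score, sid, tstart, l, r, mm in _placements(
            s, genome_index, params.max_mismatches
        ):
            clip = L - (r - l)
            if clip < max_clip:
                mapped.append((score, sid, tstart, l, r, fwd))
            elif r - l >= genome_index.k:
                partial.append((score, sid, tstart, l, r, fwd))

    def clip_for_strand(l: int, r: int, fwd: bool) -> tuple[int, int]:
        # cigar is written in reference orientation: left clip precedes the
        # M segment along the reference
        return (l, L - r)

    # 2. transcript-space placements projected to the genome (full-length)
    projected: dict[tuple, SamRecord] = {}
    if not mapped and transcript_index is not None:
        for s, fwd in ((seq, True), (rc, False)):
            for tid, start, mm, score in _full_placements(
                s, transcript_index, params.max_mismatches
            ):
                model = transcript_models[tid]
                rec = project_to_genome(
                    model, start, start + L, read.read_id, seq,
                    score, read.read_quality, read_forward_on_cdna=fwd,
                )
                key = (score, rec.contig_id, rec.pos, rec.strand, rec.cigar)
                projected[key] = rec

    all_keys = set(projected)
    for score, sid, tstart, l, r, fwd in mapped:
        lc, rcl = clip_for_strand(l, r, fwd)
        cig = (f"{lc}S" if lc else "") + f"{r - l}M" + (f"{rcl}S" if rcl else "")
        all_keys.add((score, sid, tstart, fwd, cig))
    if all_keys:
        best_score = max(k[0] for k in all_keys)
        best = sorted(k for k in all_keys if k[0] == best_score)
        score, contig, pos, strand, cigar = best[0]
        rec = projected.get(
            best[0],
            SamRecord(
                read_id=read.read_id,
                mapped=True,
                strand=strand,
                contig_id=contig,
                pos=pos,
                mapping_score=score,
                cigar=cigar,
                sequence=seq,
                read_quality=read.read_quality,
            ),
        )
        status = UNIQUE if len(best) == 1 else MULTI
        return rec, status

    # 3. best partial placement (a candidate half of a split read)
    if partial:
        score, sid, tstart, l, r, fwd = max(partial, key=lambda p: p[0])
        lc, rcl = clip_for_strand(l, r, fwd)
        cig = (f"{lc}S" if lc else "") + f"{r - l}M" + (f"{rcl}S" if rcl else "")
        rec = SamRecord(
            read_id=read.read_id,
            mapped=True,
            strand=fwd,
            contig_id=sid,
            pos=tstart,
            mapping_score=score,
            cigar=cig,
            sequence=seq,
            read_quality=read.read_quality,
        )
        return rec, PARTIAL

    rec = SamRecord(
        read_id=read.read_id,
        mapped=False,
        strand=True,
        contig_id=None,
        pos=None,
        mapping_score=0,
        cigar=None,
        sequence=seq,
        read_quality=read.read_quality,
    )
    return rec, UNMAPPED


def map_reads(
    reads,
    genome: dict[str, str],
    params: MappingParams,
    annotation: list[TranscriptModel] | None = None,
) -> list[tuple[SamRecord, str]]:
    """Map a collection of reads; builds the indices once."""
    genome_index = build_index(genome, params.k)
    transcript_index = None
    models = None
    if annotation:
        models = {m.transcript_id: m for m in annotation}
        cdna = {
            tid: m.spliced_sequence(genome)
            for tid, m in models.items()
            if m.spliced_length >= params.k
        }
        transcript_index = build_index(cdna, params.k)
    return [
        map_read(r, genome_index, transcript_index, models, params) for r in reads
    ]


def quality_filter(
    alignments: list[tuple[SamRecord, str]], params: MappingParams
) -> list[tuple[SamRecord, str]]:
    """Keep mapped records passing both scalar quality and score thresholds."""
    return [
        (rec, status)
        for rec, status in alignments
        if rec.mapped
        and rec.read_quality >= params.min_read_quality
        and rec.mapping_score >= params.min_mapping_score
    ]
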