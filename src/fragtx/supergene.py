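"""Super-gene construction and iterative split-read rescue.

All assembled exons on one strand of one contig are laced together into a
single "super-gene" cDNA with a bijective cDNA<->genome coordinate map.
High-quality reads that previously failed to map, or mapped only partially
(a clipped CIGAR suggestive of one half of a split read), are remapped
contiguously against the super-gene cDNAs; placements straddling two or
more exon blocks project back to the genome as new N-gapped split
alignments, which are merged into the alignment set before re-assembly.

Junctions are only ever emitted between distinct exon blocks of one
super-gene, never within a block and never between contigs (splice events
between contigs are an acknowledged blind spot on fragmented assemblies).
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

from .assembly import AssemblyParams, annotate_counts, assemble
from .io_utils import (
    PARTIAL,
    UNIQUE,
    UNMAPPED,
    SamRecord,
    TranscriptModel,
    reverse_complement,
)
from .mapping import MappingParams, _full_placements, build_index, quality_filter


@dataclass
class SuperGene:
    supergene_id: str
    contig_id: str
    strand: bool
    blocks: list[tuple[int, int]]  # sorted, disjoint genomic intervals
    cdna_sequence: str
    _cumlen: list[int] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self._cumlen = [0]
        for a, b in self.blocks:
            self._cumlen.append(self._cumlen[-1] + (b - a))

    @property
    def length(self) -> int:
        return self._cumlen[-1]

    def genome_position(self, offset: int) -> int:
        """Map a cDNA offset (transcription order) to a genomic position."""
        if not 0 <= offset < self.length:
            raise IndexError(offset)
        if not self.strand:
            offset = self.length - 1 - offset
        i = bisect_right(self._cumlen, offset) - 1
        return self.blocks[i][0] + (offset - self._cumlen[i])

    def cdna_offset(self, genome_pos: int) -> int:
        """Inverse of :meth:`genome_position` (bijection over covered bases)."""
        for i, (a, b) in enumerate(self.blocks):
            if a <= genome_pos < b:
                off = self._cumlen[i] + (genome_pos - a)
                return off if self.strand else self.length - 1 - off
        raise IndexError(genome_pos)

    def project(self, cdna_start: int, cdna_end: int) -> list[tuple[int, int]]:
        """Genomic blocks (ascending) covered by a cDNA interval."""
        if cdna_start < 0 or cdna_end > self.length or cdna_start >= cdna_end:
            raise ValueError("interval outside super-gene cDNA")
        if self.strand:
            lo, hi = cdna_start, cdna_end
        else:
            lo, hi = self.length - cdna_end, self.length - cdna_start
        out = []
        for i, (a, b) in enumerate(self.blocks):
            s = max(lo, self._cumlen[i])
            e = min(hi, self._cumlen[i + 1])
            if s < e:
                out.append((a + s - self._cumlen[i], a + e - self._cumlen[i]))
        return out


def build_supergenes(
    models: list[TranscriptModel], genome: dict[str, str]
) -> list[SuperGene]:
    """Union the exons of all models per contig strand into super-genes."""
    pooled: dict[tuple[str, bool], list[tuple[int, int]]] = {}
    for m in models:
        if m.contig_id not in genome:
            raise KeyError(f"model {m.transcript_id} references unknown contig {m.contig_id}")
        pooled.setdefault((m.contig_id, m.strand), []).extend(m.exons)
    out = []
    for (contig, strand), exons in sorted(pooled.items()):
        exons.sort()
        blocks: list[tuple[int, int]] = []
        for a, b in exons:
            if blocks and a <= blocks[-1][1]:
                blocks[-1] = (blocks[-1][0], max(blocks[-1][1], b))
            else:
                blocks.append((a, b))
        cdna = "".join(genome[contig][a:b] for a, b in blocks)
        if not strand:
            cdna = reverse_complement(cdna)
        out.append(
            SuperGene(
                supergene_id=f"SG.{contig}.{'+' if strand else '-'}",
                contig_id=contig,
                strand=strand,
                blocks=blocks,
                cdna_sequence=cdna,
            )
        )
    return out


def select_rescue_candidates(
    alignments: list[tuple[SamRecord, str]], params: MappingParams
) -> list[SamRecord]:
    """High-quality reads that are unmapped or partial; never fully mapped."""
    return [
        rec
        for rec, status in alignments
        if status in (UNMAPPED, PARTIAL)
        and rec.read_quality >= params.min_read_quality
    ]


def rescue_split_reads(
    candidates: list[SamRecord],
    supergenes: list[SuperGene],
    params: MappingParams,
) -> list[tuple[SamRecord, str]]:
    """Remap candidates against super-gene cDNAs and project the hits.

    A candidate that places contiguously and uniquely on one super-gene
    cDNA is projected through the coordinate map; if the projection spans
    two or more blocks with at least ``min_anchor`` matched bases beyond
    each junction it becomes a new genome-space split alignment, otherwise
    a plain alignment within one block.
    """
    by_id = {sg.supergene_id: sg for sg in supergenes}
    cdna = {
        sid: sg.cdna_sequence for sid, sg in by_id.items() if sg.length >= params.k
    }
    if not cdna:
        return []
    index = build_index(cdna, params.k)
    out: list[tuple[SamRecord, str]] = []
    for rec in candidates:
        seq = rec.sequence
        L = len(seq)
        hits = []
        for s, fwd in ((seq, True), (reverse_complement(seq), False)):
            for sid, start, mm, score in _full_placements(
                s, index, params.max_mismatches
            ):
                hits.append((score, sid, start, fwd))
        if not hits:
            continue
        best_score = max(h[0] for h in hits)
        best = sorted(set(h for h in hits if h[0] == best_score))
        if len(best) != 1:
            continue  # ambiguous rescue placements are not trusted
        score, sid, start, fwd = best[0]
        sg = by_id[sid]
        blocks = sg.project(start, start + L)
        if any(b - a < params.min_anchor for a, b in blocks):
            continue
        cig = []
        for i, (a, b) in enumerate(blocks):
            if i > 0:
                gap = a - blocks[i - 1][1]
                if gap > params.max_intron:
                    cig = None
                    break
                cig.append(f"{gap}N")
            cig.append(f"{b - a}M")
        if cig is None:
            continue
        strand = sg.strand if fwd else not sg.strand
        out.append(
            (
                SamRecord(
                    read_id=rec.read_id,
                    mapped=True,
                    strand=strand,
                    contig_id=sg.contig_id,
                    pos=blocks[0][0],
                    mapping_score=score,
                    cigar="".join(cig),
                    sequence=seq,
                    read_quality=rec.read_quality,
                ),
                UNIQUE,
            )
        )
    return out


def merge_alignments(
    original: list[tuple[SamRecord, str]],
    rescued: list[tuple[SamRecord, str]],
) -> list[tuple[SamRecord, str]]:
    """Union of the original set and rescued placements, by read id.

    A read present in both keeps the rescued split placement; an equal-score
    non-split conflict keeps the original.
    """
    rescued_by_id = {rec.read_id: (rec, st) for rec, st in rescued}
    out: list[tuple[SamRecord, str]] = []
    seen: set[str] = set()
    for rec, status in original:
        repl = rescued_by_id.get(rec.read_id)
        if repl is not None and (repl[0].is_split or repl[0].mapping_score > rec.mapping_score):
            out.append(repl)
        else:
            out.append((rec, status))
        seen.add(rec.read_id)
    for rid, pair in rescued_by_id.items():
        if rid not in seen:
            out.append(pair)
    return out


def _junction_set(models: list[TranscriptModel]) -> set[tuple[str, bool, int, int]]:
    out = set()
    for m in models:
        for d, a in m.junctions():
            out.add((m.contig_id, m.strand, d, a))
    return out


def iterate_rescue(
    alignments: list[tuple[SamRecord, str]],
    genome: dict[str, str],
    mapping_params: MappingParams,
    assembly_params: AssemblyParams,
    max_rounds: int = 1,
) -> tuple[list[TranscriptModel], list[tuple[SamRecord, str]], list[dict]]:
    """[assemble -> super-genes -> rescue -> merge -> re-assemble] loop.

    Stops after ``max_rounds`` rescue rounds or at the fixed point where a
    round contributes no new junction. Returns the final models, the final
    alignment set, and a per-round ledger of junction / model counts.
    """
    if max_rounds < 1:
        raise ValueError("max_rounds must be >= 1")
    filtered = quality_filter(alignments, mapping_params)
    models = assemble(filtered, genome, assembly_params, id_prefix="R0")
    ledger = [
        {
            "round": 0,
            "n_junctions": len(_junction_set(models)),
            "n_new_split_reads": 0,
            **annotate_counts(models),
        }
    ]
    for rnd in range(1, max_rounds + 1):
        supergenes = build_supergenes(models, genome)
        candidates = select_rescue_candidates(alignments, mapping_params)
        rescued = rescue_split_reads(candidates, supergenes, mapping_params)
        prev_junctions = _junction_set(models)
        alignments = merge_alignments(alignments, rescued)
        filtered = quality_filter(alignments, mapping_params)
        new_models = assemble(filtered, genome, assembly_params, id_prefix=f"R{rnd}")
        new_junctions = _junction_set(new_models)
        models = new_models
        ledger.append(
            {
                "round": rnd,
                "n_junctions": len(new_junctions),
                "n_new_split_reads": len(rescued),
                **annotate_counts(models),
            }
        )
        if not (new_junctions - prev_junctions):
            break
    return models, alignments, ledger
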