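"""Assembly of mapped short reads into transcript models.

Coverage islands of uniquely-mapped high-quality reads become candidate
exons; split (N-gapped) alignments define junctions; junction-consistent
paths through the island graph become multi-exon models, with the support
filters of the reference-guided assembler this stands in for: a minimum of
2 unique reads per transcribed region, a junction kept only if its support
is at least ``junction_fraction`` of the best junction sharing a splice
site, and isoform paths pruned below ``isoform_fraction`` of the locus
maximum.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .io_utils import UNIQUE, SamRecord, TranscriptModel


@dataclass
class AssemblyParams:
    min_unique_reads: int = 2
    isoform_fraction: float = 0.3
    junction_fraction: float = 0.1
    pre_mrna_fraction: float = 0.0
    max_intron: int = 100_000

    def __post_init__(self) -> None:
        for name in ("isoform_fraction", "junction_fraction", "pre_mrna_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class Island:
    start: int
    end: int
    support: int


def coverage_islands(
    alignments: list[SamRecord],
    contig_id: str,
    strand: bool,
    contig_length: int,
    params: AssemblyParams,
) -> list[Island]:
    """Maximal intervals with per-base coverage >= 1 and enough reads.

    ``alignments`` must already be the uniquely-mapped, quality-filtered
    set; islands supported by fewer than ``min_unique_reads`` reads are
    discarded.
    """
    cov = np.zeros(contig_length + 1, dtype=np.int32)
    spans = []
    for rec in alignments:
        if rec.contig_id != contig_id or rec.strand != strand:
            continue
        blocks = rec.blocks()
        if not blocks:
            continue
        for a, b in blocks:
            cov[a] += 1
            cov[b] -= 1
        spans.append((blocks[0][0], blocks[-1][1]))
    cov = np.cumsum(cov)[:-1]
    covered = cov > 0
    if not covered.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], covered.view(np.int8), [0]))))
    islands = []
    spans.sort()
    starts = np.array([s for s, _ in spans])
    ends = np.array([e for _, e in spans])
    for a, b in zip(edges[::2], edges[1::2]):
        support = int(np.sum((starts < b) & (ends > a)))
        if support >= params.min_unique_reads:
            islands.append(Island(int(a), int(b), support))
    return islands


def junction_graph(
    split_alignments: list[SamRecord], params: AssemblyParams
) -> dict[tuple[str, bool, int, int], int]:
    """Count split-read junctions and apply the shared-site support filter."""
    support: dict[tuple[str, bool, int, int], int] = {}
    for rec in split_alignments:
        blocks = rec.blocks()
        for i in range(len(blocks) - 1):
            donor, acceptor = blocks[i][1], blocks[i + 1][0]
            if acceptor - donor > params.max_intron:
                continue
            key = (rec.contig_id, rec.strand, donor, acceptor)
            support[key] = support.get(key, 0) + 1
    if not support:
        return {}
    by_donor: dict[tuple, int] = {}
    by_acceptor: dict[tuple, int] = {}
    for (c, s, d, a), n in support.items():
        by_donor[(c, s, d)] = max(by_donor.get((c, s, d), 0), n)
        by_acceptor[(c, s, a)] = max(by_acceptor.get((c, s, a), 0), n)
    kept = {}
    for (c, s, d, a), n in support.items():
        best = max(by_donor[(c, s, d)], by_acceptor[(c, s, a)])
        if n >= params.junction_fraction * best:
            kept[(c, s, d, a)] = n
    return kept


def _paths_through(
    islands: list[Island],
    edges: dict[int, list[tuple[int, int, int, int]]],
    start_nodes: list[int],
    max_paths: int = 200,
):
    """Enumerate junction-consistent paths (greedy, highest support first)."""
    paths = []
    stack = [((i,), ()) for i in reversed(start_nodes)]
    while stack and len(paths) < max_paths:
        nodes, cuts = stack.pop()
        outs = edges.get(nodes[-1], [])
        if not outs:
            paths.append((nodes, cuts))
            continue
        for j, sup, d, a in sorted(outs, key=lambda e: -e[1]):
            stack.append((nodes + (j,), cuts + ((d, a, sup),)))
    return paths


def call_transcripts(
    islands_by_key: dict[tuple[str, bool], list[Island]],
    junctions: dict[tuple[str, bool, int, int], int],
    params: AssemblyParams,
    id_prefix: str = "STX",
) -> list[TranscriptModel]:
    """Chain islands through retained junctions into transcript models."""
    models: list[TranscriptModel] = []
    counter = itertools.count(1)
    ignored: list[tuple] = []
    for (contig, strand), islands in sorted(islands_by_key.items()):
        islands = sorted(islands, key=lambda i: i.start)
        # junction endpoints -> island indices
        def find(pos: int) -> int | None:
            for idx, isl in enumerate(islands):
                if isl.start <= pos <= isl.end:
                    return idx
            return None

        edges: dict[int, list[tuple[int, int, int, int]]] = {}
        has_in: set[int] = set()
        linked: set[int] = set()
        for (c, s, d, a), sup in sorted(junctions.items()):
            if c != contig or s != strand:
                continue
            i1, i2 = find(d), find(a)
            if i1 is None or i2 is None or i1 >= i2:
                ignored.append((c, s, d, a))
                continue
            edges.setdefault(i1, []).append((i2, sup, d, a))
            has_in.add(i2)
            linked.update((i1, i2))
        # connected components over linked islands define loci
        parent = list(range(len(islands)))

        def root(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i1, outs in edges.items():
            for i2, *_ in outs:
                parent[root(i1)] = root(i2)
        start_nodes = [i for i in range(len(islands)) if i in linked and i not in has_in]
        paths = _paths_through(islands, edges, start_nodes)
        multi = [(n, c) for n, c in paths if len(n) >= 2]
        locus_max: dict[int, int] = {}
        for nodes, cuts in multi:
            r = root(nodes[0])
            sup = min(s for _, _, s in cuts)
            locus_max[r] = max(locus_max.get(r, 0), sup)
        seen: set[tuple] = set()
        for nodes, cuts in multi:
            path_support = min(sup for _, _, sup in cuts)
            if path_support < params.isoform_fraction * locus_max[root(nodes[0])]:
                continue
            exons = []
            for idx, node in enumerate(nodes):
                isl = islands[node]
                a = cuts[idx - 1][1] if idx > 0 else isl.start
                b = cuts[idx][0] if idx < len(cuts) else isl.end
                if a >= b:
                    break
                exons.append((a, b))
            else:
                key = tuple(exons)
                if key in seen:
                    continue
                seen.add(key)
                models.append(
                    TranscriptModel(
                        transcript_id=f"{id_prefix}.{next(counter):05d}",
                        contig_id=contig,
                        strand=strand,
                        exons=exons,
                        support=path_support,
                        provenance="shortread",
                    )
                )
        for idx, isl in enumerate(islands):
            if idx in linked:
                continue
            models.append(
                TranscriptModel(
                    transcript_id=f"{id_prefix}.{next(counter):05d}",
                    contig_id=contig,
                    strand=strand,
                    exons=[(isl.start, isl.end)],
                    support=isl.support,
                    provenance="shortread",
                )
            )
    return models


def assemble(
    alignments: list[tuple[SamRecord, str]],
    genome: dict[str, str],
    params: AssemblyParams,
    id_prefix: str = "STX",
) -> list[TranscriptModel]:
    """Full short-read assembly from filtered alignments.

    Only uniquely-mapped records contribute coverage and junction support;
    multi-mapped records are retained in files but excluded here.
    """
    unique = [rec for rec, status in alignments if status == UNIQUE]
    keys = sorted({(r.contig_id, r.strand) for r in unique})
    islands_by_key = {}
    for contig, strand in keys:
        isl = coverage_islands(
            unique, contig, strand, len(genome[contig]), params
        )
        if isl:
            islands_by_key[(contig, strand)] = isl
    junctions = junction_graph([r for r in unique if r.is_split], params)
    return call_transcripts(islands_by_key, junctions, params, id_prefix)


def annotate_counts(models: list[TranscriptModel]) -> dict[str, float]:
    """Summary: multi/single-exon counts and mean spliced length."""
    n_multi = sum(1 for m in models if m.is_multi_exon)
    n_single = len(models) - n_multi
    mean_len = (
        float(np.mean([m.spliced_length for m in models])) if models else 0.0
    )
    return {
        "n_multi_exon": n_multi,
        "n_single_exon": n_single,
        "mean_length": mean_len,
    }
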