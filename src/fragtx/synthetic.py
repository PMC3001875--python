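"""Synthetic genomes, gene models, reads and expression with known truth.

The generator emulates the study system the pipeline is built for: a genome
fragmented into thousands of short contigs with A/T-rich composition
(default 65% A+T), multi-exon genes with cassette isoforms, single-exon
genes, intronless pseudogene-like duplicates that attract short reads but
carry no expression, long cDNA reads with a ~278 bp mean length, and
strand-specific 50 bp short reads over two replicated conditions in which a
designated gene subset is depleted (the irradiation contrast).

Every generator is deterministic given its arguments and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io_utils import TranscriptModel, reverse_complement, write_gtf

BASES = np.array(list("ACGT"))


class ParameterError(ValueError):
    pass


class PlacementError(RuntimeError):
    pass


@dataclass
class GenomeParams:
    n_contigs: int = 50
    contig_length_range: tuple[int, int] = (5_000, 20_000)
    at_fraction: float = 0.65
    repeat_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_contigs < 0:
            raise ParameterError("n_contigs must be >= 0")
        if not 0.0 <= self.at_fraction <= 1.0:
            raise ParameterError("at_fraction must lie in [0, 1]")
        if not 0.0 <= self.repeat_fraction < 1.0:
            raise ParameterError("repeat_fraction must lie in [0, 1)")
        lo, hi = self.contig_length_range
        if lo <= 0 or hi < lo:
            raise ParameterError("invalid contig_length_range")


@dataclass
class GenomeSet:
    """Contig sequences plus (once annotated) ground-truth gene models."""

    contigs: dict[str, str]
    params: GenomeParams | None = None
    genes: list["GeneTruth"] = field(default_factory=list)

    def contig_length(self, contig_id: str) -> int:
        return len(self.contigs[contig_id])


@dataclass
class GeneTruth:
    gene_id: str
    contig_id: str
    strand: bool
    exons: list[tuple[int, int]]
    isoforms: list[list[int]]  # exon-index subsets, transcription order kept
    is_single_exon: bool
    is_pseudogene_copy: bool
    baseline_expression: float

    def isoform_ids(self) -> list[str]:
        return [f"{self.gene_id}.i{j + 1}" for j in range(len(self.isoforms))]

    def isoform_exons(self, j: int) -> list[tuple[int, int]]:
        return [self.exons[i] for i in self.isoforms[j]]

    def isoform_model(self, j: int) -> TranscriptModel:
        return TranscriptModel(
            transcript_id=self.isoform_ids()[j],
            contig_id=self.contig_id,
            strand=self.strand,
            exons=self.isoform_exons(j),
            gene_id=self.gene_id,
            provenance="truth",
        )

    def junctions(self) -> set[tuple[str, bool, int, int]]:
        out = set()
        for j in range(len(self.isoforms)):
            for d, a in self.isoform_model(j).junctions():
                out.add((self.contig_id, self.strand, d, a))
        return out


@dataclass
class SimRead:
    read_id: str
    sequence: str
    gene_id: str  # "intergenic" for background reads
    isoform_id: str
    offset: int  # start offset on the spliced isoform
    read_quality: float = 1.0


@dataclass
class ReadSet:
    platform: str  # "long" | "short"
    reads: list[SimRead]

    def __len__(self) -> int:
        return len(self.reads)


@dataclass
class ExpressionTruth:
    """Per-gene baseline rates and per-condition multipliers."""

    baseline: dict[str, float]
    multipliers: dict[str, dict[str, float]]  # condition -> gene -> multiplier
    replicates: dict[str, int]

    def rate(self, gene_id: str, condition: str) -> float:
        return self.baseline[gene_id] * self.multipliers[condition].get(gene_id, 1.0)


# ---------------------------------------------------------------------------


def generate_genome(params: GenomeParams) -> GenomeSet:
    """Draw random contigs at the requested A+T fraction.

    When ``repeat_fraction > 0`` a shared pool of repeat elements is spliced
    into every contig so that a fraction of bases is common across contigs.
    """
    rng = np.random.default_rng(params.seed)
    at = params.at_fraction
    probs = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])

    def draw(n: int) -> str:
        return "".join(BASES[rng.choice(4, size=n, p=probs)])

    pool = [draw(500) for _ in range(10)] if params.repeat_fraction > 0 else []
    contigs: dict[str, str] = {}
    lo, hi = params.contig_length_range
    for i in range(params.n_contigs):
        length = int(rng.integers(lo, hi + 1))
        seq = draw(length)
        if pool:
            n_repeat_bases = int(params.repeat_fraction * length)
            placed = 0
            seq_l = list(seq)
            while placed < n_repeat_bases:
                elem = pool[rng.integers(len(pool))]
                take = min(len(elem), n_repeat_bases - placed)
                start = int(rng.integers(0, length - take + 1))
                seq_l[start : start + take] = elem[:take]
                placed += take
            seq = "".join(seq_l)
        contigs[f"contig{i + 1:05d}"] = seq
    return GenomeSet(contigs=contigs, params=params)


def _place_interval(
    occupied: dict[str, list[tuple[int, int]]],
    genome: GenomeSet,
    length: int,
    rng: np.random.Generator,
    gap: int = 100,
) -> tuple[str, bool, int]:
    """Find a free slot of ``length`` bp on a random contig.

    Loci never overlap, not even across strands, so intron interiors stay
    free of foreign exons and their edge bases may be adjusted.
    """
    contig_ids = list(genome.contigs)
    order = rng.permutation(len(contig_ids))
    strand = bool(rng.integers(2))
    last = contig_ids[0] if contig_ids else "?"
    for idx in order:
        cid = contig_ids[idx]
        last = cid
        clen = len(genome.contigs[cid])
        if clen < length + 2 * gap:
            continue
        taken = sorted(occupied.get(cid, []))
        # free gaps between taken intervals
        cursor = gap
        slots = []
        for a, b in taken:
            if a - cursor >= length + gap:
                slots.append((cursor, a - gap))
            cursor = max(cursor, b + gap)
        if clen - gap - cursor >= length:
            slots.append((cursor, clen - gap))
        if not slots:
            continue
        a, b = slots[int(rng.integers(len(slots)))]
        start = int(rng.integers(a, b - length + 1))
        occupied.setdefault(cid, []).append((start, start + length))
        return cid, strand, start
    raise PlacementError(
        f"no contig has {length} bp of free space (last tried: {last})"
    )


def generate_gene_models(
    genome: GenomeSet,
    n_genes: int,
    exon_count_range: tuple[int, int] = (2, 6),
    isoform_prob: float = 0.3,
    single_exon_fraction: float = 0.2,
    pseudogene_fraction: float = 0.1,
    exon_length_range: tuple[int, int] = (100, 300),
    intron_length_range: tuple[int, int] = (100, 600),
    seed: int = 0,
    gtf_path=None,
) -> list[GeneTruth]:
    """Place non-overlapping gene models and attach expression baselines.

    Pseudogene copies are intronless duplicates (1-3% mutated) of a real
    gene's spliced sequence written into free genomic space; they carry zero
    expression but attract short reads, reproducing the single-exon
    confounder the merge rules exist to remove.
    """
    if n_genes > 0 and not genome.contigs:
        raise ParameterError("cannot place genes on an empty genome")
    rng = np.random.default_rng(seed)
    n_single = int(round(single_exon_fraction * n_genes))
    n_pseudo = int(round(pseudogene_fraction * n_genes))
    n_multi = n_genes - n_single - n_pseudo
    if n_multi < 0:
        raise ParameterError("single_exon_fraction + pseudogene_fraction > 1")

    occupied: dict[str, list[tuple[int, int]]] = {}
    genes: list[GeneTruth] = []

    def disambiguate_junctions(cid: str, exons: list[tuple[int, int]]) -> None:
        """Make splice sites locally unambiguous.

        Real aligners place junctions uniquely thanks to the GT-AG intron
        motif; here the equivalent constraint is that the first intron base
        differs from the first base of the next exon and the last intron
        base differs from the last base of the previous exon, so a junction
        cannot slide along identical flanking bases.
        """
        seq = list(genome.contigs[cid])
        for (a1, b1), (a2, b2) in zip(exons, exons[1:]):
            if seq[b1] == seq[a2]:
                seq[b1] = str(rng.choice([b for b in "ACGT" if b != seq[a2]]))
            if seq[a2 - 1] == seq[b1 - 1]:
                seq[a2 - 1] = str(
                    rng.choice([b for b in "ACGT" if b != seq[b1 - 1]])
                )
        genome.contigs[cid] = "".join(seq)

    def rates(n):
        return 10 ** rng.uniform(0, 3, size=n)  # log-uniform over [1, 1e3]

    multi_rates = rates(n_multi)
    single_rates = rates(n_single)
    for g in range(n_multi):
        n_ex = int(rng.integers(exon_count_range[0], exon_count_range[1] + 1))
        ex_lens = rng.integers(*exon_length_range, size=n_ex, endpoint=True)
        in_lens = rng.integers(*intron_length_range, size=n_ex - 1, endpoint=True)
        total = int(ex_lens.sum() + in_lens.sum())
        cid, strand, start = _place_interval(occupied, genome, total, rng)
        exons = []
        pos = start
        for i in range(n_ex):
            exons.append((pos, pos + int(ex_lens[i])))
            pos += int(ex_lens[i])
            if i < n_ex - 1:
                pos += int(in_lens[i])
        disambiguate_junctions(cid, exons)
        isoforms = [list(range(n_ex))]
        if n_ex >= 3 and rng.random() < isoform_prob:
            skip = int(rng.integers(1, n_ex - 1))  # internal cassette exon
            isoforms.append([i for i in range(n_ex) if i != skip])
        genes.append(
            GeneTruth(
                gene_id=f"gene{g + 1:04d}",
                contig_id=cid,
                strand=strand,
                exons=exons,
                isoforms=isoforms,
                is_single_exon=False,
                is_pseudogene_copy=False,
                baseline_expression=float(multi_rates[g]) if n_multi else 0.0,
            )
        )
    for s in range(n_single):
        length = int(rng.integers(*exon_length_range, endpoint=True) * 2)
        cid, strand, start = _place_interval(occupied, genome, length, rng)
        genes.append(
            GeneTruth(
                gene_id=f"gene{n_multi + s + 1:04d}",
                contig_id=cid,
                strand=strand,
                exons=[(start, start + length)],
                isoforms=[[0]],
                is_single_exon=True,
                is_pseudogene_copy=False,
                baseline_expression=float(single_rates[s]),
            )
        )
    # pseudogene copies: overwrite genome bases with a mutated spliced copy
    sources = [g for g in genes if not g.is_pseudogene_copy]
    for p in range(n_pseudo):
        src = sources[int(rng.integers(len(sources)))]
        spliced = src.isoform_model(0).spliced_sequence(genome.contigs)
        mut_rate = rng.uniform(0.01, 0.03)
        seq = list(spliced)
        n_mut = rng.binomial(len(seq), mut_rate)
        for i in rng.choice(len(seq), size=n_mut, replace=False):
            cur = seq[i]
            seq[i] = str(rng.choice([b for b in "ACGT" if b != cur]))
        dup = "".join(seq)
        cid, strand, start = _place_interval(occupied, genome, len(dup), rng)
        placed = dup if strand else reverse_complement(dup)
        contig = genome.contigs[cid]
        genome.contigs[cid] = contig[:start] + placed + contig[start + len(dup):]
        genes.append(
            GeneTruth(
                gene_id=f"pseudo{p + 1:04d}",
                contig_id=cid,
                strand=strand,
                exons=[(start, start + len(dup))],
                isoforms=[[0]],
                is_single_exon=True,
                is_pseudogene_copy=True,
                baseline_expression=0.0,
            )
        )
    genome.genes = genes
    if gtf_path is not None:
        write_truth_gtf(genes, gtf_path)
    return genes


def write_truth_gtf(genes: list[GeneTruth], path) -> None:
    models = []
    for g in genes:
        for j in range(len(g.isoforms)):
            models.append(g.isoform_model(j))
    write_gtf(models, path)


def default_expression_truth(
    genes: list[GeneTruth],
    conditions: tuple[str, ...] = ("intact", "irradiated"),
    n_replicates: int = 2,
) -> ExpressionTruth:
    return ExpressionTruth(
        baseline={g.gene_id: g.baseline_expression for g in genes},
        multipliers={c: {} for c in conditions},
        replicates={c: n_replicates for c in conditions},
    )


def apply_irradiation_effect(
    truth: ExpressionTruth,
    depleted_gene_ids: list[str],
    fold: float,
    condition: str = "irradiated",
) -> ExpressionTruth:
    """Divide the multipliers of the listed genes by ``fold`` in one condition."""
    if fold <= 1:
        raise ParameterError("fold must be > 1")
    unknown = [g for g in depleted_gene_ids if g not in truth.baseline]
    if unknown:
        raise KeyError(f"unknown gene ids: {', '.join(sorted(unknown))}")
    mult = truth.multipliers[condition]
    for g in depleted_gene_ids:
        mult[g] = mult.get(g, 1.0) / fold
    return truth


# ---------------------------------------------------------------------------
# read simulation


def _expressed_isoforms(genes, genome, condition=None, truth=None):
    """(isoform_id, gene_id, spliced_seq, weight) for isoforms with rate > 0."""
    out = []
    for g in genes:
        rate = g.baseline_expression
        if truth is not None and condition is not None:
            rate = truth.rate(g.gene_id, condition)
        if rate <= 0:
            continue
        share = rate / len(g.isoforms)
        for j, iso_id in enumerate(g.isoform_ids()):
            seq = g.isoform_model(j).spliced_sequence(genome.contigs)
            out.append((iso_id, g.gene_id, seq, share))
    return out


def _mutate(seq: str, error_rate: float, rng) -> str:
    if error_rate <= 0:
        return seq
    out = []
    for ch in seq:
        r = rng.random()
        if r < error_rate * 0.8:  # substitution
            out.append(str(rng.choice([b for b in "ACGT" if b != ch])))
        elif r < error_rate * 0.9:  # deletion
            continue
        elif r < error_rate:  # insertion
            out.append(ch)
            out.append(str(BASES[rng.integers(4)]))
        else:
            out.append(ch)
    return "".join(out)


def simulate_long_reads(
    genome: GenomeSet,
    n_reads: int,
    mean_length: float = 278.0,
    error_rate: float = 0.0,
    seed: int = 0,
    min_length: int = 40,
) -> ReadSet:
    """Draw long cDNA reads from spliced isoform sequences.

    Lengths follow a lognormal whose mean matches ``mean_length``, truncated
    to the isoform length, emulating the right-skewed length profile of
    long-read transcriptome sequencing.
    """
    rng = np.random.default_rng(seed)
    isoforms = _expressed_isoforms(genome.genes, genome)
    if n_reads > 0 and not isoforms:
        raise ParameterError("no expressed isoform to sample long reads from")
    reads: list[SimRead] = []
    if n_reads == 0:
        return ReadSet(platform="long", reads=reads)
    weights = np.array([w * len(s) for _, _, s, w in isoforms], dtype=float)
    weights /= weights.sum()
    sigma = 0.45
    mu = math.log(mean_length) - sigma**2 / 2
    picks = rng.choice(len(isoforms), size=n_reads, p=weights)
    for i, pick in enumerate(picks):
        iso_id, gene_id, seq, _ = isoforms[pick]
        length = int(round(rng.lognormal(mu, sigma)))
        length = max(min_length, min(length, len(seq)))
        start = int(rng.integers(0, len(seq) - length + 1))
        frag = seq[start : start + length]
        frag = _mutate(frag, error_rate, rng)
        reads.append(
            SimRead(
                read_id=f"L{i + 1:06d}",
                sequence=frag,
                gene_id=gene_id,
                isoform_id=iso_id,
                offset=start,
                read_quality=1.0,
            )
        )
    return ReadSet(platform="long", reads=reads)


def simulate_short_reads(
    genome: GenomeSet,
    truth: ExpressionTruth,
    n_reads_per_sample: int,
    seed: int = 0,
    error_rate: float = 0.0,
    read_length: int = 50,
    low_quality_fraction: float = 0.05,
) -> dict[str, ReadSet]:
    """Strand-specific 50 bp reads for every (condition, replicate) sample.

    Per-sample read counts per isoform are multinomial in expression rate x
    effective spliced length. Reads carry the sense-strand sequence. A small
    fraction is tagged with low scalar quality to exercise quality filters.
    """
    for cond, mult in truth.multipliers.items():
        if any(m < 0 for m in mult.values()):
            raise ParameterError(f"negative multiplier in condition {cond!r}")
    rng = np.random.default_rng(seed)
    samples: dict[str, ReadSet] = {}
    for cond in truth.multipliers:
        for rep in range(1, truth.replicates[cond] + 1):
            sample_id = f"{cond}_{rep}"
            isoforms = _expressed_isoforms(genome.genes, genome, cond, truth)
            usable = [
                (iso, gid, seq, w)
                for iso, gid, seq, w in isoforms
                if len(seq) >= read_length
            ]
            reads: list[SimRead] = []
            if usable and n_reads_per_sample > 0:
                weights = np.array(
                    [w * (len(s) - read_length + 1) for _, _, s, w in usable]
                )
                weights = weights / weights.sum()
                counts = rng.multinomial(n_reads_per_sample, weights)
                r = 0
                for (iso_id, gene_id, seq, _), c in zip(usable, counts):
                    if c == 0:
                        continue
                    starts = rng.integers(0, len(seq) - read_length + 1, size=c)
                    for st in starts:
                        frag = seq[st : st + read_length]
                        frag = _mutate(frag, error_rate, rng)
                        qual = 1.0
                        if rng.random() < low_quality_fraction:
                            qual = float(rng.uniform(0.0, 0.4))
                        r += 1
                        reads.append(
                            SimRead(
                                read_id=f"{sample_id}.S{r:07d}",
                                sequence=frag,
                                gene_id=gene_id,
                                isoform_id=iso_id,
                                offset=int(st),
                                read_quality=qual,
                            )
                        )
            samples[sample_id] = ReadSet(platform="short", reads=reads)
    return samples
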