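# Methods

This note documents the models, rules and numerical choices behind
`fragtx`, and what its synthetic benchmarks do and do not demonstrate.

## The problem setting

The package targets transcriptome construction for a genome that exists
only as thousands of short contigs (the planarian assembly is the model:
~43,000 super-contigs, >65% A+T, heavily repetitive). Two consequences
drive the design: many genes are truncated at contig ends, so splice
events between contigs are invisible; and short reads map promiscuously to
pseudogenes and unresolved duplications, so single-exon short-read calls
are unreliable. The pipeline combines a long-read assembly (trustworthy
but shallow) with ultra-deep short reads (deep but annotation-dependent),
and uses an iterative "super-gene" remapping step to discover splice
junctions the starting annotation misses.

## Synthetic data: what it emulates

`fragtx.synthetic` generates the study conditions with known truth:

- **Genome** — i.i.d. bases at a configurable A+T fraction (default 0.65),
  contigs of 5–20 kb by default, an optional shared repeat pool. Loci
  never overlap, not even across strands.
- **Genes** — multi-exon genes (2–6 exons of 100–300 bp, introns of
  100–600 bp), a configurable fraction of single-exon genes, and cassette
  isoforms with probability `isoform_prob`. Baseline expression is drawn
  log-uniform over [1, 10³], spanning the dynamic range seen in deep
  RNA-seq RPKM tables.
- **Pseudogene copies** — intronless duplicates of a real gene's spliced
  sequence, mutated at 1–3%, with zero expression. They reproduce the
  confounder that motivates the single-exon removal rules: short reads
  still map to them, long reads (expression-derived) do not.
- **Junction distinctness** — the first intron base is forced to differ
  from the first base of the following exon, and the last intron base from
  the last base of the preceding exon. Real aligners resolve the
  equivalent ambiguity with the GT–AG intron motif; without this
  constraint a junction can slide along identical flanking bases and no
  motif-free method can place it (or assemble the exon edge) exactly. The
  generator therefore makes splice sites locally unambiguous rather than
  modelling motif scoring, which is out of scope.
- **Reads** — long reads with lognormal lengths (σ = 0.45, mean matched to
  the 278 bp target, minimum 40 bp), drawn from spliced isoforms in either
  orientation; strand-specific 50 bp short reads with per-sample
  multinomial counts proportional to rate × effective length, uniform
  start positions, optional substitution/indel errors and a scalar
  per-read quality (5% of reads tagged low-quality by default). The
  irradiation contrast divides the multipliers of a designated gene set by
  a fold factor in the irradiated condition only; 14.28 (the canonical
  stem-cell marker depletion) is the default demo fold.

Not emulated: position- and sequence-dependent error profiles, coverage
bias, fragment-length effects, colour-space chemistry (reads are simulated
in base space; the quality filter operates on the scalar quality),
inter-contig genes. Passing benchmarks on this generator therefore shows
the *logic* of the pipeline is correct under its stated assumptions, not
that it is robust to every artefact of real instruments.

## Mapping

A seed-and-extend mapper (exact k-mer index, k = 16, three sampled seeds
per read per orientation). Per candidate diagonal the best segment with at
most 3 mismatches is chosen under +1 match / −2 mismatch scoring with
max-scoring terminal trimming — without that trimming, junction-straddling
reads with short overhangs are accepted as full-length placements and
their mismatched tails smear assembled exon edges by several bases, which
silently breaks junction-exact rescue. Placements clipped below 30% of the
read count as mapped; at or above 30% they are *partial* — a candidate
half of a split read. Unmapped and partial high-quality reads form the
rescue pool. Reads failing a contiguous genome placement are tried against
annotated cDNAs and projected back through the exon chain as N-gapped
genome alignments. Ties across distinct best-scoring loci give
`uniqueness = multi`; only unique placements feed assembly and counting.
The default score threshold 40 corresponds to ≤3 mismatches on a 50 bp
read and stands in for the (unpublished) platform score cutoff.

## Assembly

Coverage islands are maximal intervals of per-base unique coverage ≥1
supported by ≥2 uniquely-mapped high-quality reads. Junctions are kept if
their split-read support is ≥ `junction_fraction` (0.1) of the best
junction sharing either splice site. Islands are chained through junctions
into loci (connected components); paths are enumerated greedily by
descending support (capped at 200 per locus) and pruned below
`isoform_fraction` (0.3) of the locus maximum — a thresholded stand-in
for full flow decomposition, which the pipeline's behaviour does not
require. Unlinked islands become single-exon models. Nearby islands are
never merged across a coverage gap. The defaults mirror a widely used
reference-guided assembler's settings (`-I 100000 -F 0 -f 0.3 -j 0.1`,
min 2 unique reads); where that tool's quoted `-F 0`/`-f 0.3` pair is
internally inconsistent, the 0.3 isoform fraction is the default and both
knobs are exposed.

## Super-gene rescue

All exons of all models on one contig strand are unioned into ordered
blocks; the concatenated sequence (reverse-complemented for the minus
strand) is the super-gene cDNA, with a bijective cDNA↔genome map. One
super-gene per strand per expressed contig. Candidates (unmapped or
partial, quality ≥0.5) are remapped contiguously against the cDNAs;
a unique best full-length placement spanning ≥2 blocks with ≥10 matched
bases beyond every junction becomes a new genome-space split alignment;
within-block placements are kept as plain alignments; ambiguous placements
are discarded. New split reads replace the candidates' previous records
and the alignment set is re-assembled. The loop (default 1 round,
generalised with `max_rounds`) stops at a fixed point in the junction set.
Inter-contig junctions are deliberately not attempted — the fragmented-
assembly blind spot is reproduced, not patched. The 10 bp anchor and the
30% partial threshold are package choices: 30% of 50 bp leaves a ≥15 bp
stub for seeding, and 10 bp anchors suppress one-base spurious joins.

Rescue effectiveness is depth-limited by construction: an exon edge can
only be assembled exactly if some read ends exactly at it, so junction-
exact rescue needs on the order of ≥100× per-transcript coverage (the real
study operated at ~1000×). The rescue benchmark therefore runs 200 genes
at uniform ~140× with half the annotation withheld; recall is measured
against withheld junctions having ≥2 straddling reads with ≥15 bp on each
side.

## Long-read assembly

Suffix–prefix overlaps (≥40 bp at ≥95% identity, both orientations,
ungapped on k-mer-witnessed diagonals) define the overlap graph; exact
substring containments are absorbed first. Components (isogroups) are
consistently oriented, proper dovetail overlaps recomputed, transitively
reduced, and each maximal path yields one isotig by chaining consensus
(first-read bases win overlap disagreements; adequate for the low-error
reads simulated). Branches — cassette isoforms — yield one isotig per
alternative. Exact reconstruction of a transcript requires reads tiling
through both termini; with uniformly random starts the extreme ends are
often uncovered, so the exactness test uses deterministic tilings and the
random-read tests assert containment and counts. EST co-assembly is
modelled by pooling a second read set. N50 is the largest L such that
contigs ≥ L hold at least half the assembled bases; saturation curves
assemble nested seeded subsets.

## Platform merge

The homology screen calls a short-read transcript matched if a local
alignment to any long-read contig spans ≥50 columns at ≥95% identity
(Smith–Waterman via Biopython's PairwiseAligner, match +1 / mismatch −2 /
gap open −3, extend −2, both strands, k-mer pre-filter standing in for a
database-size-dependent E-value cutoff that is not reproducible). Collapse
merges containments (edlib infix alignment within the identity budget) and
proper dovetails into superstrings; internal differences block merging.
The merge then applies, in order and with a full decision log: screen →
keep unmatched multi-exon, drop unmatched single-exon → co-assemble →
drop single-exon short-read-only singletons → emit with provenance labels
(`longread_only` / `shortread_only_multiexon` / `combined`).

## ORF calling

Six frames; codons with N match neither start nor stop; peptides exclude
the stop. A reading may start at an ATG or at the sequence edge, and may
end at a stop or run off the edge, giving the four completeness classes.
Anchored readings (≥1 of start/stop present) are preferred over fully open
edge-to-edge readings, which win only when no frame has an anchor; within
a class-rank the longest wins, then frame order +1, +2, +3, −1, −2, −3,
then leftmost. Calls under 10 codons are suppressed by default — in real
transcript sets the pileup of ~50 aa ORFs is dominated by spurious frames
in untranslated sequence.

## Expression contrast

RPKM = 1e9 × count / (total_mapped × length) with per-sample totals; a
transcript is kept if RPKM ≥ 1 in at least one sample. Group comparison
follows the weighted-proportions scheme of the beta-binomial SAGE test:
library-size weights, group proportion p̂ = Σwᵢpᵢ, and a variance that is
the larger of the within-library binomial term p̂(1−p̂)/N and the unbiased
weighted between-replicate term. The statistic (p̂_A−p̂_B)/√(V_A+V_B) is
referred to a t distribution with Welch–Satterthwaite degrees of freedom
when the empirical term wins in both groups — the regime where the
variance is genuinely estimated, and where the test provably reduces to
Welch's two-sample t on proportions — and to the normal otherwise, since
the binomial term is a plug-in of known form (with one replicate this is
the binomial proportions z-test). The max rule makes the test
intentionally conservative near the null when replicate scatter is
comparable to counting noise; its measured null rejection at α = 0.05
under 2+2 replicates and 10⁶-read libraries is ~0.03. Fold change is
signed (−x means x-fold lower after irradiation) so that the published
marker-panel fold changes are reproduced from their printed group means;
no multiple-testing correction enters the down-regulated call (raw
p < 0.01 and fold ≤ −2), though a Benjamini–Hochberg column is emitted.

## Pipeline and determinism

`run_pipeline` executes the stages in dependency order, fanning one global
seed into per-stage sub-seeds by SHA-256 hashing, and writes a manifest of
per-stage parameters and output checksums; identical config + seed gives
byte-identical outputs. Benchmark problem sizes (200 genes / 450k reads
for rescue, 600 transcripts / 10⁶-read libraries for the DE recovery,
10⁴ transcripts for null calibration, a 25-gene demo pipeline) were chosen
so the full suite and the acceptance script each complete in minutes on a
single CPU while keeping the measured proportions stable across seeds.

## Known limitations

- Junction discovery is annotation- or rescue-driven only; there is no de
  novo intron discovery or splice-motif model.
- Super-genes cannot represent exon-skipping junctions (the skipped exon
  sits between the blocks), so cassette junctions absent from the starting
  annotation are unrecoverable by design.
- The ungapped overlap detector misses overlaps containing indels; at the
  simulated error rates (≤1%, mostly substitutions) this is negligible.
- The expression test's conservatism (max-of-variances) costs power for
  transcripts whose replicate scatter happens to dominate; strongly
  depleted genes are still detected (≥90% sensitivity in the recovery
  benchmark).
- Real-data scale figures (hundreds of millions of reads, tens of
  thousands of transcripts) are out of desk-scale reach; all quantitative
  claims here are about the synthetic conditions above.
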