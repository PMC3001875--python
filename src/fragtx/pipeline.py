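"""End-to-end orchestration: simulate -> map -> assemble -> rescue ->
long-read assembly -> merge -> ORF -> DE, with a checksummed manifest and
truth-based evaluation for synthetic runs.

One global seed fans out to per-stage sub-seeds by stable hashing so any
stage can be re-run in isolation with identical results.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import assembly, expression, io_utils, longread, mapping, merge, orf, supergene, synthetic


def stage_seed(global_seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).hexdigest()
    return int(h[:8], 16) % (2**31)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "genome": {"n_contigs": 50, "contig_length_range": [6000, 12000], "at_fraction": 0.65},
    "genes": {
        "n_genes": 200,
        "exon_count_range": [2, 5],
        "isoform_prob": 0.25,
        "single_exon_fraction": 0.2,
        "pseudogene_fraction": 0.05,
    },
    "irradiation": {"depleted_fraction": 0.2, "fold": 14.28},
    "short_reads": {"n_reads_per_sample": 60000, "error_rate": 0.0},
    "long_reads": {"n_reads": 1500, "mean_length": 278, "error_rate": 0.0},
    "mapping": {},
    "assembly": {},
    "rescue": {"max_rounds": 1, "annotation_fraction": 1.0},
    "merge": {},
    "de": {},
    "stages": [
        "simulate", "map", "assemble", "rescue", "assemble_long",
        "merge", "orf", "de",
    ],
}


def _merged_config(config: dict | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (config or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def run_pipeline(config: dict | None, outdir: str | Path) -> dict:
    """Execute the configured stages in dependency order.

    Returns the run manifest: per-stage parameters, outputs and sha256
    checksums. Stage outputs land under ``outdir``.
    """
    cfg = _merged_config(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    stages = list(cfg["stages"])
    manifest: dict = {"seed": seed, "stages": {}}

    genome = truth = samples = None
    alignments_by_sample = {}
    models = []
    merged_seqs = {}

    def record(stage: str, params: dict, outputs: list[Path]) -> None:
        manifest["stages"][stage] = {
            "params": params,
            "outputs": {p.name: _checksum(p) for p in outputs},
        }

    if "simulate" in stages:
        gp = synthetic.GenomeParams(
            n_contigs=cfg["genome"]["n_contigs"],
            contig_length_range=tuple(cfg["genome"]["contig_length_range"]),
            at_fraction=cfg["genome"]["at_fraction"],
            seed=stage_seed(seed, "genome"),
        )
        genome = synthetic.generate_genome(gp)
        synthetic.generate_gene_models(
            genome,
            n_genes=cfg["genes"]["n_genes"],
            exon_count_range=tuple(cfg["genes"]["exon_count_range"]),
            isoform_prob=cfg["genes"]["isoform_prob"],
            single_exon_fraction=cfg["genes"]["single_exon_fraction"],
            pseudogene_fraction=cfg["genes"]["pseudogene_fraction"],
            seed=stage_seed(seed, "genes"),
        )
        truth = synthetic.default_expression_truth(genome.genes)
        rng = np.random.default_rng(stage_seed(seed, "depletion"))
        expressed = [
            g.gene_id for g in genome.genes if g.baseline_expression > 0
        ]
        n_dep = int(round(cfg["irradiation"]["depleted_fraction"] * len(expressed)))
        depleted = sorted(rng.choice(expressed, size=n_dep, replace=False))
        synthetic.apply_irradiation_effect(
            truth, list(depleted), cfg["irradiation"]["fold"]
        )
        samples = synthetic.simulate_short_reads(
            genome,
            truth,
            n_reads_per_sample=cfg["short_reads"]["n_reads_per_sample"],
            error_rate=cfg["short_reads"]["error_rate"],
            seed=stage_seed(seed, "short_reads"),
        )
        genome_fa = out / "genome.fa"
        truth_gtf = out / "truth.gtf"
        io_utils.write_fasta(genome.contigs, genome_fa)
        synthetic.write_truth_gtf(genome.genes, truth_gtf)
        depleted_tsv = out / "depleted.tsv"
        io_utils.write_tsv([[g] for g in depleted], ["gene_id"], depleted_tsv)
        record(
            "simulate",
            {"n_contigs": gp.n_contigs, "n_genes": cfg["genes"]["n_genes"],
             "depleted": len(depleted), "fold": cfg["irradiation"]["fold"]},
            [genome_fa, truth_gtf, depleted_tsv],
        )

    map_params = mapping.MappingParams(**cfg["mapping"])
    if "map" in stages:
        annotation = [
            g.isoform_model(j)
            for g in genome.genes
            for j in range(len(g.isoforms))
            if not g.is_pseudogene_copy
        ]
        frac = cfg["rescue"].get("annotation_fraction", 1.0)
        if frac < 1.0:
            rng = np.random.default_rng(stage_seed(seed, "annotation"))
            keep = rng.random(len(annotation)) < frac
            annotation = [m for m, k in zip(annotation, keep) if k]
        outputs = []
        for sample_id, readset in sorted(samples.items()):
            alns = mapping.map_reads(
                readset.reads, genome.contigs, map_params, annotation
            )
            alignments_by_sample[sample_id] = alns
            path = out / f"{sample_id}.aln.tsv"
            io_utils.write_sam_like(alns, path)
            outputs.append(path)
        record("map", asdict(map_params), outputs)

    asm_params = assembly.AssemblyParams(**cfg["assembly"])
    pooled = [a for s in sorted(alignments_by_sample) for a in alignments_by_sample[s]]
    if "assemble" in stages:
        filtered = mapping.quality_filter(pooled, map_params)
        models = assembly.assemble(filtered, genome.contigs, asm_params)
        gtf = out / "assembled.gtf"
        io_utils.write_gtf(models, gtf)
        summary = out / "assembly_summary.tsv"
        counts = assembly.annotate_counts(models)
        io_utils.write_tsv(
            [[k, v] for k, v in counts.items()], ["metric", "value"], summary
        )
        record("assemble", asdict(asm_params), [gtf, summary])

    if "rescue" in stages:
        models, final_alns, ledger = supergene.iterate_rescue(
            pooled, genome.contigs, map_params, asm_params,
            max_rounds=cfg["rescue"]["max_rounds"],
        )
        gtf = out / "rescued.gtf"
        io_utils.write_gtf(models, gtf)
        ledger_tsv = out / "junction_ledger.tsv"
        io_utils.write_tsv(
            [[d["round"], d["n_junctions"], d["n_new_split_reads"],
              d["n_multi_exon"], d["n_single_exon"]] for d in ledger],
            ["round", "n_junctions", "n_new_split_reads", "n_multi_exon",
             "n_single_exon"],
            ledger_tsv,
        )
        record("rescue", {"max_rounds": cfg["rescue"]["max_rounds"]},
               [gtf, ledger_tsv])

    isotigs = []
    if "assemble_long" in stages:
        readset = synthetic.simulate_long_reads(
            genome,
            n_reads=cfg["long_reads"]["n_reads"],
            mean_length=cfg["long_reads"]["mean_length"],
            error_rate=cfg["long_reads"]["error_rate"],
            seed=stage_seed(seed, "long_reads"),
        )
        reads = {r.read_id: r.sequence for r in readset.reads}
        graph = longread.overlap_graph(reads)
        isotigs = longread.assemble_isotigs(graph, reads)
        fa = out / "isotigs.fa"
        io_utils.write_fasta({t.isotig_id: t.sequence for t in isotigs}, fa)
        mapping_tsv = out / "isotig_isogroup.tsv"
        io_utils.write_tsv(
            [[t.isotig_id, t.isogroup_id] for t in isotigs],
            ["isotig", "isogroup"], mapping_tsv,
        )
        record("assemble_long", {"n_reads": len(reads)}, [fa, mapping_tsv])

    merge_params = merge.MergeParams(**cfg["merge"])
    if "merge" in stages:
        long_contigs = {t.isotig_id: t.sequence for t in isotigs}
        collapsed, _ = merge.collapse_isoforms(long_contigs, merge_params)
        short_cdna = {
            m.transcript_id: m.spliced_sequence(genome.contigs) for m in models
        }
        report, merged_seqs, provenance = merge.merge_datasets(
            collapsed, models, short_cdna, merge_params
        )
        fa = out / "merged.fa"
        io_utils.write_fasta(merged_seqs, fa)
        report_json = out / "merge_report.json"
        rep = asdict(report)
        rep.pop("decision_log")
        report_json.write_text(json.dumps(rep, indent=1, sort_keys=True))
        log_json = out / "merge_decision_log.json"
        log_json.write_text(json.dumps(report.decision_log, indent=0))
        record("merge", asdict(merge_params), [fa, report_json, log_json])

    if "orf" in stages:
        target = merged_seqs or {
            m.transcript_id: m.spliced_sequence(genome.contigs) for m in models
        }
        calls, class_counts, hist = orf.classify_orfs(target)
        orf_tsv = out / "orfs.tsv"
        io_utils.write_tsv(
            [
                [c.transcript_id, c.frame, c.start, c.end, c.orf_class, c.peptide]
                for c in calls.values()
            ],
            ["transcript_id", "frame", "start", "end", "class", "peptide"],
            orf_tsv,
        )
        pep_fa = out / "peptides.fa"
        io_utils.write_fasta(
            {
                f"{c.transcript_id}|{c.frame:+d}|{c.start}-{c.end}": c.peptide
                for c in calls.values()
            },
            pep_fa,
        )
        record("orf", {"classes": dict(class_counts)}, [orf_tsv, pep_fa])

    de_results = []
    if "de" in stages:
        de_params = expression.DEParams(**cfg["de"])
        quant_models = models
        counts_by_sample = {}
        for sample_id, alns in sorted(alignments_by_sample.items()):
            filtered = mapping.quality_filter(alns, map_params)
            counts_by_sample[sample_id] = expression.count_unique_reads(
                filtered, quant_models
            )
        conditions = {s: s.rsplit("_", 1)[0] for s in counts_by_sample}
        table = expression.build_table(
            counts_by_sample,
            {m.transcript_id: m.spliced_length for m in quant_models},
            conditions,
        )
        filtered_table = expression.expression_filter(table, de_params)
        de_results = expression.differential_expression(filtered_table, de_params)
        de_tsv = out / "de_results.tsv"
        io_utils.write_tsv(
            [
                [
                    r.transcript_id,
                    f"{r.mean_rpkm_intact:.4f}",
                    f"{r.mean_rpkm_irradiated:.4f}",
                    f"{r.fold_change:.2f}",
                    f"{r.p_value:.4g}",
                    f"{r.p_adjusted:.4g}",
                    int(r.passes),
                ]
                for r in de_results
            ],
            ["transcript_id", "mean_rpkm_intact", "mean_rpkm_irradiated",
             "fold_change", "p_value", "p_adjusted", "passes"],
            de_tsv,
        )
        record("de", asdict(de_params), [de_tsv])

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# truth-based evaluation


def precision_recall(predicted: set, truth: set) -> tuple[float | None, float]:
    tp = len(predicted & truth)
    precision = tp / len(predicted) if predicted else None
    recall = tp / len(truth) if truth else 1.0
    return precision, recall


def evaluate_junctions(
    models: list[io_utils.TranscriptModel],
    genes: list[synthetic.GeneTruth],
) -> tuple[float | None, float]:
    predicted = set()
    for m in models:
        for d, a in m.junctions():
            predicted.add((m.contig_id, m.strand, d, a))
    truth = set()
    for g in genes:
        truth |= g.junctions()
    return precision_recall(predicted, truth)


def evaluate_transcripts(
    models: list[io_utils.TranscriptModel],
    genes: list[synthetic.GeneTruth],
) -> tuple[float | None, float]:
    predicted = {
        (m.contig_id, m.strand, tuple(m.exons)) for m in models
    }
    truth = set()
    for g in genes:
        for j in range(len(g.isoforms)):
            truth.add((g.contig_id, g.strand, tuple(g.isoform_exons(j))))
    return precision_recall(predicted, truth)


def evaluate_de(
    called_gene_ids: set[str], depleted_gene_ids: set[str]
) -> tuple[float | None, float]:
    return precision_recall(called_gene_ids, depleted_gene_ids)
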