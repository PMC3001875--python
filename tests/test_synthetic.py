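import numpy as np
import pytest

from fragtx import synthetic
from fragtx.io_utils import read_gtf, reverse_complement, write_fasta
from fragtx.synthetic import (
    GenomeParams,
    ParameterError,
    apply_irradiation_effect,
    default_expression_truth,
    generate_gene_models,
    generate_genome,
    simulate_long_reads,
    simulate_short_reads,
    write_truth_gtf,
)


class TestGenome:
    def test_empty(self):
        assert generate_genome(GenomeParams(n_contigs=0)).contigs == {}

    def test_determinism_byte_identical(self, tmp_path):
        paths = []
        for i in (1, 2):
            g = generate_genome(GenomeParams(n_contigs=5, seed=7))
            p = tmp_path / f"g{i}.fa"
            write_fasta(g.contigs, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_at_fraction(self):
        g = generate_genome(
            GenomeParams(n_contigs=50, contig_length_range=(5_000, 20_000),
                         at_fraction=0.65, seed=1)
        )
        seq = "".join(g.contigs.values())
        at = (seq.count("A") + seq.count("T")) / len(seq)
        assert abs(at - 0.65) < 0.02

    def test_repeat_pool_shared(self):
        g = generate_genome(
            GenomeParams(n_contigs=4, contig_length_range=(4_000, 5_000),
                         repeat_fraction=0.3, seed=2)
        )
        seqs = list(g.contigs.values())
        # some 100-mer of contig 0 recurs in another contig
        shared = any(
            seqs[0][i : i + 100] in s
            for i in range(0, len(seqs[0]) - 100, 50)
            for s in seqs[1:]
        )
        assert shared

    def test_invalid_params(self):
        with pytest.raises(ParameterError):
            GenomeParams(at_fraction=1.5)
        with pytest.raises(ParameterError):
            GenomeParams(repeat_fraction=1.0)
        with pytest.raises(ParameterError):
            GenomeParams(n_contigs=-1)


class TestGeneModels:
    def test_empty(self):
        genome = generate_genome(GenomeParams(n_contigs=2, seed=1))
        assert generate_gene_models(genome, 0, seed=1) == []

    def test_single_exon_fraction_forced(self):
        g = generate_genome(GenomeParams(n_contigs=5, seed=9))
        genes = generate_gene_models(
            g, 10, single_exon_fraction=1.0, pseudogene_fraction=0.0, seed=9
        )
        assert len(genes) == 10
        assert all(gene.is_single_exon for gene in genes)
        assert all(not gene.junctions() for gene in genes)

    def test_junction_count_matches_emitted_gtf(self, tmp_path):
        g = generate_genome(
            GenomeParams(n_contigs=40, contig_length_range=(8_000, 15_000), seed=5)
        )
        genes = generate_gene_models(
            g, 100, exon_count_range=(2, 6), pseudogene_fraction=0.0,
            single_exon_fraction=0.0, isoform_prob=0.0, seed=6,
        )
        path = tmp_path / "truth.gtf"
        write_truth_gtf(genes, path)
        models = read_gtf(path)
        gtf_junctions = sum(len(m.junctions()) for m in models)
        expected = sum(
            len(gene.isoforms[j]) - 1
            for gene in genes
            for j in range(len(gene.isoforms))
        )
        assert gtf_junctions == expected > 0

    def test_truth_gtf_roundtrip(self, small_world, tmp_path):
        genome, genes = small_world
        path = tmp_path / "t.gtf"
        write_truth_gtf(genes, path)
        models = {m.transcript_id: m for m in read_gtf(path)}
        for gene in genes:
            for j, iso_id in enumerate(gene.isoform_ids()):
                m = models[iso_id]
                assert m.exons == sorted(gene.isoform_exons(j))
                assert m.strand == gene.strand
                assert m.contig_id == gene.contig_id

    def test_exons_within_bounds_and_disjoint(self, small_world):
        genome, genes = small_world
        for gene in genes:
            clen = genome.contig_length(gene.contig_id)
            prev_end = -1
            for a, b in gene.exons:
                assert 0 <= a < b <= clen
                assert a > prev_end
                prev_end = b

    def test_pseudogenes_are_mutated_copies_with_zero_rate(self, small_world):
        genome, genes = small_world
        pseudo = [g for g in genes if g.is_pseudogene_copy]
        assert pseudo
        real = {
            g.gene_id: g.isoform_model(0).spliced_sequence(genome.contigs)
            for g in genes if not g.is_pseudogene_copy
        }
        for p in pseudo:
            assert p.baseline_expression == 0.0
            assert p.is_single_exon
            seq = p.isoform_model(0).spliced_sequence(genome.contigs)
            # close (1-3% divergence) to some real spliced sequence
            best = min(
                sum(a != b for a, b in zip(seq, s)) / len(s)
                for s in real.values() if len(s) == len(seq)
            )
            assert best <= 0.04


class TestExpression:
    def test_irradiation_effect(self, small_world):
        _, genes = small_world
        truth = default_expression_truth(genes)
        gid = genes[0].gene_id
        apply_irradiation_effect(truth, [gid], fold=14.28)
        assert truth.multipliers["irradiated"][gid] == pytest.approx(1 / 14.28)
        # canonical depletion magnitude: 275.7 -> 19.3
        assert 275.7 * truth.multipliers["irradiated"][gid] == pytest.approx(
            19.3, abs=0.05
        )
        # untouched elsewhere
        assert truth.multipliers["intact"] == {}

    def test_effect_composes_and_validates(self, small_world):
        _, genes = small_world
        truth = default_expression_truth(genes)
        gid = genes[0].gene_id
        apply_irradiation_effect(truth, [gid], 2.0)
        apply_irradiation_effect(truth, [gid], 2.0)
        assert truth.multipliers["irradiated"][gid] == pytest.approx(0.25)
        apply_irradiation_effect(truth, [], 5.0)  # empty set: no-op
        with pytest.raises(KeyError, match="nope"):
            apply_irradiation_effect(truth, ["nope"], 2.0)
        with pytest.raises(ParameterError):
            apply_irradiation_effect(truth, [gid], 1.0)


class TestLongReads:
    def test_empty(self, small_world):
        genome, _ = small_world
        assert len(simulate_long_reads(genome, 0, seed=1)) == 0

    def test_exact_substrings_when_error_free(self, small_world):
        genome, genes = small_world
        rs = simulate_long_reads(genome, 200, error_rate=0.0, seed=2)
        spliced = {
            iso: g.isoform_model(j).spliced_sequence(genome.contigs)
            for g in genes
            for j, iso in enumerate(g.isoform_ids())
        }
        for r in rs.reads:
            source = spliced[r.isoform_id]
            assert (
                r.sequence in source or reverse_complement(r.sequence) in source
            )

    def test_mean_length(self, small_world):
        genome, _ = small_world
        rs = simulate_long_reads(genome, 5_000, mean_length=278, seed=3)
        mean = np.mean([len(r.sequence) for r in rs.reads])
        assert 250 <= mean <= 306


class TestShortReads:
    def test_all_zero_multipliers_empty(self, small_world):
        genome, genes = small_world
        truth = default_expression_truth(genes)
        truth.baseline = {g: 0.0 for g in truth.baseline}
        samples = simulate_short_reads(genome, truth, 1_000, seed=1)
        assert all(len(rs) == 0 for rs in samples.values())

    def test_negative_multiplier_rejected(self, small_world):
        genome, genes = small_world
        truth = default_expression_truth(genes)
        truth.multipliers["irradiated"][genes[0].gene_id] = -1.0
        with pytest.raises(ParameterError):
            simulate_short_reads(genome, truth, 100, seed=1)

    def test_reads_are_50bp_sense_substrings(self, small_world):
        genome, genes = small_world
        truth = default_expression_truth(genes)
        samples = simulate_short_reads(
            genome, truth, 2_000, seed=2, low_quality_fraction=0.0
        )
        spliced = {
            iso: g.isoform_model(j).spliced_sequence(genome.contigs)
            for g in genes
            for j, iso in enumerate(g.isoform_ids())
        }
        for rs in samples.values():
            for r in rs.reads:
                assert len(r.sequence) == 50
                assert spliced[r.isoform_id][r.offset : r.offset + 50] == r.sequence

    def test_depletion_recovered_from_origins(self, small_world):
        genome, genes = small_world
        truth = default_expression_truth(genes)
        expressed = [g.gene_id for g in genes if g.baseline_expression > 0]
        depleted = expressed[:5]
        apply_irradiation_effect(truth, depleted, fold=20.0)
        samples = simulate_short_reads(genome, truth, 100_000, seed=3)
        def counts(sample, gid):
            return sum(1 for r in samples[sample].reads if r.gene_id == gid)
        for gid in depleted:
            a = counts("intact_1", gid) + counts("intact_2", gid)
            b = counts("irradiated_1", gid) + counts("irradiated_2", gid)
            if a >= 200:  # baseline high enough to measure the ratio
                ratio = a / max(b, 1)
                assert 10 <= ratio <= 40  # within 2-fold of the true 20


def test_generators_deterministic(small_world):
    genome, genes = small_world
    truth = default_expression_truth(genes)
    a = simulate_short_reads(genome, truth, 500, seed=11)
    b = simulate_short_reads(genome, truth, 500, seed=11)
    assert all(
        [(r.read_id, r.sequence) for r in a[s].reads]
        == [(r.read_id, r.sequence) for r in b[s].reads]
        for s in a
    )
    la = simulate_long_reads(genome, 50, seed=11)
    lb = simulate_long_reads(genome, 50, seed=11)
    assert [r.sequence for r in la.reads] == [r.sequence for r in lb.reads]
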