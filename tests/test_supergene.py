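import numpy as np
import pytest

from oracles import project_bruteforce

from fragtx import assembly, mapping, supergene, synthetic
from fragtx.io_utils import PARTIAL, UNIQUE, UNMAPPED, SamRecord, TranscriptModel, reverse_complement
from fragtx.mapping import MappingParams
from fragtx.supergene import (
    build_supergenes,
    iterate_rescue,
    merge_alignments,
    rescue_split_reads,
    select_rescue_candidates,
)


def _genome(seed=0, n=1, length=2_000):
    rng = np.random.default_rng(seed)
    return {
        f"c{i}": "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])
        for i in range(n)
    }


class TestBuildSupergenes:
    def test_two_exon_example(self):
        genome = _genome()
        models = [TranscriptModel("t", "c0", True, [(100, 200), (300, 400)])]
        (sg,) = build_supergenes(models, genome)
        assert sg.length == 200
        assert sg.cdna_sequence == genome["c0"][100:200] + genome["c0"][300:400]
        # junction map around the block join
        assert sg.genome_position(99) == 199
        assert sg.genome_position(100) == 300
        assert sg.cdna_offset(300) == 100

    def test_single_exon_identity_map(self):
        genome = _genome()
        models = [TranscriptModel("t", "c0", True, [(500, 600)])]
        (sg,) = build_supergenes(models, genome)
        assert sg.blocks == [(500, 600)]
        assert all(sg.genome_position(i) == 500 + i for i in range(100))

    def test_one_per_strand(self):
        genome = _genome()
        models = [
            TranscriptModel("a", "c0", True, [(0, 100)]),
            TranscriptModel("b", "c0", False, [(300, 400)]),
            TranscriptModel("d", "c0", True, [(50, 150)]),  # overlaps a: unioned
        ]
        sgs = build_supergenes(models, genome)
        assert len(sgs) == 2
        plus = next(s for s in sgs if s.strand)
        assert plus.blocks == [(0, 150)]

    def test_unknown_contig_rejected(self):
        with pytest.raises(KeyError):
            build_supergenes(
                [TranscriptModel("t", "nope", True, [(0, 10)])], _genome()
            )

    @pytest.mark.parametrize("seed", range(10))
    def test_coord_map_bijection_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        genome = _genome(seed, length=4_000)
        pos, blocks = 0, []
        for _ in range(int(rng.integers(2, 6))):
            pos += int(rng.integers(20, 300))
            end = pos + int(rng.integers(30, 300))
            blocks.append((pos, end))
            pos = end
        strand = bool(rng.integers(2))
        models = [TranscriptModel("t", "c0", strand, blocks)]
        (sg,) = build_supergenes(models, genome)
        covered = sorted(p for a, b in blocks for p in range(a, b))
        seen = set()
        for off in range(sg.length):
            p = sg.genome_position(off)
            assert sg.cdna_offset(p) == off
            seen.add(p)
        assert sorted(seen) == covered
        # interval projection agrees with per-base brute force
        for _ in range(10):
            a = int(rng.integers(0, sg.length - 1))
            b = int(rng.integers(a + 1, sg.length + 1))
            assert sg.project(a, b) == project_bruteforce(blocks, strand, a, b)


class TestCandidates:
    def _aln(self, status, qual=1.0, cigar="50M"):
        mapped = status != UNMAPPED
        return (
            SamRecord("r", mapped, True, "c" if mapped else None,
                      0 if mapped else None, 30, cigar if mapped else None,
                      "A" * 50, qual),
            status,
        )

    def test_selection_rules(self):
        params = MappingParams(min_read_quality=0.5)
        alns = [
            self._aln(UNIQUE),                       # fully mapped: never
            self._aln(PARTIAL, cigar="20S30M"),      # partial: yes
            self._aln(UNMAPPED),                     # unmapped: yes
            self._aln(UNMAPPED, qual=0.2),           # low quality: no
            self._aln(PARTIAL, qual=0.3),            # low quality: no
        ]
        cands = select_rescue_candidates(alns, params)
        assert [c.read_id for c in cands] == ["r", "r"]
        assert {s for _, s in alns[1:3]} == {PARTIAL, UNMAPPED}


class TestRescue:
    def test_straddling_candidate_becomes_split_read(self):
        genome = _genome(3)
        sg_models = [TranscriptModel("t", "c0", True, [(100, 200), (300, 400)])]
        (sg,) = build_supergenes(sg_models, genome)
        # read with 30 bases from block 1 and 20 from block 2
        seq = genome["c0"][170:200] + genome["c0"][300:320]
        cand = SamRecord("x", False, True, None, None, 0, None, seq, 1.0)
        (rec, status), = rescue_split_reads(
            [cand], [sg], MappingParams()
        )
        assert status == UNIQUE
        assert rec.pos == 170
        assert rec.cigar == "30M100N20M"

    def test_within_block_no_junction(self):
        genome = _genome(3)
        (sg,) = build_supergenes(
            [TranscriptModel("t", "c0", True, [(100, 400)])], genome
        )
        seq = genome["c0"][150:200]
        cand = SamRecord("x", False, True, None, None, 0, None, seq, 1.0)
        (rec, status), = rescue_split_reads([cand], [sg], MappingParams())
        assert "N" not in rec.cigar

    def test_no_match_stays_unmapped(self):
        genome = _genome(3)
        (sg,) = build_supergenes(
            [TranscriptModel("t", "c0", True, [(100, 400)])], genome
        )
        cand = SamRecord("x", False, True, None, None, 0, None, "A" * 50, 1.0)
        assert rescue_split_reads([cand], [sg], MappingParams()) == []

    def test_min_anchor_enforced(self):
        genome = _genome(3)
        (sg,) = build_supergenes(
            [TranscriptModel("t", "c0", True, [(100, 200), (300, 400)])], genome
        )
        # only 5 bases beyond the junction: below the 10 bp anchor
        seq = genome["c0"][155:200] + genome["c0"][300:305]
        cand = SamRecord("x", False, True, None, None, 0, None, seq, 1.0)
        out = rescue_split_reads([cand], [sg], MappingParams())
        assert not any("N" in r.cigar for r, _ in out)

    def test_minus_strand_projection(self):
        genome = _genome(4)
        (sg,) = build_supergenes(
            [TranscriptModel("t", "c0", False, [(100, 200), (300, 400)])], genome
        )
        # sense read across the junction on the minus strand
        spliced = reverse_complement(genome["c0"][100:200] + genome["c0"][300:400])
        seq = spliced[80:130]  # straddles the join at offset 100
        cand = SamRecord("x", False, True, None, None, 0, None, seq, 1.0)
        (rec, status), = rescue_split_reads([cand], [sg], MappingParams())
        assert rec.cigar == "30M100N20M"
        assert rec.strand is False
        assert rec.blocks() == [(170, 200), (300, 320)]


class TestMergeAlignments:
    def _rec(self, rid, cigar="50M", score=50):
        return SamRecord(rid, True, True, "c", 0, score, cigar, "A" * 50, 1.0)

    def test_empty_rescue_identity(self):
        orig = [(self._rec("a"), UNIQUE)]
        assert merge_alignments(orig, []) == orig

    def test_disjoint_union(self):
        orig = [(self._rec(f"o{i}"), UNIQUE) for i in range(10)]
        resc = [(self._rec(f"n{i}", "25M100N25M"), UNIQUE) for i in range(3)]
        assert len(merge_alignments(orig, resc)) == 13

    def test_split_rescue_replaces_partial(self):
        orig = [(self._rec("a", "30M20S", 30), PARTIAL)]
        resc = [(self._rec("a", "30M100N20M", 50), UNIQUE)]
        (rec, status), = merge_alignments(orig, resc)
        assert rec.is_split and status == UNIQUE


class TestIterateRescue:
    def test_no_candidates_single_round(self, mapped_world):
        genome, genes, samples, alignments, params = mapped_world
        clean = [(r, s) for r, s in alignments if s == UNIQUE]
        models, final, ledger = iterate_rescue(
            clean, genome.contigs, params, assembly.AssemblyParams(), max_rounds=3
        )
        assert ledger[-1]["n_new_split_reads"] == 0
        assert len(ledger) <= 3

    def test_rescue_recovers_withheld_junctions(self):
        g = synthetic.generate_genome(
            synthetic.GenomeParams(n_contigs=12, contig_length_range=(8_000, 12_000),
                                   seed=31)
        )
        genes = synthetic.generate_gene_models(
            g, 30, pseudogene_fraction=0.0, isoform_prob=0.0, seed=32
        )
        for gene in genes:
            gene.baseline_expression = 100.0
        truth = synthetic.default_expression_truth(genes)
        samples = synthetic.simulate_short_reads(
            g, truth, 60_000, seed=33, low_quality_fraction=0.0
        )
        annotation = [gene.isoform_model(0) for gene in genes]
        rng = np.random.default_rng(34)
        kept = [m for m in annotation if rng.random() < 0.5]
        params = MappingParams()
        alns = mapping.map_reads(
            samples["intact_1"].reads, g.contigs, params, kept
        )
        models, final, ledger = iterate_rescue(
            alns, g.contigs, params, assembly.AssemblyParams(), max_rounds=2
        )
        assert ledger[1]["n_junctions"] > ledger[0]["n_junctions"]
        assert ledger[1]["n_multi_exon"] > ledger[0]["n_multi_exon"]
        # junction superset (monotonicity across the rescue round)
        truth_j = set()
        for gene in genes:
            truth_j |= gene.junctions()
        found = set()
        for m in models:
            for d, a in m.junctions():
                found.add((m.contig_id, m.strand, d, a))
        assert found <= truth_j  # soundness on an error-free fixture
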