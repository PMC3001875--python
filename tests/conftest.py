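from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fragtx import synthetic

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_world():
    """A small genome with annotated genes and uniform expression."""
    params = synthetic.GenomeParams(
        n_contigs=10, contig_length_range=(6_000, 10_000), seed=3
    )
    genome = synthetic.generate_genome(params)
    genes = synthetic.generate_gene_models(
        genome, 30, pseudogene_fraction=0.1, isoform_prob=0.3, seed=4
    )
    return genome, genes


@pytest.fixture(scope="session")
def mapped_world(small_world):
    """small_world plus one mapped short-read sample (full annotation)."""
    from fragtx import mapping

    genome, genes = small_world
    truth = synthetic.default_expression_truth(genes)
    samples = synthetic.simulate_short_reads(
        genome, truth, 30_000, seed=5, low_quality_fraction=0.02
    )
    annotation = [
        g.isoform_model(j)
        for g in genes
        for j in range(len(g.isoforms))
        if not g.is_pseudogene_copy
    ]
    params = mapping.MappingParams()
    alignments = mapping.map_reads(
        samples["intact_1"].reads, genome.contigs, params, annotation
    )
    return genome, genes, samples, alignments, params


def random_transcript_model(rng: np.random.Generator, contig_len: int = 5_000):
    """A random multi-exon model for projection property tests."""
    from fragtx.io_utils import TranscriptModel

    n_ex = int(rng.integers(1, 6))
    pos = int(rng.integers(0, 200))
    exons = []
    for _ in range(n_ex):
        length = int(rng.integers(30, 300))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(30, 400))
    return TranscriptModel(
        "t", "c", bool(rng.integers(2)), exons
    )
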