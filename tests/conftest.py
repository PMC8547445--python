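import numpy as np
import pytest

from txarch import pipeline, synthetic_data as sd
from txarch.io_formats import Annotation, CoverageTrack, GeneFeature


@pytest.fixture(scope="session")
def dataset():
    """Default magnetosome-island-like synthetic dataset (seed 1)."""
    return sd.simulate_dataset(seed=1)


@pytest.fixture(scope="session")
def tss_results(dataset):
    return pipeline.run_tss(
        dataset.annotation,
        dataset.enriched,
        dataset.control,
        dataset.wtss,
        dataset.three_prime,
    )


def make_track(counts, strand="+", library="wtss", depth=None, normalized=False):
    return CoverageTrack(
        contig_id="chr",
        strand=strand,
        counts=np.asarray(counts, dtype=float),
        library_type=library,
        total_mapped_reads=depth,
        normalized=normalized,
    )


def make_gene(start, end, strand="+", gene_id=None, contig="chr"):
    return GeneFeature(
        contig_id=contig,
        start=start,
        end=end,
        strand=strand,
        gene_id=gene_id or f"g_{start}_{end}{strand}",
    )


@pytest.fixture
def simple_annotation():
    """Two forward genes and one reverse gene on a 10-kb contig."""
    return Annotation(
        [
            make_gene(1000, 2000, "+", "geneA"),
            make_gene(2500, 3500, "+", "geneB"),
            make_gene(5000, 6000, "-", "geneC"),
        ]
    )
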