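"""txarch: transcriptional architecture of bacterial operons.

TSS calling from 5'-enriched/control end libraries, positional TSS
classification with cross-library confidence filtering, terminator calling
from 3'-end peaks and whole-transcriptome coverage drops, bioluminescence
promoter-strength quantification, and TSS-anchored promoter conservation
scoring — with a planted-truth synthetic data generator covering every stage.
"""

from importlib import resources

from .io_formats import (
    Annotation,
    CoverageTrack,
    GeneFeature,
    GenomeRecord,
    WellSeries,
    read_bedgraph,
    read_fasta,
    read_gff3,
    read_plate_csv,
    write_bedgraph,
    write_fasta,
    write_gff3,
    write_tss_table,
)
from .tss_calling import TSSCandidate, call_candidates, compute_rrs, enrichment_score
from .tss_annotation import (
    ClassifiedTSS,
    ClassFractions,
    class_fractions,
    classify_tss,
    filter_confident,
    threeprime_support,
    wtss_support,
)
from .tts_calling import OperonReport, TTSCall, call_tts, summarize_architecture
from .reporter import (
    PromoterActivity,
    call_active,
    compare_groups,
    compute_rlu,
    relative_strength,
    rlu_max,
    summarize_plate,
)
from .conservation import (
    PromoterWindow,
    extract_window,
    global_align,
    identity_profile,
    percent_identity,
)
from .pipeline import PipelineConfig, run_conserve, run_report, run_reporter, run_tss, run_tts
from . import synthetic_data

__version__ = "0.1.0"


def promoter_free_sequence() -> str:
    """The 100-nt inert promoter-free sequence (PFS) used to replace native
    promoter regions without shortening the locus; shipped as a FASTA fixture."""
    ref = resources.files("txarch") / "data" / "pfs.fasta"
    lines = ref.read_text().splitlines()
    return "".join(line.strip() for line in lines if not line.startswith(">"))
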