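"""Positional TSS classification and cross-library confidence filtering.

Candidates are classified by where they fall relative to the gene annotation:

* **pTSS** — primary: intergenic, within ``upstream_window`` bp upstream of a
  same-strand gene start.
* **iTSS** — intragenic, sense: inside a same-strand gene body.
* **asTSS** — antisense: inside, or within the upstream window of, an
  opposite-strand gene only.
* **oTSS** — none of the above.

Gene-internal location dominates proximity to the next downstream start
(iTSS before pTSS): a start inside gene k of an operon is intragenic even
when gene k+1 begins shortly downstream.

A classified TSS is *confident* when its enrichment score reaches the
curation threshold (default 1.4) and at least one cross-library criterion
holds: (i) whole-transcriptome coverage steps up downstream of it, or
(ii) the 3'-end library is enriched just upstream of it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from decimal import Decimal, ROUND_HALF_UP

import numpy as np

from .io_formats import Annotation, CoverageTrack, GeneFeature
from .tss_calling import TSSCandidate

TSS_CLASSES = ("pTSS", "iTSS", "asTSS", "oTSS")

__all__ = [
    "ClassifiedTSS",
    "ClassFractions",
    "classify_tss",
    "wtss_support",
    "threeprime_support",
    "filter_confident",
    "class_fractions",
]


@dataclass(frozen=True)
class ClassifiedTSS:
    candidate: TSSCandidate
    tss_class: str
    assigned_gene: str | None
    distance_to_feature: int | None
    all_labels: tuple[str, ...] = ()
    wtss_support: bool = False
    threeprime_support: bool = False
    confident: bool = False
    whitelisted: bool = False


@dataclass(frozen=True)
class ClassFractions:
    counts: dict[str, int]
    percentages: dict[str, float]
    denominator: int
    decimals: int


def _signed_distance(position: int, gene: GeneFeature) -> int:
    """Distance from the gene's start codon in transcription direction
    (negative = the TSS lies upstream of the gene start)."""
    if gene.strand == "+":
        return position - gene.start
    return (gene.end - 1) - position


def _is_upstream_of(position: int, gene: GeneFeature, window: int) -> bool:
    d = _signed_distance(position, gene)
    return -window <= d < 0


def classify_tss(
    candidate: TSSCandidate,
    annotation: Annotation,
    upstream_window: int = 250,
) -> ClassifiedTSS:
    """Assign one of the four positional classes by first matching rule.

    Rule order: intragenic sense, primary, antisense, other.  The gene
    triggering the winning rule is recorded with its signed distance; among
    equally eligible genes the smallest |distance| wins, then lexicographic
    gene id.  Every rule that matched is kept in ``all_labels``.
    """
    pos, strand = candidate.position, candidate.strand
    contig = candidate.contig_id
    inside = annotation.overlapping(contig, pos)
    inside_sense = [g for g in inside if g.strand == strand]
    inside_anti = [g for g in inside if g.strand != strand]

    # genes whose upstream window contains the candidate
    upstream_sense: list[GeneFeature] = []
    upstream_anti: list[GeneFeature] = []
    for g in annotation.contig_features(contig):
        if _is_upstream_of(pos, g, upstream_window):
            (upstream_sense if g.strand == strand else upstream_anti).append(g)

    labels: list[str] = []
    if inside_sense:
        labels.append("iTSS")
    if upstream_sense:
        labels.append("pTSS")
    if inside_anti or upstream_anti:
        labels.append("asTSS")
    if not labels:
        labels.append("oTSS")

    def pick(genes: list[GeneFeature]) -> GeneFeature:
        return min(genes, key=lambda g: (abs(_signed_distance(pos, g)), g.gene_id))

    if inside_sense:
        tss_class = "iTSS"
        gene = pick(inside_sense)
    elif upstream_sense:
        tss_class = "pTSS"
        gene = pick(upstream_sense)
    elif inside_anti or upstream_anti:
        tss_class = "asTSS"
        gene = pick(inside_anti + upstream_anti)
    else:
        return ClassifiedTSS(candidate, "oTSS", None, None, all_labels=("oTSS",))

    return ClassifiedTSS(
        candidate,
        tss_class,
        assigned_gene=gene.gene_id,
        distance_to_feature=_signed_distance(pos, gene),
        all_labels=tuple(labels),
    )


def _strand_windows(position: int, strand: str, flank: int, n: int) -> tuple[slice, slice]:
    """(upstream, downstream) index slices in transcription orientation,
    truncated at the contig edge."""
    if strand == "+":
        up = slice(max(position - flank, 0), max(position, 0))
        down = slice(min(position + 1, n), min(position + 1 + flank, n))
    else:
        up = slice(min(position + 1, n), min(position + 1 + flank, n))
        down = slice(max(position - flank, 0), max(position, 0))
    return up, down


def wtss_support(
    tss: TSSCandidate | ClassifiedTSS,
    wtss_track: CoverageTrack,
    flank: int = 50,
    min_fold: float = 1.5,
) -> bool:
    """Criterion (i): whole-transcriptome coverage increases downstream.

    True iff mean coverage over the ``flank`` bases downstream of the TSS
    exceeds ``min_fold`` times the mean over the ``flank`` bases upstream,
    with the upstream mean floored at one pseudo-count. Windows truncated
    at the contig edge are evaluated as-is.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    cand = tss.candidate if isinstance(tss, ClassifiedTSS) else tss
    if wtss_track.strand != cand.strand:
        raise ValueError("WTSS track strand does not match the TSS strand")
    counts = wtss_track.counts
    up, down = _strand_windows(cand.position, cand.strand, flank, len(counts))
    down_vals = counts[down]
    if down_vals.size == 0:
        return False
    up_vals = counts[up]
    up_mean = max(float(up_vals.mean()) if up_vals.size else 0.0, 1.0)
    return float(down_vals.mean()) > min_fold * up_mean


def threeprime_support(
    tss: TSSCandidate | ClassifiedTSS,
    three_prime_track: CoverageTrack,
    upstream_window: int = 100,
    min_peak_fraction: float = 0.1,
    min_abs_peak: float = 5.0,
) -> bool:
    """Criterion (ii): 3'-end enrichment upstream of the TSS.

    A local-enrichment proxy: the maximal 3'-end count within
    ``upstream_window`` bases upstream must reach ``min_peak_fraction``
    of the track's 99th-percentile nonzero count (its typical peak
    height), and never less than ``min_abs_peak`` reads so that sparse
    single-read background cannot trigger support.
    """
    cand = tss.candidate if isinstance(tss, ClassifiedTSS) else tss
    if three_prime_track.strand != cand.strand:
        raise ValueError("3'-end track strand does not match the TSS strand")
    counts = three_prime_track.counts
    nonzero = counts[counts > 0]
    if nonzero.size == 0:
        return False
    threshold = max(min_peak_fraction * float(np.percentile(nonzero, 99)), min_abs_peak)
    up, _down = _strand_windows(cand.position, cand.strand, upstream_window, len(counts))
    window_vals = counts[up]
    if window_vals.size == 0:
        return False
    return float(window_vals.max()) >= threshold


def filter_confident(
    classified: list[ClassifiedTSS],
    curation_threshold: float = 1.4,
    whitelist: set[tuple[int, str]] | None = None,
) -> list[ClassifiedTSS]:
    """Keep TSS passing the curation score AND at least one support criterion.

    Survivors get ``confident=True``.  Whitelisted (0-based position, strand)
    pairs — the hook for manually curated sites that miss the automatic
    threshold — are retained with ``confident=False, whitelisted=True``.
    """
    whitelist = whitelist or set()
    out: list[ClassifiedTSS] = []
    for t in classified:
        passes = (
            t.candidate.enrichment_score >= curation_threshold
            and (t.wtss_support or t.threeprime_support)
        )
        if passes:
            out.append(replace(t, confident=True))
        elif (t.candidate.position, t.candidate.strand) in whitelist:
            out.append(replace(t, confident=False, whitelisted=True))
    return out


def class_fractions(
    classified: "list[ClassifiedTSS] | dict[str, int]",
    decimals: int = 1,
) -> ClassFractions:
    """Per-class counts and half-up-rounded percentages.

    Accepts either a classified TSS list or pre-tallied per-class counts
    (the form printed in genome-wide summaries).
    """
    if isinstance(classified, dict):
        counts = {c: int(classified.get(c, 0)) for c in TSS_CLASSES}
    else:
        counts = {c: 0 for c in TSS_CLASSES}
        for t in classified:
            counts[t.tss_class] += 1
    denominator = sum(counts.values())
    if denominator == 0:
        raise ValueError("cannot compute class fractions of an empty set")
    q = Decimal(1).scaleb(-decimals)
    percentages = {
        c: float(
            (Decimal(100 * n) / Decimal(denominator)).quantize(q, rounding=ROUND_HALF_UP)
        )
        for c, n in counts.items()
    }
    return ClassFractions(counts, percentages, denominator, decimals)
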