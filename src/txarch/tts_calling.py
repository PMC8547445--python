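"""Transcription termination site calling and per-operon architecture summary.

A TTS is called where a 3'-end sequencing peak (>= ``min_peak`` reads,
local maximum) sits near the end of a same-strand coding sequence and the
whole-transcriptome coverage drops across it: mean WTSS downstream of the
peak at most ``max_drop_ratio`` times the mean upstream.  The near-gene-end
constraint spans from ``inside_window`` bases inside the CDS (terminators
are sometimes mapped within the last stretch of the gene) to
``downstream_window`` bases past its stop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import Annotation, CoverageTrack, GeneFeature
from .tss_annotation import ClassifiedTSS, _strand_windows

__all__ = ["TTSCall", "TranscriptionalUnit", "OperonReport", "call_tts", "summarize_architecture"]


@dataclass(frozen=True)
class TTSCall:
    contig_id: str
    position: int
    strand: str
    peak_count: float
    assigned_gene: str
    wtss_drop_ratio: float


@dataclass(frozen=True)
class TranscriptionalUnit:
    """One promoter-to-terminator span (0-based half-open genomic interval)."""

    start: int
    end: int
    strand: str
    opened_by: int          # TSS position (0-based)
    tss_class: str
    closed_by_tts: bool     # False = runs to the operon boundary


@dataclass(frozen=True)
class OperonReport:
    name: str
    contig_id: str
    strand: str
    span: tuple[int, int]
    tss: tuple[ClassifiedTSS, ...]
    tts: tuple[TTSCall, ...]
    units: tuple[TranscriptionalUnit, ...]


def _gene_stop_boundary(gene: GeneFeature) -> int:
    """Coordinate of the gene's 3' (stop-codon-side) boundary."""
    return gene.end - 1 if gene.strand == "+" else gene.start


def call_tts(
    three_prime: CoverageTrack,
    wtss: CoverageTrack,
    annotation: Annotation,
    min_peak: float = 2500,
    downstream_window: int = 150,
    inside_window: int = 200,
    flank: int = 50,
    max_drop_ratio: float = 0.5,
    collapse_window: int = 10,
) -> list[TTSCall]:
    """Call termination sites on one contig/strand.

    A position ``p`` is called iff all of:

    a. ``three_prime[p] >= min_peak``;
    b. ``p`` falls between ``inside_window`` bases inside and
       ``downstream_window`` bases past the 3' end of a same-strand gene
       (that gene — nearest such end — is assigned);
    c. mean WTSS over the ``flank`` bases downstream of ``p`` is at most
       ``max_drop_ratio`` times the mean over the ``flank`` bases upstream
       (upstream mean floored at 1 pseudo-count).

    Peaks within ``collapse_window`` bp collapse to the maximum (leftmost
    on ties).
    """
    if min_peak <= 0:
        raise ValueError("min_peak must be positive")
    if three_prime.strand != wtss.strand or three_prime.contig_id != wtss.contig_id:
        raise ValueError("3'-end and WTSS tracks must share contig and strand")
    strand = three_prime.strand
    genes = [
        g
        for g in annotation.contig_features(three_prime.contig_id)
        if g.strand == strand
    ]
    if not genes:
        return []

    counts = three_prime.counts
    n = len(counts)
    candidates = np.flatnonzero(counts >= min_peak)

    calls: list[TTSCall] = []
    for p in candidates:
        p = int(p)
        near = []
        for g in genes:
            boundary = _gene_stop_boundary(g)
            if strand == "+":
                lo, hi = boundary - inside_window, boundary + downstream_window
            else:
                lo, hi = boundary - downstream_window, boundary + inside_window
            if lo <= p <= hi:
                near.append((abs(p - boundary), g.gene_id, g))
        if not near:
            continue
        gene = min(near)[2]

        up, down = _strand_windows(p, strand, flank, len(wtss.counts))
        down_vals = wtss.counts[down]
        up_vals = wtss.counts[up]
        up_mean = max(float(up_vals.mean()) if up_vals.size else 0.0, 1.0)
        down_mean = float(down_vals.mean()) if down_vals.size else 0.0
        ratio = down_mean / up_mean
        if ratio > max_drop_ratio:
            continue
        calls.append(
            TTSCall(
                contig_id=three_prime.contig_id,
                position=p,
                strand=strand,
                peak_count=float(counts[p]),
                assigned_gene=gene.gene_id,
                wtss_drop_ratio=ratio,
            )
        )
    return _collapse_peaks(calls, collapse_window)


def _collapse_peaks(calls: list[TTSCall], window: int) -> list[TTSCall]:
    if window <= 0 or not calls:
        return calls
    out: list[TTSCall] = []
    cluster = [calls[0]]
    for c in calls[1:]:
        if c.position - cluster[-1].position <= window:
            cluster.append(c)
        else:
            out.append(max(cluster, key=lambda x: (x.peak_count, -x.position)))
            cluster = [c]
    out.append(max(cluster, key=lambda x: (x.peak_count, -x.position)))
    return out


def summarize_architecture(
    classified_tss: list[ClassifiedTSS],
    tts_calls: list[TTSCall],
    annotation: Annotation,
    operon_definitions: dict[str, list[str]],
) -> list[OperonReport]:
    """Assemble a per-operon transcriptional-architecture report.

    Each confident (or manually whitelisted) sense TSS assigned to an operon
    gene opens a transcriptional unit; the unit closes at the next
    downstream called TTS assigned to the operon, or at the operon boundary.
    Antisense TSS are reported but open no sense unit.
    """
    reports: list[OperonReport] = []
    for name, gene_ids in operon_definitions.items():
        try:
            genes = [annotation.get(g) for g in gene_ids]
        except KeyError as exc:
            raise KeyError(f"operon {name!r}: {exc.args[0]}") from None
        contig = genes[0].contig_id
        strand = genes[0].strand
        span = (min(g.start for g in genes), max(g.end for g in genes))
        id_set = set(gene_ids)

        op_tss = sorted(
            (t for t in classified_tss if t.assigned_gene in id_set),
            key=lambda t: t.candidate.position,
        )
        op_tts = sorted(
            (t for t in tts_calls if t.assigned_gene in id_set),
            key=lambda t: t.position,
        )
        sense = [
            t
            for t in op_tss
            if t.candidate.strand == strand
            and t.tss_class in ("pTSS", "iTSS")
            and (t.confident or t.whitelisted)
        ]

        units: list[TranscriptionalUnit] = []
        for t in sense:
            pos = t.candidate.position
            if strand == "+":
                closers = [x.position for x in op_tts if x.strand == strand and x.position > pos]
                end = min(closers) if closers else max(span[1], pos + 1)
                unit = TranscriptionalUnit(
                    pos, end + 1 if closers else end, strand, pos, t.tss_class, bool(closers)
                )
            else:
                closers = [x.position for x in op_tts if x.strand == strand and x.position < pos]
                start = max(closers) if closers else min(span[0], pos)
                unit = TranscriptionalUnit(
                    start, pos + 1, strand, pos, t.tss_class, bool(closers)
                )
            units.append(unit)
        reports.append(
            OperonReport(
                name=name,
                contig_id=contig,
                strand=strand,
                span=span,
                tss=tuple(op_tss),
                tts=tuple(op_tts),
                units=tuple(units),
            )
        )
    return reports
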