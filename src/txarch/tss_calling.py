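"""TSS candidate calling from paired 5'-enriched / 5'-control coverage.

The 5'-enriched library (Cappable-seq style: 5'-triphosphate ends captured and
streptavidin-enriched) concentrates reads at genuine transcription initiation
sites; processed 5' monophosphate ends appear equally in the uncapped control.
Per-position counts are depth-normalized to a relative read score
(RRS, reads-per-million) and a putative TSS is annotated wherever

    enrichment_score = log2(RRS / RRS_control)

exceeds the threshold (> 1 for the permissive set; >= 1.4 for the curated
set, applied downstream with cross-library support).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .io_formats import CoverageTrack

__all__ = ["TSSCandidate", "compute_rrs", "enrichment_score", "call_candidates"]


@dataclass(frozen=True)
class TSSCandidate:
    """A putative TSS: position of the first transcribed nucleotide (0-based)."""

    contig_id: str
    position: int
    strand: str
    raw_count: float
    rrs: float
    rrs_control: float
    enrichment_score: float


def compute_rrs(track: CoverageTrack) -> CoverageTrack:
    """Depth-normalize counts to reads-per-million (the relative read score).

    rrs[i] = counts[i] / total_mapped_reads * 1e6.  Idempotent on already
    normalized tracks is deliberately NOT assumed: pass raw tracks.
    """
    if track.total_mapped_reads is None or track.total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be positive for RRS normalization")
    return CoverageTrack(
        contig_id=track.contig_id,
        strand=track.strand,
        counts=track.counts / track.total_mapped_reads * 1e6,
        library_type=track.library_type,
        total_mapped_reads=track.total_mapped_reads,
        normalized=True,
    )


def enrichment_score(rrs: float, rrs_control: float, control_floor: float = 1.0) -> float:
    """log2 ratio of enriched to control RRS, with a floor on the control.

    The floor (default: the RRS of a single control read is a sensible
    caller-supplied value) guards against division by zero at positions the
    control library did not sample.  ``rrs == 0`` returns ``-inf``.
    """
    if rrs < 0 or rrs_control < 0:
        raise ValueError("RRS values must be non-negative")
    if control_floor <= 0:
        raise ValueError("control_floor must be positive")
    if rrs == 0:
        return float("-inf")
    return math.log2(rrs / max(rrs_control, control_floor))


def call_candidates(
    enriched: CoverageTrack,
    control: CoverageTrack,
    min_score: float = 1.0,
    min_raw_count: int = 5,
    cluster_window: int = 5,
    control_floor: float | None = None,
    raw_enriched: CoverageTrack | None = None,
) -> list[TSSCandidate]:
    """Call TSS candidates where the enrichment score exceeds ``min_score``.

    Both tracks must already be RRS-normalized and share contig and strand.
    Candidates within ``cluster_window`` bp on the same strand are collapsed
    to the position of maximal RRS (leftmost on ties).  ``min_raw_count``
    suppresses single-read artifacts; raw counts are reconstructed from the
    track's depth unless ``raw_enriched`` supplies them directly.

    The default ``control_floor`` is the RRS of a single read in the control
    library (1e6 / control depth).
    """
    if enriched.contig_id != control.contig_id:
        raise ValueError(
            f"contig mismatch: {enriched.contig_id!r} vs {control.contig_id!r}"
        )
    if enriched.strand != control.strand:
        raise ValueError(f"strand mismatch: {enriched.strand!r} vs {control.strand!r}")
    if not (enriched.normalized and control.normalized):
        raise ValueError("both tracks must be RRS-normalized (see compute_rrs)")
    if control_floor is None:
        control_floor = 1e6 / control.total_mapped_reads

    n = min(len(enriched.counts), len(control.counts))
    rrs = enriched.counts[:n]
    rrs_ctl = control.counts[:n]
    if raw_enriched is not None:
        raw = raw_enriched.counts[:n]
    else:
        raw = rrs * enriched.total_mapped_reads / 1e6

    with np.errstate(divide="ignore"):
        score = np.log2(rrs / np.maximum(rrs_ctl, control_floor))
    passing = np.flatnonzero((score > min_score) & (raw >= min_raw_count))

    candidates = [
        TSSCandidate(
            contig_id=enriched.contig_id,
            position=int(p),
            strand=enriched.strand,
            raw_count=float(raw[p]),
            rrs=float(rrs[p]),
            rrs_control=float(rrs_ctl[p]),
            enrichment_score=float(score[p]),
        )
        for p in passing
    ]
    return _collapse_clusters(candidates, cluster_window)


def _collapse_clusters(candidates: list[TSSCandidate], window: int) -> list[TSSCandidate]:
    """Greedy left-to-right collapse: neighbors within ``window`` bp merge,
    keeping the maximal-RRS member (leftmost on ties)."""
    if window <= 0 or not candidates:
        return candidates
    out: list[TSSCandidate] = []
    cluster: list[TSSCandidate] = [candidates[0]]
    for cand in candidates[1:]:
        if cand.position - cluster[-1].position <= window:
            cluster.append(cand)
        else:
            out.append(max(cluster, key=lambda c: (c.rrs, -c.position)))
            cluster = [cand]
    out.append(max(cluster, key=lambda c: (c.rrs, -c.position)))
    return out
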