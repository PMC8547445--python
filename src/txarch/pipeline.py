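"""Stage orchestration: thresholds in one config object, both strands per run.

`PipelineConfig` carries every tunable of the chain (candidate score > 1,
curation score >= 1.4, 2,500-read terminator peak, 150-bp downstream window,
-50..-5 promoter offsets, ...), can be loaded from a flat key=value text
file, and is echoed into a machine-readable run manifest next to the
outputs so a run is reproducible from its own records.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import conservation, reporter, tss_annotation, tss_calling, tts_calling
from .io_formats import Annotation, CoverageTrack, GenomeRecord
from .tss_annotation import ClassifiedTSS, ClassFractions
from .tts_calling import OperonReport, TTSCall

__all__ = [
    "PipelineConfig",
    "read_whitelist",
    "run_tss",
    "run_tts",
    "run_report",
    "run_reporter",
    "run_conserve",
]


@dataclass(frozen=True)
class PipelineConfig:
    # TSS calling
    min_score: float = 1.0
    min_raw_count: int = 5
    cluster_window: int = 5
    # classification / confidence
    upstream_window: int = 250
    curation_threshold: float = 1.4
    wtss_flank: int = 50
    wtss_min_fold: float = 1.5
    threeprime_window: int = 100
    min_peak_fraction: float = 0.1
    # TTS calling
    tts_min_peak: float = 2500.0
    tts_downstream_window: int = 150
    tts_inside_window: int = 200
    tts_flank: int = 50
    max_drop_ratio: float = 0.5
    # reporter
    od_floor: float = 0.01
    smooth_window: int = 3
    # conservation
    align_match: float = 1.0
    align_mismatch: float = -1.0
    align_gap: float = -2.0
    window_from: int = -50
    window_to: int = -5
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Flat ``key = value`` text config; unknown keys are rejected."""
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        values: dict[str, object] = {}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.split("#")[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected 'key = value'")
                key, value = (part.strip() for part in line.split("=", 1))
                if key not in fields:
                    raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
                target = fields[key]
                values[key] = int(value) if "int" in str(target) else float(value)
        return cls(**values)

    def manifest(self, inputs: dict[str, str]) -> dict:
        cfg = dataclasses.asdict(self)
        digest = hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest()[:16]
        return {"config": cfg, "config_hash": digest, "inputs": inputs}


def read_whitelist(path: str | Path) -> set[tuple[int, str]]:
    """Manual-curation whitelist: one '1-based-position strand' per line;
    returned 0-based."""
    out: set[tuple[int, str]] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#")[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2 or parts[1] not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: expected '<1-based position> <strand>'")
            out.add((int(parts[0]) - 1, parts[1]))
    return out


def _classify_strand(
    enriched: CoverageTrack,
    control: CoverageTrack,
    wtss: CoverageTrack,
    three_prime: CoverageTrack,
    annotation: Annotation,
    config: PipelineConfig,
) -> list[ClassifiedTSS]:
    enriched_rrs = tss_calling.compute_rrs(enriched)
    control_rrs = tss_calling.compute_rrs(control)
    candidates = tss_calling.call_candidates(
        enriched_rrs,
        control_rrs,
        min_score=config.min_score,
        min_raw_count=config.min_raw_count,
        cluster_window=config.cluster_window,
    )
    out: list[ClassifiedTSS] = []
    for cand in candidates:
        classified = tss_annotation.classify_tss(
            cand, annotation, upstream_window=config.upstream_window
        )
        classified = dataclasses.replace(
            classified,
            wtss_support=tss_annotation.wtss_support(
                cand, wtss, flank=config.wtss_flank, min_fold=config.wtss_min_fold
            ),
            threeprime_support=tss_annotation.threeprime_support(
                cand,
                three_prime,
                upstream_window=config.threeprime_window,
                min_peak_fraction=config.min_peak_fraction,
            ),
        )
        out.append(classified)
    return out


def run_tss(
    annotation: Annotation,
    enriched: dict[str, CoverageTrack],
    control: dict[str, CoverageTrack],
    wtss: dict[str, CoverageTrack],
    three_prime: dict[str, CoverageTrack],
    config: PipelineConfig | None = None,
    whitelist: set[tuple[int, str]] | None = None,
) -> tuple[list[ClassifiedTSS], list[ClassifiedTSS], ClassFractions]:
    """Candidate calling, classification and confidence filtering, both strands.

    Track dicts are keyed by strand.  Returns (all classified putative TSS,
    the confident/whitelisted subset, class fractions over the putative set).
    """
    config = config or PipelineConfig()
    classified: list[ClassifiedTSS] = []
    for strand in sorted(enriched):
        for name, tracks in (
            ("control", control), ("wtss", wtss), ("three_prime", three_prime),
        ):
            if strand not in tracks:
                raise ValueError(f"TSS stage: missing {name} track for strand {strand!r}")
        classified.extend(
            _classify_strand(
                enriched[strand], control[strand], wtss[strand], three_prime[strand],
                annotation, config,
            )
        )
    classified.sort(key=lambda t: (t.candidate.position, t.candidate.strand))
    confident = tss_annotation.filter_confident(
        classified, curation_threshold=config.curation_threshold, whitelist=whitelist
    )
    fractions = tss_annotation.class_fractions(classified)
    return classified, confident, fractions


def run_tts(
    annotation: Annotation,
    three_prime: dict[str, CoverageTrack],
    wtss: dict[str, CoverageTrack],
    config: PipelineConfig | None = None,
) -> list[TTSCall]:
    """Terminator calling over both strands."""
    config = config or PipelineConfig()
    calls: list[TTSCall] = []
    for strand in sorted(three_prime):
        if strand not in wtss:
            raise ValueError(f"TTS stage: missing wtss track for strand {strand!r}")
        calls.extend(
            tts_calling.call_tts(
                three_prime[strand],
                wtss[strand],
                annotation,
                min_peak=config.tts_min_peak,
                downstream_window=config.tts_downstream_window,
                inside_window=config.tts_inside_window,
                flank=config.tts_flank,
                max_drop_ratio=config.max_drop_ratio,
            )
        )
    calls.sort(key=lambda c: (c.position, c.strand))
    return calls


def run_report(
    confident_tss: list[ClassifiedTSS],
    tts_calls: list[TTSCall],
    annotation: Annotation,
    operon_definitions: dict[str, list[str]],
) -> list[OperonReport]:
    return tts_calling.summarize_architecture(
        confident_tss, tts_calls, annotation, operon_definitions
    )


def run_reporter(
    plate_series,
    control_label: str,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    config = config or PipelineConfig()
    return reporter.summarize_plate(
        plate_series,
        control_label,
        od_floor=config.od_floor,
        smooth_window=config.smooth_window,
    )


def run_conserve(
    genome: GenomeRecord,
    confident_tss: list[ClassifiedTSS],
    ortholog_table: dict[str, dict[str, str | None]],
    config: PipelineConfig | None = None,
    locus_names: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Extract -50..-5 windows at confident TSS and score cross-taxon identity."""
    config = config or PipelineConfig()
    windows = []
    for t in confident_tss:
        cand = t.candidate
        locus = (locus_names or {}).get(cand.position, f"tss_{cand.position + 1}{cand.strand}")
        windows.append(
            conservation.extract_window(
                genome,
                cand.position,
                cand.strand,
                from_offset=config.window_from,
                to_offset=config.window_to,
                locus_id=locus,
            )
        )
    needed = {locus for row in ortholog_table.values() for locus in row}
    windows = [w for w in windows if w.locus_id in needed] or windows
    return conservation.identity_profile(
        windows,
        ortholog_table,
        match=config.align_match,
        mismatch=config.align_mismatch,
        gap=config.align_gap,
    )


# --------------------------------------------------------------------------
# tabular output helpers

def tts_table(calls: list[TTSCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "position": c.position + 1,
                "strand": c.strand,
                "peak_count": c.peak_count,
                "assigned_gene": c.assigned_gene,
                "wtss_drop_ratio": round(c.wtss_drop_ratio, 4),
            }
            for c in calls
        ],
        columns=["position", "strand", "peak_count", "assigned_gene", "wtss_drop_ratio"],
    )


def architecture_tables(reports: list[OperonReport]) -> tuple[pd.DataFrame, list[str]]:
    """(units TSV frame, BED lines 'operon:unit_index')."""
    rows = []
    bed: list[str] = []
    for rep in reports:
        for i, u in enumerate(rep.units, start=1):
            rows.append(
                {
                    "operon": rep.name,
                    "unit": i,
                    "start": u.start + 1,
                    "end": u.end,
                    "strand": u.strand,
                    "opened_by_tss": u.opened_by + 1,
                    "tss_class": u.tss_class,
                    "closed_by_tts": u.closed_by_tts,
                }
            )
            bed.append(
                f"{rep.contig_id}\t{u.start}\t{u.end}\t{rep.name}:{i}\t0\t{u.strand}"
            )
    frame = pd.DataFrame(
        rows,
        columns=[
            "operon", "unit", "start", "end", "strand",
            "opened_by_tss", "tss_class", "closed_by_tts",
        ],
    )
    return frame, bed
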