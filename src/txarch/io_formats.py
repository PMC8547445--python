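"""Readers/writers for the formats the pipeline touches, and the domain containers.

All internal coordinates are 0-based half-open; every file-facing surface
(GFF3, TSS/TTS tables) converts to/from 1-based inclusive at the boundary.
Coverage is strand-specific throughout: one :class:`CoverageTrack` holds one
contig, one strand, one library.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

LIBRARY_TYPES = ("five_prime_enriched", "five_prime_control", "wtss", "three_prime")

__all__ = [
    "GenomeRecord",
    "GeneFeature",
    "Annotation",
    "CoverageTrack",
    "WellSeries",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_bedgraph",
    "write_bedgraph",
    "write_tss_table",
    "read_plate_csv",
]


class FormatError(ValueError):
    """Raised for malformed input files (message names the offending line)."""


@dataclass(frozen=True)
class GenomeRecord:
    """A single contig: id plus uppercase nucleotide sequence."""

    contig_id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError(f"empty sequence for contig {self.contig_id!r}")
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)

    def reverse_complement(self) -> "GenomeRecord":
        return GenomeRecord(self.contig_id, str(Seq(self.sequence).reverse_complement()))


@dataclass(frozen=True, order=True)
class GeneFeature:
    """A gene/CDS feature in internal 0-based half-open coordinates."""

    contig_id: str
    start: int
    end: int
    strand: str
    gene_id: str
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.gene_id!r}: require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end

    @property
    def tss_proximal_end(self) -> int:
        """Genomic coordinate of the feature's 5' (start-codon-side) boundary."""
        return self.start if self.strand == "+" else self.end - 1


class Annotation:
    """An ordered, queryable collection of :class:`GeneFeature`.

    Features are kept sorted by (contig, start); per-contig lookups use
    binary search over start/end arrays, which is ample at the scale of a
    bacterial genome annotation.
    """

    def __init__(self, features: Iterable[GeneFeature]):
        self.features: list[GeneFeature] = sorted(
            features, key=lambda f: (f.contig_id, f.start, f.end, f.gene_id)
        )
        self._by_contig: dict[str, list[GeneFeature]] = {}
        for f in self.features:
            self._by_contig.setdefault(f.contig_id, []).append(f)
        self._starts = {
            c: np.array([f.start for f in fs]) for c, fs in self._by_contig.items()
        }
        self._max_len = {
            c: max((len(f) for f in fs), default=0) for c, fs in self._by_contig.items()
        }

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self) -> Iterator[GeneFeature]:
        return iter(self.features)

    def contig_features(self, contig_id: str) -> list[GeneFeature]:
        return self._by_contig.get(contig_id, [])

    def overlapping(self, contig_id: str, position: int, strand: str | None = None) -> list[GeneFeature]:
        """All features containing ``position`` (optionally restricted to a strand)."""
        fs = self._by_contig.get(contig_id)
        if not fs:
            return []
        starts = self._starts[contig_id]
        # only features starting within max feature length of `position` can contain it
        lo = int(np.searchsorted(starts, position - self._max_len[contig_id], side="left"))
        hi = int(np.searchsorted(starts, position, side="right"))
        out = [f for f in fs[lo:hi] if f.contains(position)]
        if strand is not None:
            out = [f for f in out if f.strand == strand]
        return out

    def get(self, gene_id: str) -> GeneFeature:
        for f in self.features:
            if f.gene_id == gene_id:
                return f
        raise KeyError(f"gene {gene_id!r} not in annotation")


@dataclass
class CoverageTrack:
    """Strand-specific per-base counts for one contig and one library.

    ``total_mapped_reads`` is the depth normalizer; when not supplied it
    defaults to the sum of the track's counts.
    """

    contig_id: str
    strand: str
    counts: np.ndarray
    library_type: str
    total_mapped_reads: float | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.library_type not in LIBRARY_TYPES:
            raise ValueError(f"unknown library_type {self.library_type!r}")
        if np.any(self.counts < 0):
            raise ValueError("coverage counts must be non-negative")
        if self.total_mapped_reads is None:
            self.total_mapped_reads = float(self.counts.sum())
        if not self.normalized and self.total_mapped_reads <= 0:
            # an all-zero raw track is legal; keep a unit normalizer
            self.total_mapped_reads = 1.0

    def __len__(self) -> int:
        return len(self.counts)


@dataclass
class WellSeries:
    """One plate-reader well: aligned time / OD565 / light vectors."""

    well_id: str
    label: str
    time_h: np.ndarray
    od565: np.ndarray
    light_au: np.ndarray
    replicate_id: str = ""

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.od565 = np.asarray(self.od565, dtype=float)
        self.light_au = np.asarray(self.light_au, dtype=float)
        if not (len(self.time_h) == len(self.od565) == len(self.light_au)):
            raise ValueError(f"well {self.well_id!r}: unequal vector lengths")
        if len(self.time_h) > 1 and np.any(np.diff(self.time_h) <= 0):
            raise FormatError(f"well {self.well_id!r}: time must be strictly increasing")

    def __len__(self) -> int:
        return len(self.time_h)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[GenomeRecord]:
    records = [GenomeRecord(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.contig_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3

_GFF_TYPES = {"gene", "CDS"}


def read_gff3(path: str | Path, feature_types: set[str] | None = None) -> Annotation:
    """Parse gene/CDS features from a GFF3 file.

    GFF3 1-based inclusive coordinates become internal 0-based half-open.
    The ``ID`` (falling back to ``locus_tag``/``Name``) attribute supplies
    ``gene_id``; ``Name`` supplies the display name.
    """
    feature_types = feature_types or _GFF_TYPES
    features: list[GeneFeature] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 tab-separated columns, got {len(fields)}")
            contig, _source, ftype, start_s, end_s, _score, strand, _frame, attrs = fields
            if ftype not in feature_types:
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: unknown strand {strand!r}")
            if start1 > end1:
                raise FormatError(
                    f"{path}:{lineno}: start > end ({start1} > {end1}); "
                    "features crossing the origin of a circular chromosome are not supported"
                )
            attr = _parse_attributes(attrs)
            gene_id = attr.get("ID") or attr.get("locus_tag") or attr.get("Name")
            if not gene_id:
                raise FormatError(f"{path}:{lineno}: feature has no ID/locus_tag/Name attribute")
            features.append(
                GeneFeature(
                    contig_id=contig,
                    start=start1 - 1,
                    end=end1,
                    strand=strand,
                    gene_id=gene_id,
                    name=attr.get("Name", ""),
                )
            )
    return Annotation(features)


def _parse_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part or "=" not in part:
            continue
        key, value = part.split("=", 1)
        out[key] = value
    return out


def write_gff3(annotation: Annotation, path: str | Path, feature_type: str = "gene") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in annotation:
            attrs = f"ID={f.gene_id}"
            if f.name:
                attrs += f";Name={f.name}"
            fh.write(
                f"{f.contig_id}\ttxarch\t{feature_type}\t{f.start + 1}\t{f.end}\t.\t{f.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# bedGraph

def read_bedgraph(
    path: str | Path,
    library_type: str,
    strand: str,
    total_mapped_reads: float | None = None,
    contig_length: int | None = None,
) -> CoverageTrack:
    """Read one strand-specific bedGraph into a dense counts array.

    Intervals must be 0-based half-open, non-overlapping and non-negative;
    positions absent from the file are zero.
    """
    contig: str | None = None
    intervals: list[tuple[int, int, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            c, s, e, v = fields
            try:
                start, end, value = int(s), int(e), float(v)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed interval") from exc
            if value < 0:
                raise FormatError(f"{path}:{lineno}: negative coverage value {value}")
            if start < 0 or end <= start:
                raise FormatError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            if contig is None:
                contig = c
            elif c != contig:
                raise FormatError(f"{path}:{lineno}: multiple contigs in one track ({contig!r}, {c!r})")
            intervals.append((start, end, value))
    if contig is None:
        contig = "unknown"
    intervals.sort()
    for (s0, e0, _), (s1, _, _) in zip(intervals, intervals[1:]):
        if s1 < e0:
            raise FormatError(f"{path}: overlapping intervals at position {s1}")
    length = contig_length if contig_length is not None else (intervals[-1][1] if intervals else 0)
    counts = np.zeros(max(length, intervals[-1][1] if intervals else 0), dtype=float)
    for s0, e0, v in intervals:
        counts[s0:e0] = v
    return CoverageTrack(
        contig_id=contig,
        strand=strand,
        counts=counts,
        library_type=library_type,
        total_mapped_reads=total_mapped_reads,
    )


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Run-length-encode a track back to bedGraph (zero runs omitted)."""
    counts = track.counts
    with open(path, "w") as fh:
        if len(counts) == 0:
            return
        boundaries = np.flatnonzero(np.diff(counts)) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [len(counts)]))
        for s, e in zip(starts, ends):
            v = counts[s]
            if v != 0:
                v_out = int(v) if float(v).is_integer() else v
                fh.write(f"{track.contig_id}\t{s}\t{e}\t{v_out}\n")


# ---------------------------------------------------------------------------
# TSS table (Table-S2-style TSV)

TSS_TABLE_COLUMNS = [
    "position",
    "strand",
    "class",
    "RRS",
    "RRS_control",
    "enrichment_score",
    "assigned_gene",
    "distance_to_feature",
    "wtss_support",
    "threeprime_support",
    "confident",
]


def write_tss_table(tss_list: Sequence, path: str | Path) -> None:
    """Write classified TSS to TSV; positions are emitted 1-based."""
    rows = []
    for t in tss_list:
        cand = t.candidate
        rows.append(
            {
                "position": cand.position + 1,
                "strand": cand.strand,
                "class": t.tss_class,
                "RRS": round(cand.rrs, 4),
                "RRS_control": round(cand.rrs_control, 4),
                "enrichment_score": round(cand.enrichment_score, 4),
                "assigned_gene": t.assigned_gene or "NA",
                "distance_to_feature": t.distance_to_feature if t.assigned_gene else "NA",
                "wtss_support": t.wtss_support,
                "threeprime_support": t.threeprime_support,
                "confident": t.confident,
            }
        )
    pd.DataFrame(rows, columns=TSS_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# plate-reader CSV

PLATE_COLUMNS = {"well", "label", "time_h", "od565", "light_au"}


def read_plate_csv(path: str | Path) -> list[WellSeries]:
    """Read a long-format plate CSV into one :class:`WellSeries` per well.

    Rows may arrive unsorted; within a well, timepoints are sorted
    ascending and duplicated timepoints are an error.
    """
    df = pd.read_csv(path)
    missing = PLATE_COLUMNS - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(sorted(missing))}")
    series: list[WellSeries] = []
    for well_id, group in df.groupby("well", sort=True):
        group = group.sort_values("time_h")
        times = group["time_h"].to_numpy(dtype=float)
        if len(times) > 1 and np.any(np.diff(times) <= 0):
            raise FormatError(f"{path}: duplicate timepoints in well {well_id!r}")
        labels = group["label"].unique()
        series.append(
            WellSeries(
                well_id=str(well_id),
                label=str(labels[0]),
                time_h=times,
                od565=group["od565"].to_numpy(dtype=float),
                light_au=group["light_au"].to_numpy(dtype=float),
            )
        )
    return series


def write_plate_csv(series: Iterable[WellSeries], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["well", "label", "time_h", "od565", "light_au"])
        for s in series:
            for t, od, light in zip(s.time_h, s.od565, s.light_au):
                writer.writerow([s.well_id, s.label, f"{t:g}", f"{od:.6g}", f"{light:.6g}"])
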