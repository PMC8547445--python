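"""TSS-anchored promoter windows and cross-taxon sequence identity.

The core promoter region is taken -50 to -5 relative to a confirmed TSS
(46 nt, promoter-sense).  Each reference window is globally aligned against
the orthologous sequence supplied for every other species, and percent
identity (matched columns over all alignment columns, gaps included) fills
a species x locus matrix; species lacking the region leave a missing cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GenomeRecord

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = set("ACGTN")

__all__ = [
    "PromoterWindow",
    "Alignment",
    "extract_window",
    "global_align",
    "percent_identity",
    "identity_profile",
    "reverse_complement",
]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PromoterWindow:
    """A promoter-sense sequence window anchored at a TSS.

    Offsets are negative, counted in transcription direction; on the minus
    strand the genomic slice is mirrored downstream in genome coordinates
    and reverse-complemented so that ``sequence`` reads promoter-sense.
    """

    species_id: str
    locus_id: str
    tss_position: int
    strand: str
    from_offset: int
    to_offset: int
    sequence: str
    truncated: bool = False

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Alignment:
    aligned_a: str
    aligned_b: str
    score: float

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a)


def extract_window(
    genome: GenomeRecord,
    tss_position: int,
    strand: str,
    from_offset: int = -50,
    to_offset: int = -5,
    species_id: str = "",
    locus_id: str = "",
) -> PromoterWindow:
    """Extract the [from_offset, to_offset] window upstream of a TSS.

    Windows reaching past a contig edge are truncated and flagged; a window
    entirely off the contig is an error.
    """
    if not (from_offset < to_offset < 0):
        raise ValueError("offsets must satisfy from_offset < to_offset < 0")
    n = len(genome.sequence)
    if strand == "+":
        lo, hi = tss_position + from_offset, tss_position + to_offset + 1
    elif strand == "-":
        lo, hi = tss_position - to_offset, tss_position - from_offset + 1
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    clipped_lo, clipped_hi = max(lo, 0), min(hi, n)
    if clipped_lo >= clipped_hi:
        raise ValueError(
            f"promoter window [{lo}, {hi}) lies entirely outside contig {genome.contig_id!r}"
        )
    seq = genome.sequence[clipped_lo:clipped_hi]
    if strand == "-":
        seq = reverse_complement(seq)
    return PromoterWindow(
        species_id=species_id,
        locus_id=locus_id,
        tss_position=tss_position,
        strand=strand,
        from_offset=from_offset,
        to_offset=to_offset,
        sequence=seq,
        truncated=(clipped_lo, clipped_hi) != (lo, hi),
    )


def global_align(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
    end_gap_free: bool = False,
) -> Alignment:
    """Optimal end-to-end alignment under linear gap scoring (Needleman-Wunsch).

    Traceback is deterministic, preferring diagonal over a gap in ``b``
    ("up") over a gap in ``a`` ("left") on score ties.  With
    ``end_gap_free=True`` leading/trailing gaps are unpenalized (semiglobal;
    used when one sequence is a short window inside a longer region).
    """
    a, b = a.upper(), b.upper()
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    for name, s in (("a", a), ("b", b)):
        bad = set(s) - _VALID
        if bad:
            raise ValueError(f"sequence {name} contains non-ACGTN characters: {sorted(bad)}")

    la, lb = len(a), len(b)
    score = np.zeros((la + 1, lb + 1))
    # pointers: 0 = diagonal, 1 = up (gap in b), 2 = left (gap in a)
    ptr = np.zeros((la + 1, lb + 1), dtype=np.int8)
    edge = 0.0 if end_gap_free else gap
    score[1:, 0] = np.arange(1, la + 1) * edge
    score[0, 1:] = np.arange(1, lb + 1) * edge
    ptr[1:, 0] = 1
    ptr[0, 1:] = 2
    for i in range(1, la + 1):
        ai = a[i - 1]
        for j in range(1, lb + 1):
            sub = match if ai == b[j - 1] else mismatch
            gap_up = gap if not (end_gap_free and j == lb) else 0.0
            gap_left = gap if not (end_gap_free and i == la) else 0.0
            options = (
                score[i - 1, j - 1] + sub,
                score[i - 1, j] + gap_up,
                score[i, j - 1] + gap_left,
            )
            best = max(options)
            score[i, j] = best
            ptr[i, j] = options.index(best)  # ties resolve diag > up > left

    out_a: list[str] = []
    out_b: list[str] = []
    i, j = la, lb
    while i > 0 or j > 0:
        move = ptr[i, j]
        if move == 0 and i > 0 and j > 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
        elif move == 1 and i > 0:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
    return Alignment("".join(reversed(out_a)), "".join(reversed(out_b)), float(score[la, lb]))


def percent_identity(alignment: Alignment) -> float:
    """100 x matched columns / total alignment columns (gaps included)."""
    matches = sum(
        1 for x, y in zip(alignment.aligned_a, alignment.aligned_b) if x == y and x != "-"
    )
    return 100.0 * matches / alignment.n_columns


def identity_profile(
    reference_windows: list[PromoterWindow],
    ortholog_table: dict[str, dict[str, str | None]],
    reference_species: str = "reference",
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
    end_gap_free: bool = False,
) -> pd.DataFrame:
    """Percent identity of each species' ortholog against each reference window.

    ``ortholog_table`` maps species -> locus -> sequence (or None when the
    region was not found; the corresponding cell stays missing).  Every
    locus in the table must have a reference window.  The reference species
    row is 100 wherever defined.  With ``end_gap_free=True`` supplied
    regions may be longer than the 46-nt window; identity is then computed
    over the columns where the reference window is aligned.
    """
    by_locus = {w.locus_id: w for w in reference_windows}
    loci = [w.locus_id for w in reference_windows]
    for species, row in ortholog_table.items():
        for locus in row:
            if locus not in by_locus:
                raise KeyError(
                    f"species {species!r} names locus {locus!r} absent from the reference windows"
                )
    data: dict[str, dict[str, float]] = {reference_species: {l: 100.0 for l in loci}}
    for species, row in sorted(ortholog_table.items()):
        cells: dict[str, float] = {}
        for locus in loci:
            seq = row.get(locus)
            if seq is None or locus not in row:
                continue
            aln = global_align(
                by_locus[locus].sequence, seq,
                match=match, mismatch=mismatch, gap=gap, end_gap_free=end_gap_free,
            )
            if end_gap_free:
                cells[locus] = _windowed_identity(aln)
            else:
                cells[locus] = percent_identity(aln)
        data[species] = cells
    df = pd.DataFrame.from_dict(data, orient="index", dtype=float)
    # keep fully-missing species as all-NA rows (from_dict drops empty dicts)
    return df.reindex(index=list(data), columns=loci)


def _windowed_identity(aln: Alignment) -> float:
    """Identity over the columns spanned by sequence ``a`` (skips the
    end-gap columns a semiglobal alignment leaves around a short window)."""
    cols = [i for i, x in enumerate(aln.aligned_a) if x != "-"]
    if not cols:
        return 0.0
    lo, hi = cols[0], cols[-1] + 1
    matches = sum(
        1
        for x, y in zip(aln.aligned_a[lo:hi], aln.aligned_b[lo:hi])
        if x == y and x != "-"
    )
    return 100.0 * matches / (hi - lo)


def write_identity_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", na_rep="NA", index_label="species")
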