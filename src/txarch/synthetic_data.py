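"""Synthetic data with planted ground truth for every pipeline stage.

The generator emulates the four sequencing libraries of a bacterial
TSS/TTS-mapping experiment on a desk-scale genome:

* 5'-enriched vs 5'-control — sharp single-base count peaks at planted TSS,
  enriched over the control by a configurable factor, with +-1 nt positional
  jitter (0.1/0.8/0.1 mass); processed-RNA background sites appear with equal
  expectation in both libraries.
* WTSS — additive piecewise-constant coverage: each planted TSS raises
  coverage from its position downstream by its expression level, each
  planted terminator multiplies coverage beyond it by its read-through
  fraction; Poisson count noise throughout.
* 3'-end — count peaks at planted terminators over a sparse background.

Plus a plate-reader simulator (logistic growth, light proportional to
promoter activity x OD with a per-well lognormal scale factor) and a
promoter-divergence simulator (independent per-site substitution).

The default scenario mirrors a magnetosome-island-like layout: one 17-gene
~16-kb operon carrying one primary TSS, seven intragenic sense TSS and two
antisense TSS; a two-unit operon split by an internal terminator; and two
single-unit operons (one on the minus strand).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conservation import PromoterWindow
from .io_formats import Annotation, CoverageTrack, GeneFeature, GenomeRecord, WellSeries

__all__ = [
    "OperonSpec",
    "PlantedTSS",
    "PlantedTTS",
    "ReporterParams",
    "DivergenceParams",
    "SimulationConfig",
    "PlantedTruth",
    "SimulatedDataset",
    "default_config",
    "simulate_genome_annotation",
    "simulate_five_prime_libraries",
    "simulate_wtss",
    "simulate_three_prime",
    "simulate_reporter",
    "simulate_promoter_divergence",
    "simulate_dataset",
]

CONTIG = "synthetic_contig_1"
_JITTER = ((-1, 0.1), (0, 0.8), (1, 0.1))


@dataclass(frozen=True)
class OperonSpec:
    name: str
    start: int
    n_genes: int
    gene_length: int
    intergenic_gaps: tuple[int, ...]   # n_genes - 1 entries
    strand: str

    def gene_coords(self) -> list[tuple[int, int]]:
        coords = []
        pos = self.start
        for i in range(self.n_genes):
            coords.append((pos, pos + self.gene_length))
            if i < self.n_genes - 1:
                pos += self.gene_length + self.intergenic_gaps[i]
        return coords


@dataclass(frozen=True)
class PlantedTSS:
    position: int
    strand: str
    class_intent: str            # pTSS / iTSS / asTSS / oTSS
    enrichment_factor: float
    expression_level: float      # expected enriched reads at the site and WTSS TU depth
    operon: str = ""


@dataclass(frozen=True)
class PlantedTTS:
    position: int
    strand: str
    peak_height: float
    read_through_fraction: float
    operon: str = ""


@dataclass(frozen=True)
class ReporterParams:
    carrying_capacity: float = 0.4   # OD565 plateau (K)
    growth_rate: float = 0.15        # per hour (r)
    od0: float = 0.01
    alpha: float = 1e4               # promoter activity: planted RLU
    sigma: float = 0.1               # per-well lognormal scale noise
    n_cycles: int = 200
    interval_h: float = 1 / 3        # 20-minute cycles


@dataclass(frozen=True)
class DivergenceParams:
    substitution_rate: float = 0.2   # per-site probability m
    n_species: int = 5


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    genome_length: int = 50_000
    operons: tuple[OperonSpec, ...] = ()
    planted_tss: tuple[PlantedTSS, ...] = ()
    planted_tts: tuple[PlantedTTS, ...] = ()
    background_processed_site_rate: float = 0.2   # sites per kb
    background_site_level: float = 200.0          # expected reads, both libraries
    wtss_background: float = 2.0                  # per-base WTSS floor
    three_prime_background_rate: float = 0.02     # expected stray 3' reads per base
    library_depth: float = 1e6
    reporter: ReporterParams = field(default_factory=ReporterParams)
    divergence: DivergenceParams = field(default_factory=DivergenceParams)

    def __post_init__(self) -> None:
        for t in self.planted_tss:
            if not 0 <= t.position < self.genome_length:
                raise ValueError(f"planted TSS at {t.position} outside the genome")
            if t.enrichment_factor <= 0:
                raise ValueError("enrichment_factor must be positive")
        for t in self.planted_tts:
            if not 0 <= t.position < self.genome_length:
                raise ValueError(f"planted TTS at {t.position} outside the genome")
            if not 0 <= t.read_through_fraction <= 1:
                raise ValueError("read_through_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class PlantedTruth:
    seed: int
    tss: tuple[PlantedTSS, ...]
    tts: tuple[PlantedTTS, ...]
    background_sites: tuple[tuple[int, str], ...] = ()

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "kind": "TSS",
                "position": t.position + 1,
                "strand": t.strand,
                "detail": t.class_intent,
                "expected_score": float(np.log2(t.enrichment_factor)),
                "level": t.expression_level,
                "operon": t.operon,
            }
            for t in self.tss
        ] + [
            {
                "kind": "TTS",
                "position": t.position + 1,
                "strand": t.strand,
                "detail": f"read_through={t.read_through_fraction}",
                "expected_score": np.nan,
                "level": t.peak_height,
                "operon": t.operon,
            }
            for t in self.tts
        ]
        return pd.DataFrame(
            rows,
            columns=["kind", "position", "strand", "detail", "expected_score", "level", "operon"],
        )


def _rng(config_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config_seed, stream]))


# ---------------------------------------------------------------------------
# default scenario

def default_config(seed: int = 0) -> SimulationConfig:
    """The magnetosome-island-like study scenario (50-kb genome).

    Expression levels along the 17-gene operon escalate so that every
    stacked sense TSS still produces a detectable (>1.5-fold) step in WTSS
    coverage on top of the transcription flowing in from upstream starts.
    """
    big = OperonSpec("bigop", 3000, 17, 900, (50,) * 16, "+")
    twotu = OperonSpec("twotu", 24000, 4, 600, (30, 400, 30), "+")
    small = OperonSpec("smallop", 31000, 4, 450, (30, 30, 30), "+")
    rev = OperonSpec("revop", 38000, 3, 500, (40, 40), "-")

    big_coords = big.gene_coords()
    twotu_coords = twotu.gene_coords()
    small_coords = small.gene_coords()
    rev_coords = rev.gene_coords()

    tss: list[PlantedTSS] = [
        PlantedTSS(big_coords[0][0] - 30, "+", "pTSS", 8.0, 60.0, "bigop"),
    ]
    itss_levels = (60.0, 90.0, 150.0, 250.0, 430.0, 730.0, 1250.0)
    for gene_idx, level in zip((0, 2, 4, 6, 8, 10, 12), itss_levels):
        tss.append(
            PlantedTSS(big_coords[gene_idx][0] + 450, "+", "iTSS", 8.0, level, "bigop")
        )
    for gene_idx in (5, 9):
        tss.append(
            PlantedTSS(big_coords[gene_idx][0] + 300, "-", "asTSS", 8.0, 80.0, "bigop")
        )
    tss += [
        PlantedTSS(twotu_coords[0][0] - 30, "+", "pTSS", 8.0, 100.0, "twotu"),
        PlantedTSS(twotu_coords[2][0] - 30, "+", "pTSS", 8.0, 100.0, "twotu"),
        PlantedTSS(small_coords[0][0] - 30, "+", "pTSS", 8.0, 120.0, "smallop"),
        PlantedTSS(rev_coords[-1][1] + 30, "-", "pTSS", 8.0, 120.0, "revop"),
    ]
    tts = [
        PlantedTTS(big_coords[-1][1] + 40, "+", 4000.0, 0.02, "bigop"),
        PlantedTTS(twotu_coords[1][1] + 40, "+", 3000.0, 0.05, "twotu"),
        PlantedTTS(twotu_coords[-1][1] + 40, "+", 3000.0, 0.02, "twotu"),
        PlantedTTS(small_coords[-1][1] + 40, "+", 3000.0, 0.02, "smallop"),
        PlantedTTS(rev_coords[0][0] - 40, "-", 3000.0, 0.02, "revop"),
    ]
    return SimulationConfig(
        seed=seed,
        operons=(big, twotu, small, rev),
        planted_tss=tuple(tss),
        planted_tts=tuple(tts),
    )


DEFAULT_OPERON_GENES = {
    "bigop": [f"bigop_g{i + 1:02d}" for i in range(17)],
    "twotu": [f"twotu_g{i + 1:02d}" for i in range(4)],
    "smallop": [f"smallop_g{i + 1:02d}" for i in range(4)],
    "revop": [f"revop_g{i + 1:02d}" for i in range(3)],
}


# ---------------------------------------------------------------------------
# genome + annotation

def simulate_genome_annotation(config: SimulationConfig) -> tuple[GenomeRecord, Annotation]:
    """Random (seeded) genome sequence with the configured operon layout."""
    rng = _rng(config.seed, 1)
    seq = "".join(rng.choice(list("ACGT"), size=config.genome_length))
    features: list[GeneFeature] = []
    for op in config.operons:
        for i, (start, end) in enumerate(op.gene_coords()):
            if end > config.genome_length:
                raise ValueError(f"operon {op.name!r} extends past the genome end")
            features.append(
                GeneFeature(
                    contig_id=CONTIG,
                    start=start,
                    end=end,
                    strand=op.strand,
                    gene_id=f"{op.name}_g{i + 1:02d}",
                    name=f"{op.name}_g{i + 1:02d}",
                )
            )
    ordered = sorted(features, key=lambda f: f.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end:
            raise ValueError(f"genes {a.gene_id!r} and {b.gene_id!r} overlap")
    return GenomeRecord(CONTIG, seq), Annotation(features)


def planted_truth(config: SimulationConfig) -> PlantedTruth:
    rng = _rng(config.seed, 2)
    n_bg = rng.poisson(config.background_processed_site_rate * config.genome_length / 1000)
    positions = sorted(rng.integers(0, config.genome_length, size=n_bg))
    strands = rng.choice(["+", "-"], size=n_bg)
    return PlantedTruth(
        seed=config.seed,
        tss=config.planted_tss,
        tts=config.planted_tts,
        background_sites=tuple((int(p), str(s)) for p, s in zip(positions, strands)),
    )


# ---------------------------------------------------------------------------
# sequencing libraries

def _add_jittered_peak(counts: np.ndarray, rng: np.random.Generator, position: int, level: float) -> None:
    for offset, mass in _JITTER:
        p = position + offset
        if 0 <= p < len(counts):
            counts[p] += rng.poisson(level * mass)


def simulate_five_prime_libraries(
    config: SimulationConfig,
    truth: PlantedTruth,
    strand: str = "+",
) -> tuple[CoverageTrack, CoverageTrack]:
    """Enriched and control 5'-end tracks for one strand.

    Planted TSS receive Poisson counts at ``expression_level x depth_scale``
    in the enriched library and the same over ``enrichment_factor`` in the
    control; processed-RNA background sites receive equal expectation in
    both.  ``depth_scale`` is 1 at the default 1e6 depth.
    """
    if config.library_depth <= 0:
        raise ValueError("library_depth must be positive")
    depth_scale = config.library_depth / 1e6
    rng_e = _rng(config.seed, 10 if strand == "+" else 11)
    rng_c = _rng(config.seed, 12 if strand == "+" else 13)
    n = config.genome_length
    enriched = np.zeros(n)
    control = np.zeros(n)
    for t in truth.tss:
        if t.strand != strand:
            continue
        level = t.expression_level * depth_scale
        _add_jittered_peak(enriched, rng_e, t.position, level)
        _add_jittered_peak(control, rng_c, t.position, level / t.enrichment_factor)
    for pos, s in truth.background_sites:
        if s != strand:
            continue
        level = config.background_site_level * depth_scale
        _add_jittered_peak(enriched, rng_e, pos, level)
        _add_jittered_peak(control, rng_c, pos, level)
    make = lambda counts, lib: CoverageTrack(
        CONTIG, strand, counts, lib, total_mapped_reads=config.library_depth
    )
    return make(enriched, "five_prime_enriched"), make(control, "five_prime_control")


def _expected_wtss(config: SimulationConfig, truth: PlantedTruth, strand: str) -> np.ndarray:
    n = config.genome_length
    expected = np.full(n, config.wtss_background)
    events: list[tuple[int, int, float]] = []  # (direction-ordered key, kind, value)
    for t in truth.tss:
        if t.strand == strand:
            events.append((t.position, 0, t.expression_level))
    for t in truth.tts:
        if t.strand == strand:
            events.append((t.position, 1, t.read_through_fraction))
    if not events:
        return expected
    level = 0.0
    if strand == "+":
        events.sort(key=lambda e: (e[0], e[1]))
        prev = 0
        for pos, kind, value in events:
            boundary = pos if kind == 0 else pos + 1
            expected[prev:boundary] += level
            level = level + value if kind == 0 else level * value
            prev = boundary
        expected[prev:] += level
    else:
        # walk right-to-left; a TSS covers positions <= pos, a terminator's
        # effect begins at pos - 1 and leftward
        events.sort(key=lambda e: (-e[0], e[1]))
        prev = n
        for pos, kind, value in events:
            boundary = pos + 1 if kind == 0 else pos
            expected[boundary:prev] += level
            level = level + value if kind == 0 else level * value
            prev = boundary
        expected[:prev] += level
    return expected


def simulate_wtss(
    config: SimulationConfig,
    truth: PlantedTruth,
    strand: str = "+",
) -> CoverageTrack:
    """Whole-transcriptome coverage: Poisson noise around the additive
    piecewise-constant expectation defined by planted TSS and terminators."""
    rng = _rng(config.seed, 20 if strand == "+" else 21)
    expected = _expected_wtss(config, truth, strand)
    counts = rng.poisson(expected).astype(float)
    return CoverageTrack(CONTIG, strand, counts, "wtss", total_mapped_reads=config.library_depth)


def simulate_three_prime(
    config: SimulationConfig,
    truth: PlantedTruth,
    strand: str = "+",
) -> CoverageTrack:
    """3'-end counts: Poisson(peak_height) at each planted terminator with
    small +-1 shoulders, over a sparse uniform background."""
    rng = _rng(config.seed, 30 if strand == "+" else 31)
    n = config.genome_length
    counts = rng.poisson(config.three_prime_background_rate, size=n).astype(float)
    for t in truth.tts:
        if t.strand != strand:
            continue
        counts[t.position] += rng.poisson(t.peak_height)
        for offset in (-1, 1):
            p = t.position + offset
            if 0 <= p < n:
                counts[p] += rng.poisson(0.05 * t.peak_height)
    return CoverageTrack(CONTIG, strand, counts, "three_prime", total_mapped_reads=config.library_depth)


# ---------------------------------------------------------------------------
# reporter assay

def simulate_reporter(
    alpha: float,
    params: ReporterParams | None = None,
    seed: int = 0,
    label: str = "promoter",
    well_id: str = "A1",
    background_light: float = 0.0,
    spike_prob: float = 0.0,
    spike_factor: float = 50.0,
) -> WellSeries:
    """One plate-reader well: logistic growth, promoter-proportional light.

    OD follows logistic growth from ``od0`` to ``carrying_capacity``; light
    is ``alpha x OD`` times a single per-well lognormal scale factor
    (clone-to-clone variability), plus an optional additive background and
    optional isolated detector spikes (``spike_prob`` per timepoint).
    """
    p = params or ReporterParams()
    if not (p.carrying_capacity > p.od0 > 0) or p.growth_rate <= 0:
        raise ValueError("require carrying_capacity > od0 > 0 and growth_rate > 0")
    if alpha < 0 or p.sigma < 0:
        raise ValueError("alpha and sigma must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 40]))
    t = np.arange(p.n_cycles) * p.interval_h
    growth = np.exp(p.growth_rate * t)
    od = p.carrying_capacity * p.od0 * growth / (
        p.carrying_capacity + p.od0 * (growth - 1)
    )
    scale = float(rng.lognormal(0.0, p.sigma)) if p.sigma > 0 else 1.0
    light = alpha * od * scale + background_light
    if spike_prob > 0:
        spikes = rng.random(p.n_cycles) < spike_prob
        light = np.where(spikes, light * spike_factor, light)
    return WellSeries(well_id=well_id, label=label, time_h=t, od565=od, light_au=light)


# ---------------------------------------------------------------------------
# promoter divergence

def simulate_promoter_divergence(
    window: PromoterWindow,
    m: float,
    n_species: int,
    seed: int = 0,
) -> dict[str, dict[str, str]]:
    """Ortholog table: each species' copy of the window with every site
    independently substituted (probability ``m``) to a uniformly chosen
    different base."""
    if not 0 <= m <= 1:
        raise ValueError("substitution probability m must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 50]))
    bases = "ACGT"
    table: dict[str, dict[str, str]] = {}
    for k in range(n_species):
        chars = []
        for base in window.sequence:
            if rng.random() < m and base in bases:
                others = bases.replace(base, "")
                chars.append(others[rng.integers(0, 3)])
            else:
                chars.append(base)
        table[f"species_{k + 1:02d}"] = {window.locus_id or "locus": "".join(chars)}
    return table


# ---------------------------------------------------------------------------
# one-call bundle

@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: GenomeRecord
    annotation: Annotation
    truth: PlantedTruth
    enriched: dict[str, CoverageTrack]
    control: dict[str, CoverageTrack]
    wtss: dict[str, CoverageTrack]
    three_prime: dict[str, CoverageTrack]


def simulate_dataset(config: SimulationConfig | None = None, seed: int | None = None) -> SimulatedDataset:
    """Generate the full study dataset (both strands of all four libraries)."""
    if config is None:
        config = default_config(seed=seed if seed is not None else 0)
    elif seed is not None and seed != config.seed:
        raise ValueError("pass the seed through the config")
    genome, annotation = simulate_genome_annotation(config)
    truth = planted_truth(config)
    enriched, control, wtss, three_prime = {}, {}, {}, {}
    for strand in ("+", "-"):
        enriched[strand], control[strand] = simulate_five_prime_libraries(config, truth, strand)
        wtss[strand] = simulate_wtss(config, truth, strand)
        three_prime[strand] = simulate_three_prime(config, truth, strand)
    return SimulatedDataset(config, genome, annotation, truth, enriched, control, wtss, three_prime)
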