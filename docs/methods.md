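# Methods

This note documents the models, parameter choices and numerical conventions
behind `txarch`, and what the synthetic-data experiments do and do not
demonstrate about real data.

## Coordinates and containers

All internal arithmetic is 0-based half-open; every file-facing surface
(GFF3 in/out, TSS/TTS tables) is 1-based inclusive, converted only at the
I/O boundary. Coverage is strand-specific throughout: a `CoverageTrack`
holds one contig, one strand, one library, plus the depth normalizer
`total_mapped_reads`. bedGraph files carry no depth metadata, so the
normalizer is supplied by the caller (CLI: `--library-depth`) and defaults
to the track's own signal sum — adequate for single-library exploration,
wrong for cross-library ratios when the two libraries have very different
on-target fractions, which is why the explicit flag exists. Circular
chromosomes are not modeled; features crossing the origin are rejected.

## TSS calling

The relative read score is reads-per-million:
`rrs[i] = counts[i] / total_mapped_reads × 1e6`. The enrichment score is
`log2(rrs / max(rrs_control, floor))`. Choices the published procedure
leaves open, with our defaults:

- **Control floor** — the RRS of a single control read (`1e6 / depth`).
  A position the control library never sampled cannot produce an infinite
  score; the floor is the smallest observable nonzero control value, the
  least informative prior consistent with the data. Configurable.
- **`min_raw_count` = 5 reads** — a purely score-based rule would pass
  single-read artifacts at zero-control positions; manual curation of the
  original workflow is replaced by this explicit filter.
- **Clustering: 5 bp, keep max RRS, leftmost on ties** — 5′-end capture is
  single-base resolution but real signal bleeds ±1 nt; a 5-bp window merges
  shoulders without merging distinct nearby promoters.
- **Thresholds** — candidate annotation is strict `> 1.0`; the curated set
  uses `≥ 1.4`. Both configurable per run and echoed into the run manifest.

## TSS classification and confidence

Rule order is iTSS → pTSS → asTSS → oTSS; gene-internal position dominates
proximity to the next downstream gene start, which matters inside operons
where a start in gene *k* may also be < 250 bp from gene *k*+1. Every rule
that matched is kept in `all_labels` for transparency. The pTSS window is
250 bp by default; known leaders in the motivating system run up to
~350 nt, so the window is a surfaced per-run parameter rather than a
constant. Equidistant genes tie-break to the smaller |distance|, then
lexicographic gene id.

Confidence requires curation score plus at least one cross-library
criterion:

- **WTSS step-up**: mean coverage over the 50 bases downstream
  > 1.5 × mean over the 50 bases upstream (upstream floored at one
  pseudo-count; windows truncated at contig edges are used as-is).
- **3′-end enrichment upstream**: maximal 3′-end count within 100 bases
  upstream ≥ 0.1 × the track's 99th-percentile nonzero count, never less
  than 5 reads. The source procedure states this criterion qualitatively;
  the percentile proxy scales with library depth and the absolute floor
  keeps one stray background read from counting as enrichment.

A whitelist of (position, strand) pairs reproduces manual curation:
whitelisted sub-threshold sites are retained flagged
`confident=false, whitelisted=true`, and do open transcriptional units.

Class percentages round half-up (`Decimal`), matching the convention of the
published tallies they are compared against.

## TTS calling

A call requires (a) a 3′-end peak ≥ 2,500 reads (raw uniquely-mapped reads,
as published; for desk-scale simulations the threshold is configurable),
(b) position between 200 bp inside and 150 bp past a same-strand gene's 3′
end, and (c) mean WTSS over the 50 bases downstream of the peak ≤ 0.5 × the
mean over the 50 bases upstream. The drop is assessed relative to the peak
position, not the CDS end — the published rule does not say which; relative
to the peak makes the read-through fraction the directly measured quantity.
The inside-window of 200 bp is motivated by terminators observed within the
last ~180 bp of a gene. Peaks within 10 bp collapse keep-max.

Architecture summary: within a named operon, each confident (or
whitelisted) sense TSS opens a transcriptional unit; the unit closes at the
next downstream called TTS assigned to the operon, else at the operon
boundary. Antisense TSS are reported but open no sense unit.

## Reporter quantification

`RLU(t) = light / OD565`, with timepoints below `od_floor = 0.01` OD masked
— early sparse cultures otherwise blow up the ratio (with an additive light
background *b*, RLU ≈ α + b/OD, maximal at the floor; the simulator's
background option reproduces this closed form and justifies masking).
`RLU_max` is the maximum of the rolling-median-smoothed curve
(window 3, odd), earliest time on ties; the median removes isolated
detector spikes without displacing a sustained maximum. Activity is strict
`>` against the maximum control-well `RLU_max` of the same run: the
promoterless control's residual signal is treated as reproducible
background, not subtracted. Replicates are aggregated per label as
mean of per-well maxima (per-clone-then-aggregate). Relative strength is
the ratio of label means ×100; a range-midpoint mode exists solely for
comparisons against published ranges and is labelled approximate.
Group comparison uses Welch's unequal-variance *t* (safer than Student
across clones of unknown variance) or Kruskal–Wallis with tie correction,
both via scipy; the tests validate them against hand closed forms.

## Conservation

Windows are −50..−5 relative to the TSS (46 nt), reverse-complemented on
the minus strand so sequences read promoter-sense; windows truncated at a
contig edge are flagged. Alignment is a hand-rolled Needleman–Wunsch with
linear gap scoring and deterministic traceback (diagonal > up > left on
ties), validated in the tests against exhaustive enumeration and an
independent aligner. Identity is matched columns over all columns, gaps
included. A semiglobal mode (`end_gap_free`) supports orthologous regions
longer than the window, scoring only the columns the reference spans.
Ortholog discovery is out of scope: the species → locus → sequence table is
an input.

In the divergence-recovery experiments the identity is scored under a gap
penalty strict enough (−100) that the alignment stays ungapped: the
divergence simulator is substitution-only, so the closed-form expectation
`E[identity] = 100 × (1 − m)` is defined positionally, and at high
divergence a permissive gap penalty would let the aligner manufacture
spurious gapped matches between effectively random sequences (at m = 1 the
default scoring yields ~38% identity instead of 0 for exactly this reason).

## Synthetic data

The generator plants ground truth for every stage:

- **5′ libraries** — at each planted TSS, enriched counts
  ~ Poisson(level × depth/10⁶) spread 0.1/0.8/0.1 over ±1 nt; control
  counts the same over the enrichment factor (default 8, i.e. expected
  score 3). Background processed-RNA sites (0.2/kb, level 200) hit both
  libraries with equal expectation — they exercise the score filter's
  specificity. Default depth 10⁶ reads, genome 50 kb: the full suite runs
  in seconds.
- **WTSS** — additive piecewise-constant expectation: each TSS raises
  coverage by its level from its position downstream (strand-aware), each
  terminator multiplies coverage beyond it by its read-through fraction;
  Poisson noise on top of a 2×/base floor.
- **3′-end** — Poisson(peak) at each terminator with 5% shoulders, sparse
  Poisson(0.02)/base background.
- **Reporter** — logistic OD growth (K = 0.4, r = 0.15 h⁻¹, OD₀ = 0.01,
  200 cycles × 20 min); light = α × OD × one per-well lognormal scale
  factor (σ = 0.1). The noise is per-well, not per-timepoint: it models
  clone-to-clone scale variability, makes RLU exactly constant within a
  well (the noise-free oracle σ = 0 gives RLU ≡ α), and makes the median
  across wells the natural unbiased recovery statistic (lognormal median
  = 1). Per-timepoint detector spikes are a separate opt-in option
  (`spike_prob`), which is what the rolling median defends against.
- **Divergence** — each site substituted with probability m to a uniformly
  chosen *different* base; no indels by default.

The default scenario: a 17-gene ~16-kb operon (1 pTSS, 7 iTSS with
escalating expression levels so each stacked start still makes a ≥1.65-fold
WTSS step over the transcription flowing in from upstream, 2 asTSS), a
4-gene operon split into two units by an internal terminator, a 4-gene
single-unit operon, and a 3-gene minus-strand operon. Everything is
deterministic under (config, seed), per-component RNG streams, so files are
byte-identical across runs.

**What passing does and does not show.** The generator uses Poisson counts
(negative-binomial overdispersion, mapper artifacts, GC bias and
condition-dependent expression are absent), plants TSS at single positions
with fixed enrichment, and separates operons cleanly. Perfect recovery here
demonstrates the calling logic, the coordinate/strand handling and the
threshold semantics — not performance on real libraries, where enrichment
factors vary per promoter, processed 5′ ends cluster non-uniformly, and
termination is often partial. Problem sizes (50-kb genome, 20-seed
recovery runs, 200 divergence replicates, 50 reporter wells) were chosen as
the smallest at which the binomial/Poisson error of each recovery statistic
is comfortably inside its asserted tolerance.

## Known limitations

- Single-contig tracks; no BAM/SAM input (coverage tracks are the input
  unit) and no GEO download helpers.
- The pTSS/asTSS upstream window is one global parameter, not learned per
  gene; very long 5′ leaders need a larger window.
- The 3′-enrichment confidence proxy is a heuristic; with a dense
  background of 3′ ends its percentile threshold loses specificity.
- `relative_strength` on range midpoints is an approximation for comparing
  against published ranges, not a statistical estimate.
- The aligner is O(len²) pure Python — fine for 46-nt promoter windows,
  not meant for long regions.
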