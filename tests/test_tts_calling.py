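"""Terminator calling and transcriptional-unit architecture."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from txarch.io_formats import Annotation
from txarch.tss_annotation import ClassifiedTSS
from txarch.tss_calling import TSSCandidate
from txarch.tts_calling import call_tts, summarize_architecture
from txarch.synthetic_data import (
    OperonSpec,
    PlantedTSS,
    PlantedTTS,
    SimulationConfig,
    planted_truth,
    simulate_genome_annotation,
    simulate_three_prime,
    simulate_wtss,
)
from txarch import pipeline

from conftest import make_gene, make_track


def _fixture_tracks(peak=3000.0, wtss_high=200.0, wtss_low=20.0):
    """One forward gene ending at 500; 3' peak 40 bp downstream; WTSS step."""
    ann = Annotation([make_gene(100, 500, "+", "geneA")])
    three = np.zeros(800)
    three[540] = peak
    wtss = np.concatenate([np.full(541, wtss_high), np.full(259, wtss_low)])
    return (
        make_track(three, library="three_prime"),
        make_track(wtss),
        ann,
    )


class TestCallTTS:
    def test_peak_with_coverage_drop_called(self):
        three, wtss, ann = _fixture_tracks()
        (call,) = call_tts(three, wtss, ann)
        assert call.position == 540
        assert call.assigned_gene == "geneA"
        assert call.wtss_drop_ratio == pytest.approx(0.1)  # 20/200

    def test_peak_below_read_threshold_not_called(self):
        three, wtss, ann = _fixture_tracks(peak=2400.0)
        assert call_tts(three, wtss, ann) == []

    def test_flat_wtss_not_called(self):
        three, _wtss, ann = _fixture_tracks()
        flat = make_track(np.full(800, 200.0))
        assert call_tts(three, flat, ann) == []

    def test_peak_far_from_any_gene_end_not_called(self):
        ann = Annotation([make_gene(100, 500, "+", "geneA")])
        three = np.zeros(2000)
        three[1500] = 5000  # 1 kb past the gene end
        wtss = np.concatenate([np.full(1501, 200.0), np.full(499, 1.0)])
        assert call_tts(make_track(three, library="three_prime"), make_track(wtss), ann) == []

    def test_close_peaks_collapse_to_maximum(self):
        three, wtss, ann = _fixture_tracks()
        three.counts[545] = 4000
        (call,) = call_tts(three, wtss, ann)
        assert call.position == 545

    def test_minus_strand_geometry(self):
        ann = Annotation([make_gene(300, 700, "-", "geneR")])
        three = np.zeros(1000)
        three[260] = 3000  # 40 bp downstream of the minus-strand gene end
        wtss = np.concatenate([np.full(260, 5.0), np.full(740, 200.0)])
        (call,) = call_tts(
            make_track(three, strand="-", library="three_prime"),
            make_track(wtss, strand="-"),
            ann,
        )
        assert call.position == 260 and call.assigned_gene == "geneR"

    def test_empty_annotation_and_bad_threshold(self):
        three, wtss, _ = _fixture_tracks()
        assert call_tts(three, wtss, Annotation([])) == []
        with pytest.raises(ValueError):
            call_tts(three, wtss, Annotation([]), min_peak=0)


class TestThresholdMonotonicity:
    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(seed=st.integers(min_value=0, max_value=3000))
    def test_stricter_thresholds_never_add_calls(self, seed):
        rng = np.random.default_rng(seed)
        ann = Annotation([make_gene(i * 700, i * 700 + 500, "+", f"g{i}") for i in range(5)])
        three = rng.poisson(1.0, 3600).astype(float)
        for i in range(5):
            three[i * 700 + 520] = rng.integers(2000, 6000)
        wtss = np.full(3600, 100.0)
        for i in range(5):
            wtss[i * 700 + 521 :] *= float(rng.uniform(0.05, 1.0))
        t3, tw = make_track(three, library="three_prime"), make_track(wtss)
        base = len(call_tts(t3, tw, ann, min_peak=2500, max_drop_ratio=0.5))
        assert len(call_tts(t3, tw, ann, min_peak=4000, max_drop_ratio=0.5)) <= base
        assert len(call_tts(t3, tw, ann, min_peak=2500, max_drop_ratio=0.2)) <= base


def naive_tts(three, wtss, genes, min_peak, down_w, in_w, flank, max_ratio):
    """Literal per-position evaluation of the three calling conditions."""
    out = []
    n = len(three)
    for p in range(n):
        if three[p] < min_peak:
            continue
        near = [
            g
            for g in genes
            if (g.strand == "+" and g.end - 1 - in_w <= p <= g.end - 1 + down_w)
            or (g.strand == "-" and g.start - down_w <= p <= g.start + in_w)
        ]
        if not near:
            continue
        strand = near[0].strand
        if strand == "+":
            up = wtss[max(p - flank, 0) : p]
            down = wtss[p + 1 : p + 1 + flank]
        else:
            up = wtss[p + 1 : p + 1 + flank]
            down = wtss[max(p - flank, 0) : p]
        up_mean = max(up.mean() if len(up) else 0.0, 1.0)
        down_mean = down.mean() if len(down) else 0.0
        if down_mean / up_mean <= max_ratio:
            out.append(p)
    # collapse within 10 bp keeping the max peak (leftmost on ties)
    collapsed, group = [], []
    for p in out:
        if group and p - group[-1] <= 10:
            group.append(p)
        else:
            if group:
                collapsed.append(max(group, key=lambda q: (three[q], -q)))
            group = [p]
    if group:
        collapsed.append(max(group, key=lambda q: (three[q], -q)))
    return collapsed


@settings(deadline=None, derandomize=True, max_examples=25)
@given(seed=st.integers(min_value=0, max_value=3000))
def test_oracle_equivalence_against_brute_force(seed):
    rng = np.random.default_rng(seed)
    n = 3000
    genes = [make_gene(200, 900, "+", "g1"), make_gene(1200, 2000, "+", "g2")]
    ann = Annotation(genes)
    three = rng.poisson(0.2, n).astype(float)
    for pos in rng.integers(0, n, size=8):
        three[pos] += rng.integers(1000, 5000)
    wtss = np.abs(rng.normal(100, 10, n))
    wtss[950:] *= 0.1
    t3, tw = make_track(three, library="three_prime"), make_track(wtss)
    got = [c.position for c in call_tts(t3, tw, ann)]
    assert got == naive_tts(three, wtss, genes, 2500, 150, 200, 50, 0.5)


class TestPlantedTerminatorRecovery:
    def _scenario(self, read_through):
        op = OperonSpec("op", 1000, 2, 800, (50,), "+")
        coords = op.gene_coords()
        cfg = SimulationConfig(
            seed=5,
            genome_length=5000,
            operons=(op,),
            planted_tss=(PlantedTSS(coords[0][0] - 30, "+", "pTSS", 8.0, 150.0, "op"),),
            planted_tts=(PlantedTTS(coords[-1][1] + 40, "+", 3000.0, read_through, "op"),),
            background_processed_site_rate=0.0,
        )
        _genome, ann = simulate_genome_annotation(cfg)
        truth = planted_truth(cfg)
        return (
            simulate_three_prime(cfg, truth, "+"),
            simulate_wtss(cfg, truth, "+"),
            ann,
            cfg.planted_tts[0].position,
        )

    def test_strong_terminator_always_recovered(self):
        three, wtss, ann, pos = self._scenario(read_through=0.1)
        (call,) = call_tts(three, wtss, ann)
        assert abs(call.position - pos) <= 1

    def test_full_read_through_never_called(self):
        three, wtss, ann, _pos = self._scenario(read_through=0.9)
        assert call_tts(three, wtss, ann) == []


def _confident_tss(pos, strand, tss_class, gene):
    return ClassifiedTSS(
        TSSCandidate("chr", pos, strand, 50, 50.0, 2.0, 3.0),
        tss_class,
        gene,
        -30,
        (tss_class,),
        True,
        False,
        True,
    )


class TestSummarizeArchitecture:
    def _tts(self, pos, gene, strand="+"):
        from txarch.tts_calling import TTSCall

        return TTSCall("chr", pos, strand, 3000.0, gene, 0.05)

    def test_single_promoter_single_terminator_one_unit(self, simple_annotation):
        (rep,) = summarize_architecture(
            [_confident_tss(980, "+", "pTSS", "geneA")],
            [self._tts(3540, "geneB")],
            simple_annotation,
            {"op": ["geneA", "geneB"]},
        )
        assert len(rep.units) == 1
        u = rep.units[0]
        assert u.start == 980 and u.end == 3541 and u.closed_by_tts

    def test_two_promoters_internal_terminator_two_units(self, simple_annotation):
        reps = summarize_architecture(
            [
                _confident_tss(980, "+", "pTSS", "geneA"),
                _confident_tss(2470, "+", "pTSS", "geneB"),
            ],
            [self._tts(2060, "geneA"), self._tts(3540, "geneB")],
            simple_annotation,
            {"op": ["geneA", "geneB"]},
        )
        (rep,) = reps
        assert len(rep.units) == 2
        assert rep.units[0].end == 2061     # closes at the internal terminator
        assert rep.units[1].start == 2470

    def test_no_tss_yields_no_units(self, simple_annotation):
        (rep,) = summarize_architecture(
            [], [self._tts(3540, "geneB")], simple_annotation, {"op": ["geneA", "geneB"]}
        )
        assert rep.units == ()

    def test_unknown_operon_gene_is_an_error(self, simple_annotation):
        with pytest.raises(KeyError, match="missing_gene"):
            summarize_architecture([], [], simple_annotation, {"op": ["missing_gene"]})


def test_end_to_end_architecture_matches_planted_layout(dataset, tss_results):
    """Default fixture: the unit count per operon equals the planted design."""
    _classified, confident, _fr = tss_results
    calls = pipeline.run_tts(dataset.annotation, dataset.three_prime, dataset.wtss)
    from txarch.synthetic_data import DEFAULT_OPERON_GENES

    reports = {
        r.name: r
        for r in summarize_architecture(
            confident, calls, dataset.annotation, DEFAULT_OPERON_GENES
        )
    }
    assert len(reports["bigop"].units) == 8     # 1 pTSS + 7 iTSS, one terminal TTS
    assert len(reports["twotu"].units) == 2     # split by the internal terminator
    assert len(reports["smallop"].units) == 1
    assert len(reports["revop"].units) == 1
    assert reports["twotu"].units[0].closed_by_tts
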