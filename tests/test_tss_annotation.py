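"""Positional classification, cross-library support, confidence filter."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from txarch.io_formats import Annotation
from txarch.tss_annotation import (
    TSS_CLASSES,
    class_fractions,
    classify_tss,
    filter_confident,
    threeprime_support,
    wtss_support,
)
from txarch.tss_calling import TSSCandidate

from conftest import make_gene, make_track


def cand(position, strand="+", score=2.0, contig="chr"):
    return TSSCandidate(contig, position, strand, 50.0, 50.0, 5.0, score)


class TestClassifyTSS:
    def test_intergenic_start_just_upstream_is_primary(self, simple_annotation):
        t = classify_tss(cand(983), simple_annotation)  # 17 bp upstream of geneA
        assert t.tss_class == "pTSS"
        assert t.assigned_gene == "geneA"
        assert t.distance_to_feature == -17

    def test_inside_sense_gene_is_intragenic(self, simple_annotation):
        t = classify_tss(cand(1500), simple_annotation)
        assert (t.tss_class, t.assigned_gene) == ("iTSS", "geneA")

    def test_inside_opposite_strand_gene_is_antisense(self, simple_annotation):
        t = classify_tss(cand(5500, "+"), simple_annotation)
        assert (t.tss_class, t.assigned_gene) == ("asTSS", "geneC")

    def test_no_context_is_other(self, simple_annotation):
        assert classify_tss(cand(9000), simple_annotation).tss_class == "oTSS"

    def test_empty_annotation_is_other(self):
        assert classify_tss(cand(100), Annotation([])).tss_class == "oTSS"

    def test_intragenic_dominates_proximity_to_next_start(self):
        # start inside gene1, 40 bp before gene2 begins: still intragenic
        ann = Annotation([make_gene(0, 1000, "+", "g1"), make_gene(1040, 2000, "+", "g2")])
        t = classify_tss(cand(990), ann)
        assert t.tss_class == "iTSS" and t.assigned_gene == "g1"
        assert set(t.all_labels) == {"iTSS", "pTSS"}

    def test_minus_strand_upstream_window(self):
        ann = Annotation([make_gene(1000, 2000, "-", "g1")])
        t = classify_tss(cand(2030, "-"), ann)  # 31 bp upstream on minus strand
        assert (t.tss_class, t.distance_to_feature) == ("pTSS", -31)


def naive_classify(candidate, annotation, window):
    """Brute-force all-genes scan, rules written out literally."""
    pos, strand = candidate.position, candidate.strand
    genes = annotation.contig_features(candidate.contig_id)
    inside_sense = [g for g in genes if g.strand == strand and g.start <= pos < g.end]
    if inside_sense:
        return "iTSS"

    def upstream(g):
        d = (pos - g.start) if g.strand == "+" else (g.end - 1 - pos)
        return -window <= d < 0

    if any(upstream(g) for g in genes if g.strand == strand):
        return "pTSS"
    for g in genes:
        if g.strand != strand and (g.start <= pos < g.end or upstream(g)):
            return "asTSS"
    return "oTSS"


@settings(deadline=None, derandomize=True, max_examples=40)
@given(seed=st.integers(min_value=0, max_value=5000))
def test_oracle_equivalence_against_all_genes_scan(seed):
    rng = np.random.default_rng(seed)
    genes = []
    pos = 0
    for i in range(rng.integers(1, 30)):
        pos += int(rng.integers(1, 300))
        length = int(rng.integers(50, 800))
        genes.append(make_gene(pos, pos + length, rng.choice(["+", "-"]), f"g{i}"))
        pos += length
    ann = Annotation(genes)
    span = genes[-1].end + 400
    for p in rng.integers(0, span, size=40):
        for strand in "+-":
            c = cand(int(p), strand)
            assert classify_tss(c, ann, 250).tss_class == naive_classify(c, ann, 250)


def _mirror_annotation(ann, length):
    return Annotation(
        [
            make_gene(length - g.end, length - g.start, "-" if g.strand == "+" else "+", g.gene_id)
            for g in ann
        ]
    )


@settings(deadline=None, derandomize=True, max_examples=25)
@given(seed=st.integers(min_value=0, max_value=2000))
def test_classification_invariant_under_genome_mirroring(seed):
    rng = np.random.default_rng(seed)
    length = 5000
    genes = [
        make_gene(s, s + 400, str(rng.choice(["+", "-"])), f"g{s}")
        for s in range(200, 4400, 900)
    ]
    ann = Annotation(genes)
    mirrored = _mirror_annotation(ann, length)
    for p in rng.integers(0, length, size=25):
        for strand in "+-":
            direct = classify_tss(cand(int(p), strand), ann).tss_class
            flipped = classify_tss(
                cand(length - 1 - int(p), "-" if strand == "+" else "+"), mirrored
            ).tss_class
            assert direct == flipped


class TestWTSSSupport:
    def test_step_up_supported(self):
        counts = np.concatenate([np.zeros(100), np.full(100, 100.0)])
        assert wtss_support(cand(100), make_track(counts))

    def test_flat_track_not_supported(self):
        assert not wtss_support(cand(100), make_track(np.full(200, 40.0)))

    def test_modest_increase_below_fold_threshold(self):
        counts = np.concatenate([np.full(100, 25.0), np.full(100, 30.0)])
        assert not wtss_support(cand(100), make_track(counts), min_fold=1.5)  # 1.2-fold

    def test_minus_strand_step_direction(self):
        counts = np.concatenate([np.full(100, 100.0), np.zeros(100)])
        assert wtss_support(cand(99, "-"), make_track(counts, strand="-"))
        assert not wtss_support(cand(99, "+"), make_track(counts))

    def test_bad_flank_rejected(self):
        with pytest.raises(ValueError):
            wtss_support(cand(10), make_track(np.ones(50)), flank=0)


class TestThreePrimeSupport:
    def test_terminator_peak_just_upstream(self):
        counts = np.zeros(400)
        counts[170] = 3000  # 30 bp upstream of a TSS at 200
        assert threeprime_support(cand(200), make_track(counts, library="three_prime"))

    def test_all_zero_track(self):
        assert not threeprime_support(cand(200), make_track(np.zeros(400), library="three_prime"))

    def test_peak_outside_window(self):
        counts = np.zeros(400)
        counts[50] = 3000  # 150 bp upstream, window 100
        assert not threeprime_support(
            cand(200), make_track(counts, library="three_prime"), upstream_window=100
        )

    def test_sparse_single_read_background_does_not_trigger(self):
        counts = np.zeros(400)
        counts[180] = 1.0
        assert not threeprime_support(cand(200), make_track(counts, library="three_prime"))


class TestFilterConfident:
    def _classified(self, score, wtss, three, pos=10):
        from txarch.tss_annotation import ClassifiedTSS

        return ClassifiedTSS(
            cand(pos, score=score), "pTSS", "geneA", -20, ("pTSS",), wtss, three, False
        )

    def test_one_criterion_suffices(self):
        (kept,) = filter_confident([self._classified(1.5, True, False)])
        assert kept.confident

    def test_no_support_dropped(self):
        assert filter_confident([self._classified(1.5, False, False)]) == []

    def test_subthreshold_kept_only_via_whitelist(self):
        t = self._classified(1.2, True, True, pos=42)
        assert filter_confident([t]) == []
        (kept,) = filter_confident([t], whitelist={(42, "+")})
        assert kept.whitelisted and not kept.confident


class TestClassFractions:
    def test_genome_wide_printed_tallies(self):
        fr = class_fractions({"iTSS": 3273, "asTSS": 3401, "oTSS": 319, "pTSS": 2646}, decimals=1)
        assert fr.denominator == 9639
        assert fr.percentages["iTSS"] == 34.0
        assert fr.percentages["asTSS"] == 35.3
        assert fr.percentages["oTSS"] == 3.3

    def test_high_confidence_operon_tallies(self):
        fr = class_fractions({"pTSS": 8, "iTSS": 7, "asTSS": 9, "oTSS": 1}, decimals=0)
        assert fr.percentages == {"pTSS": 32, "iTSS": 28, "asTSS": 36, "oTSS": 4}

    def test_single_class_is_hundred_percent(self):
        fr = class_fractions({"pTSS": 12}, decimals=1)
        assert fr.percentages["pTSS"] == 100.0

    def test_half_up_rounding(self):
        # 1/8 = 12.5% must round to 13 at 0 decimals, not banker's 12
        fr = class_fractions({"pTSS": 1, "iTSS": 7}, decimals=0)
        assert fr.percentages["pTSS"] == 13

    def test_counts_sum_to_denominator_and_empty_rejected(self):
        with pytest.raises(ValueError):
            class_fractions({}, decimals=1)
        fr = class_fractions({"pTSS": 2, "oTSS": 3}, decimals=2)
        assert sum(fr.counts.values()) == fr.denominator == 5


def test_every_candidate_receives_exactly_one_class(tss_results):
    classified, _confident, fractions = tss_results
    assert all(t.tss_class in TSS_CLASSES for t in classified)
    assert sum(fractions.counts.values()) == len(classified)
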