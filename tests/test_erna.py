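"""eRNA regions, RPM quantification, detectability, direction and GC."""

import numpy as np
import pandas as pd
import pytest

from ernanet.erna import (
    ERnaRecord,
    binned_activity_correlation,
    call_detectable,
    classify_direction,
    define_erna_regions,
    gc_fraction,
    label_transcribed_enhancers,
    quantify_rpm,
)
from ernanet.intervals import AnnotationRecord, AnnotationSet, GenomicInterval


def enh(start, end, eid="e1", chrom="chr1"):
    return GenomicInterval(chrom, start, end, ".", eid)


def annotation(*bodies):
    return AnnotationSet(
        genes=[AnnotationRecord(GenomicInterval("chr1", s, e, "+", f"g{i}"))
               for i, (s, e) in enumerate(bodies)]
    )


def two_sample_sheet():
    return pd.DataFrame(
        {
            "sample": ["ES_fat_rep1", "ES_fat_rep2"],
            "breed": ["ES", "ES"],
            "tissue": ["fat", "fat"],
            "replicate": [1, 2],
        }
    )


def make_record(rpm=None, region=(8000, 14000)):
    return ERnaRecord(
        "eRNA_e1", "e1",
        GenomicInterval("chr1", region[0], region[1], ".", "eRNA_e1"),
        [GenomicInterval("chr1", region[0], region[1])],
        rpm=rpm or {},
    )


class TestDefineRegions:
    def test_clear_region_single_window(self):
        [rec] = define_erna_regions([enh(10_000, 12_000)], annotation())
        assert (rec.region.start, rec.region.end) == (8000, 14_000)
        assert rec.windows == [GenomicInterval("chr1", 8000, 14_000)]

    def test_gene_body_plus_1kb_subtracted(self):
        [rec] = define_erna_regions([enh(10_000, 12_000)], annotation((13_000, 20_000)))
        assert rec.windows == [GenomicInterval("chr1", 8000, 12_000)]

    def test_fully_covered_record_dropped(self):
        recs = define_erna_regions([enh(10_000, 12_000)], annotation((6000, 16_000)))
        assert recs == []

    def test_window_span_bounded_by_region(self):
        recs = define_erna_regions(
            [enh(10_000, 12_000), enh(100_000, 101_000)],
            annotation((13_000, 20_000)),
        )
        for rec in recs:
            assert sum(len(w) for w in rec.windows) <= 6000


class TestQuantifyRpm:
    def test_rpm_and_plus_fraction(self):
        rec = make_record()
        counts = pd.DataFrame(
            {
                "erna_id": ["eRNA_e1"] * 2,
                "sample": ["ES_fat_rep1", "ES_fat_rep2"],
                "plus_count": [3, 3],
                "minus_count": [7, 7],
            }
        )
        quantify_rpm([rec], counts, {"ES_fat_rep1": 1e6, "ES_fat_rep2": 1e6}, two_sample_sheet())
        assert rec.rpm["ES_fat_rep1"] == 10.0
        assert rec.plus_fraction["ES:fat"] == pytest.approx(0.3)

    def test_zero_reads_flagged_undefined(self):
        rec = make_record()
        counts = pd.DataFrame(
            {"erna_id": ["eRNA_e1"], "sample": ["ES_fat_rep1"], "plus_count": [0], "minus_count": [0]}
        )
        quantify_rpm([rec], counts, {"ES_fat_rep1": 1e6, "ES_fat_rep2": 1e6}, two_sample_sheet())
        assert rec.rpm["ES_fat_rep1"] == 0.0
        assert rec.plus_fraction["ES:fat"] is None

    def test_negative_counts_rejected(self):
        counts = pd.DataFrame(
            {"erna_id": ["eRNA_e1"], "sample": ["ES_fat_rep1"], "plus_count": [-1], "minus_count": [0]}
        )
        with pytest.raises(ValueError):
            quantify_rpm([make_record()], counts, {"ES_fat_rep1": 1e6}, two_sample_sheet())


class TestDetectability:
    @pytest.mark.parametrize(
        "reps,expected",
        [((1.5, 0.6), True), ((0.9, 0.9), False), ((1.0, 1.0), True)],
    )
    def test_mean_rpm_threshold_inclusive(self, reps, expected):
        rec = make_record(rpm={"ES_fat_rep1": reps[0], "ES_fat_rep2": reps[1]})
        out = call_detectable([rec], two_sample_sheet(), "ES", "fat")
        assert (rec.erna_id in out) is expected

    def test_monotone_in_rpm(self):
        rec = make_record(rpm={"ES_fat_rep1": 1.2, "ES_fat_rep2": 0.9})
        sheet = two_sample_sheet()
        assert rec.erna_id in call_detectable([rec], sheet, "ES", "fat")
        rec.rpm["ES_fat_rep2"] = 5.0  # raising a replicate can never lose detectability
        assert rec.erna_id in call_detectable([rec], sheet, "ES", "fat")

    def test_single_replicate_warns_but_works(self, caplog):
        sheet = two_sample_sheet().iloc[:1]
        rec = make_record(rpm={"ES_fat_rep1": 2.0})
        with caplog.at_level("WARNING"):
            out = call_detectable([rec], sheet, "ES", "fat")
        assert rec.erna_id in out
        assert "replicate" in caplog.text


class TestDirection:
    @pytest.mark.parametrize(
        "pf,expected",
        [
            (0.50, "bidirectional"),
            (0.96, "unidirectional"),
            (0.05, "bidirectional"),
            (0.95, "bidirectional"),
            (0.951, "unidirectional"),
            (0.049, "unidirectional"),
        ],
    )
    def test_five_to_ninety_five_inclusive(self, pf, expected):
        assert classify_direction(pf) == expected

    def test_strand_symmetry(self):
        for pf in np.linspace(0, 1, 101):
            assert classify_direction(pf) == classify_direction(1 - pf)

    def test_undefined_fraction_unlabeled(self):
        assert classify_direction(None) is None


class TestGcFraction:
    @pytest.mark.parametrize(
        "seq,expected", [("ACGC", 0.75), ("AAAA", 0.0), ("ACGTN", 0.4), ("acgc", 0.75)]
    )
    def test_values(self, seq, expected):
        assert gc_fraction(seq) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gc_fraction("")


class TestBinnedCorrelation:
    def test_identity_and_anti_identity(self):
        expr = {f"e{i}": float(i) for i in range(16)}
        r, _ = binned_activity_correlation(expr, dict(expr))
        assert r == pytest.approx(1.0)
        r, _ = binned_activity_correlation(expr, {k: -v for k, v in expr.items()})
        assert r == pytest.approx(-1.0)

    def test_matches_independent_binning_oracle(self):
        rng = np.random.default_rng(11)
        expr = {f"e{i}": float(v) for i, v in enumerate(rng.random(80))}
        act = {f"e{i}": float(v) for i, v in enumerate(rng.random(80))}
        r, _ = binned_activity_correlation(expr, act, 8)
        # oracle: explicit descending sort, remainder-first binning, np.corrcoef
        order = sorted(expr, key=lambda k: -expr[k])
        sizes = [10] * 8
        chunks, pos = [], 0
        for s in sizes:
            chunks.append(order[pos : pos + s])
            pos += s
        em = [np.mean([expr[k] for k in c]) for c in chunks]
        am = [np.mean([act[k] for k in c]) for c in chunks]
        assert r == pytest.approx(np.corrcoef(em, am)[0, 1], abs=1e-12)

    def test_too_few_items_rejected(self):
        expr = {f"e{i}": float(i) for i in range(5)}
        with pytest.raises(ValueError):
            binned_activity_correlation(expr, dict(expr), 8)


class TestTranscribedLabels:
    def test_center_containment_half_open(self):
        enhancers = [enh(100, 200, "a"), enh(200, 300, "b")]
        rec = make_record(region=(147, 153))  # center 150
        labels = {l.enhancer_id: l.label for l in label_transcribed_enhancers(enhancers, [rec])}
        assert labels == {"a": "TEn", "b": "non-TEn"}

    def test_center_at_exclusive_end_not_contained(self):
        enhancers = [enh(100, 200, "a")]
        rec = make_record(region=(197, 203))  # center 200 == exclusive end
        [label] = label_transcribed_enhancers(enhancers, [rec])
        assert label.label == "non-TEn"

    def test_no_ernas_all_non_ten(self):
        labels = label_transcribed_enhancers([enh(0, 10, "a")], [])
        assert labels[0].label == "non-TEn"
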