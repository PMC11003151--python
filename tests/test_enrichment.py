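"""Hypergeometric, permutation and FDR machinery against enumeration oracles."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from ernanet.enrichment import (
    bh_fdr,
    expand_points,
    hypergeom_enrichment,
    permutation_enrichment,
    transposon_insertion_test,
)
from ernanet.intervals import GenomeLayout, GenomicInterval


def hypergeom_upper_tail_oracle(T, M, t, m):
    """Exact upper tail by direct summation of the urn pmf."""
    total = Fraction(0)
    for k in range(m, min(M, t) + 1):
        total += Fraction(math.comb(M, k) * math.comb(T - M, t - k), math.comb(T, t))
    return float(total)


class TestHypergeom:
    def test_reference_configuration(self):
        assert hypergeom_enrichment(10, 4, 5, 4) == pytest.approx(6 / 252)

    def test_zero_marked_draws_is_certain(self):
        assert hypergeom_enrichment(10, 4, 5, 0) == pytest.approx(1.0)

    def test_saturated_urn(self):
        assert hypergeom_enrichment(8, 8, 8, 8) == pytest.approx(1.0)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_enrichment(10, 12, 5, 3)
        with pytest.raises(ValueError):
            hypergeom_enrichment(10, 4, 5, 5)

    def test_full_enumeration_sweep_small_universe(self):
        for T in range(1, 13):
            for M in range(T + 1):
                for t in range(T + 1):
                    for m in range(max(0, M + t - T), min(M, t) + 1):
                        assert hypergeom_enrichment(T, M, t, m) == pytest.approx(
                            hypergeom_upper_tail_oracle(T, M, t, m), abs=1e-12
                        )


class TestExpandPoints:
    def test_point_window(self):
        [w] = expand_points([("chr1", 100_000)], 20_000)
        assert (w.start, w.end) == (80_000, 120_001)

    def test_clipping_at_zero(self):
        [w] = expand_points([("chr1", 5000)], 20_000)
        assert (w.start, w.end) == (0, 25_001)

    def test_zero_flank_single_base(self):
        [w] = expand_points([("chr1", 7)], 0)
        assert (w.start, w.end) == (7, 8)

    def test_interval_hits_expand_both_ends(self):
        [w] = expand_points([GenomicInterval("chr1", 50_000, 60_000)], 1000)
        assert (w.start, w.end) == (49_000, 61_000)


class TestPermutation:
    layout = GenomeLayout([("chr1", 1_000_000)])

    def test_saturating_features_give_p_one(self):
        query = [GenomicInterval("chr1", i * 1000, i * 1000 + 100) for i in range(20)]
        features = [GenomicInterval("chr1", 0, 1_000_000)]
        res = permutation_enrichment(query, features, self.layout, R=200, seed=1)
        assert res.observed == 20
        assert res.p_value == 1.0

    def test_empty_features_give_p_one(self):
        query = [GenomicInterval("chr1", 0, 100)]
        res = permutation_enrichment(query, [], self.layout, R=100, seed=1)
        assert res.observed == 0
        assert res.p_value == 1.0

    def test_planted_enrichment_minimal_p(self):
        # features cover 1% of the genome; all 50 query elements planted inside
        features = [GenomicInterval("chr1", 0, 10_000)]
        query = [GenomicInterval("chr1", i * 200, i * 200 + 100) for i in range(50)]
        res = permutation_enrichment(query, features, self.layout, R=1000, seed=7)
        assert res.observed == 50
        assert res.p_value == pytest.approx(1 / 1001)

    def test_oversized_element_rejected(self):
        with pytest.raises(ValueError):
            permutation_enrichment(
                [GenomicInterval("chr1", 0, 2_000_000 - 1)],
                [], GenomeLayout([("chr1", 1_000_000)]), R=10, seed=0,
            )

    def test_p_never_zero_and_in_unit_interval(self):
        features = [GenomicInterval("chr1", 0, 10_000)]
        query = [GenomicInterval("chr1", 0, 100)]
        res = permutation_enrichment(query, features, self.layout, R=50, seed=3)
        assert 0 < res.p_value <= 1


class TestBhFdr:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_order_invariant(self):
        rng = np.random.default_rng(0)
        p = rng.random(30)
        perm = rng.permutation(30)
        np.testing.assert_allclose(bh_fdr(p)[perm], bh_fdr(p[perm]))

    def test_monotone_in_each_p(self):
        p = np.array([0.01, 0.2, 0.5, 0.9])
        q0 = bh_fdr(p)
        p2 = p.copy()
        p2[1] = 0.3
        q1 = bh_fdr(p2)
        assert all(b >= a - 1e-15 for a, b in zip(q0, q1))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestTransposonTest:
    layout = GenomeLayout([("chr1", 1_000_000)])

    def _enhancers(self, n):
        return {
            f"e{i}": GenomicInterval("chr1", i * 10_000, i * 10_000 + 2000, ".", f"e{i}")
            for i in range(n)
        }

    def test_identical_groups_p_one(self):
        enh = self._enhancers(10)
        repeats = pd.DataFrame(
            [
                {"chrom": "chr1", "start": i * 10_000, "end": i * 10_000 + 100,
                 "name": "LTR/ERV1", "repeat_class": "LTR", "repeat_family": "LTR/ERV1"}
                for i in range(10)
            ]
        )
        res = transposon_insertion_test(
            [f"e{i}" for i in range(5)], [f"e{i}" for i in range(5, 10)],
            enh, repeats, self.layout, R=50, seed=0,
        )
        assert res["fisher_p"] == pytest.approx(1.0)

    def test_family_enriched_only_in_ten(self):
        enh = self._enhancers(40)
        ten = [f"e{i}" for i in range(20)]
        non_ten = [f"e{i}" for i in range(20, 40)]
        rows = [
            {"chrom": "chr1", "start": i * 10_000 + 100, "end": i * 10_000 + 1900,
             "name": "LTR/ERV1", "repeat_class": "LTR", "repeat_family": "LTR/ERV1"}
            for i in range(20)  # fully covers TEn only
        ]
        res = transposon_insertion_test(
            ten, non_ten, enh, pd.DataFrame(rows), self.layout, R=500, seed=0
        )
        fam = res["family_enrichment"].set_index(["family", "group"])
        assert fam.loc[("LTR/ERV1", "TEn"), "q"] < 0.05
        assert fam.loc[("LTR/ERV1", "non-TEn"), "q"] > 0.05
        assert res["base_fractions"]["LTR"]["TEn"] == pytest.approx(0.9)
        assert res["base_fractions"]["LTR"]["non-TEn"] == 0.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            transposon_insertion_test([], ["e0"], self._enhancers(1), pd.DataFrame(
                columns=["chrom", "start", "end", "name", "repeat_class", "repeat_family"]
            ), self.layout)
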