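"""Rank distance, skewness, extreme-value Pearson, Wilcoxon, and the
published NASH case-study table."""

import numpy as np
import pandas as pd
import pytest

from ampnet.exceptions import UndefinedStatisticError, ValidationError
from ampnet.validation import (
    assess_positive_skew,
    dist_measure,
    intersect_tables,
    load_nash_example,
    pearson_extremes,
    rank_scores,
    skewness_g1,
    validate_networks,
    wilcoxon_signed_rank,
)


def score_table(mapping, label="BW"):
    return pd.DataFrame(
        {"taxon_id": list(mapping), "network": label, "z_die": list(mapping.values())}
    )


class TestIntersect:
    def test_identical_sets_full_pairing(self):
        bw = score_table({"A": 1.0, "B": 0.0})
        mb = score_table({"A": 0.5, "B": -0.5}, "MB")
        pairs, only_bw, only_mb = intersect_tables(bw, mb)
        assert len(pairs) == 2 and only_bw == [] and only_mb == []

    def test_disjoint_sets_error(self):
        with pytest.raises(UndefinedStatisticError):
            intersect_tables(score_table({"A": 1.0}), score_table({"B": 1.0}, "MB"))

    def test_partial_overlap_reports_dropped(self):
        bw = score_table({"A": 1, "B": 2, "C": 3})
        mb = score_table({"B": 1, "C": 2, "D": 3}, "MB")
        pairs, only_bw, only_mb = intersect_tables(bw, mb)
        assert list(pairs["taxon_id"]) == ["B", "C"]
        assert only_bw == ["A"] and only_mb == ["D"]


class TestRanks:
    def test_lowest_gets_rank_one(self):
        assert list(rank_scores([-0.8, -0.56, -0.45])) == [1, 2, 3]

    def test_ties_averaged(self):
        assert list(rank_scores([0.5, 0.5, 1.0])) == [1.5, 1.5, 3]

    def test_strictly_increasing_vector(self, rng):
        x = np.sort(rng.normal(size=15))
        assert list(rank_scores(x)) == list(range(1, 16))

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            rank_scores([])


class TestDistMeasure:
    @pytest.mark.parametrize(
        "rank_bw,rank_mb,expected", [(20, 32, 12), (24, 7, 17), (5, 5, 0)]
    )
    def test_absolute_rank_difference(self, rank_bw, rank_mb, expected):
        assert dist_measure(rank_bw, rank_mb) == expected
        assert dist_measure(rank_mb, rank_bw) == expected  # symmetric

    def test_bounded_by_m_minus_one(self, rng):
        m = 20
        r1 = rank_scores(rng.normal(size=m))
        r2 = rank_scores(rng.normal(size=m))
        assert dist_measure(r1, r2).max() <= m - 1


class TestSkewness:
    def test_hand_computed_value(self):
        # m2=3, m3=6, g1=6/3^1.5; G1 = g1*sqrt(12)/2 = 2
        assert skewness_g1([1, 1, 1, 5]) == pytest.approx(2.0)

    def test_symmetric_sample_zero(self):
        assert skewness_g1([1, 2, 3, 4, 5]) == pytest.approx(0.0, abs=1e-12)

    def test_oddness_under_negation(self, rng):
        for _ in range(10):
            x = rng.normal(size=12)
            assert skewness_g1(-x) == pytest.approx(-skewness_g1(x))

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            skewness_g1([1, 2])
        with pytest.raises(UndefinedStatisticError):
            skewness_g1([3, 3, 3, 3])


class TestPositiveSkewVerdict:
    def test_right_tail_positive(self):
        verdict = assess_positive_skew([1, 1, 1, 5])
        assert verdict.positive and verdict.skew_criterion

    def test_symmetric_not_positive(self):
        verdict = assess_positive_skew([1, 2, 2, 3, 3, 4])
        assert not verdict.positive

    def test_left_tail_not_positive(self):
        verdict = assess_positive_skew([-1, -1, -1, -5])
        assert not verdict.positive
        assert verdict.g1 == pytest.approx(-2.0)

    def test_needs_four_values(self):
        with pytest.raises(UndefinedStatisticError):
            assess_positive_skew([1, 2, 3])


def pairs_frame(bw, mb, taxa=None):
    taxa = taxa or [f"T{i}" for i in range(len(bw))]
    return pd.DataFrame({"taxon_id": taxa, "z_die_bw": bw, "z_die_mb": mb})


class TestPearsonExtremes:
    def test_two_point_correlation_is_sign(self):
        pairs = pairs_frame([1.89, -0.8, 0.1], [0.88, 0.09, 0.5])
        assert pearson_extremes(pairs, k=1) == 1.0
        flipped = pairs_frame([1.89, -0.8, 0.1], [-0.88, 0.09, 0.5])
        assert pearson_extremes(flipped, k=1) == -1.0

    def test_half_selection_equals_plain_pearson(self, rng):
        bw, mb = rng.normal(size=10), rng.normal(size=10)
        pairs = pairs_frame(bw, mb)
        full = np.corrcoef(
            pairs.sort_values(["z_die_bw", "taxon_id"])["z_die_bw"],
            pairs.sort_values(["z_die_bw", "taxon_id"])["z_die_mb"],
        )[0, 1]
        assert pearson_extremes(pairs, k=5) == pytest.approx(full)

    def test_selection_uses_order_only(self, rng):
        bw, mb = rng.normal(size=12), rng.normal(size=12)
        pairs = pairs_frame(bw, mb)
        transformed = pairs_frame(np.exp(bw), mb)  # strictly increasing map
        r1 = set(pairs.sort_values(["z_die_bw", "taxon_id"]).head(2)["taxon_id"])
        r2 = set(transformed.sort_values(["z_die_bw", "taxon_id"]).head(2)["taxon_id"])
        assert r1 == r2

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError):
            pearson_extremes(pairs_frame([1, 2, 3], [1, 2, 3]), k=2)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            pearson_extremes(pairs_frame([1.0, 2.0], [3.0, 3.0]), k=1)


class TestWilcoxon:
    def test_identical_lists_degenerate(self):
        ranks = list(range(1, 11))
        with pytest.warns(UserWarning):
            stat, p = wilcoxon_signed_rank(ranks, ranks)
        assert p == 1.0

    def test_null_perturbations_rarely_significant(self):
        rejections = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=15)
            y = x + rng.normal(scale=0.3, size=15)  # symmetric perturbation
            _, p = wilcoxon_signed_rank(rank_scores(x), rank_scores(y))
            rejections += p <= 0.05
        assert rejections <= 5

    def test_large_shift_detected(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=20)
        ranks_x = rank_scores(x)
        # one list systematically shifted against the other
        _, p = wilcoxon_signed_rank(ranks_x, ranks_x + 5.0)
        assert p < 0.05

    def test_reversed_ranking_gives_symmetric_differences(self):
        # a full reversal yields differences symmetric about zero, which the
        # signed-rank test (a location test) does not flag
        ranks = rank_scores(np.arange(10.0))
        _, p = wilcoxon_signed_rank(ranks, len(ranks) + 1 - ranks)
        assert p > 0.05


class TestNashCaseStudy:
    """Published NASH gut-microbiome case study: ten genera with Die scores
    from the AMP-sharing and co-occurrence networks, their ranks within the
    study's full intersection, and the Dist values."""

    def test_dist_reproduced_from_printed_ranks(self):
        tbl = load_nash_example()
        expected = {
            "Acidovorax": 12, "Acinetobacter": 7, "Actinomyces": 4,
            "Akkermansia": 1, "Arcobacter": 17, "Bifidobacterium": 1,
            "Campylobacter": 5, "Citrobacter": 21, "Clostridium": 11,
            "Weissella": 7,
        }
        for _, row in tbl.iterrows():
            assert dist_measure(row["rank_bw"], row["rank_mb"]) == row["dist"]
            assert row["dist"] == expected[row["genus"]]

    def test_printed_ranks_consistent_with_scores(self):
        """rank_scores on each printed score column must order the genera the
        same way as the printed (full-intersection) ranks."""
        tbl = load_nash_example()
        for score_col, rank_col in [("z_die_bw", "rank_bw"), ("z_die_mb", "rank_mb")]:
            local = rank_scores(tbl[score_col])
            printed = tbl[rank_col].to_numpy()
            for i in range(len(tbl)):
                for j in range(len(tbl)):
                    if tbl[score_col][i] < tbl[score_col][j]:
                        assert printed[i] < printed[j]
                        assert local[i] < local[j]

    def test_extreme_pair_correlates_perfectly(self):
        tbl = load_nash_example()
        pairs = tbl.rename(columns={"genus": "taxon_id"})
        assert pearson_extremes(pairs, k=1) == 1.0


class TestValidateNetworks:
    def test_full_report_on_concordant_tables(self):
        bw = score_table({f"T{i}": float(i) for i in range(8)})
        mb_scores = [0.0, 1.2, 1.8, 3.1, 3.9, 5.2, 6.1, 7.0]
        mb = score_table({f"T{i}": mb_scores[i] for i in range(8)}, "MB")
        report = validate_networks(bw, mb, ks=(1, 2))
        assert report.pearson_extremes[1] == 1.0
        assert (report.pairs["dist"] == 0).all()
        assert report.wilcoxon_p == 1.0

    def test_report_round_trip(self, tmp_path):
        bw = score_table({f"T{i}": float(i) for i in range(8)})
        mb = score_table({f"T{i}": float(i % 3) for i in range(8)}, "MB")
        report = validate_networks(bw, mb, ks=(1,))
        report.write(tmp_path, "val")
        assert (tmp_path / "val.tsv").exists()
        assert (tmp_path / "val.json").exists()
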