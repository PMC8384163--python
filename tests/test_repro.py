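"""Reproducibility statistics: accuracy, CVs, rank tests, variance components.

The packaged volunteer/phantom fixtures are the five-subject, four-site
(plus five-site phantom) study tables; several expected values below are
hand-recomputed from those tables with independent arithmetic.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from pancmri.repro import (
    InsufficientDataError,
    average_cv,
    coefficient_of_variation,
    friedman_across_sites,
    load_phantom_table,
    load_volunteer_table,
    pairwise_rank_tests,
    percent_difference,
    variance_components,
)


@pytest.fixture(scope="module")
def volunteers():
    return load_volunteer_table()


@pytest.fixture(scope="module")
def phantom():
    return load_phantom_table()


def make_table(values_by_site: dict, measure="m") -> pd.DataFrame:
    rows = []
    for site, vals in values_by_site.items():
        for i, v in enumerate(vals):
            rows.append({"subject": f"S{i + 1}", "site": site, "measure": measure, "value": v})
    return pd.DataFrame(rows)


class TestPercentDifference:
    @pytest.mark.parametrize(
        "measured, reference, expected",
        [(91.2, 89.0, 2.4719), (1141.0, 1000.0, 14.1), (89.0, 89.0, 0.0)],
    )
    def test_values(self, measured, reference, expected):
        assert percent_difference(measured, reference) == pytest.approx(expected, abs=1e-4)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_difference(1.0, 0.0)


class TestCoefficientOfVariation:
    def test_volunteer5_t1_row(self):
        # hand check: mean 763.3975, sample SD 83.4526 -> 10.93%
        cv = coefficient_of_variation([676.91, 839.37, 830.25, 707.06])
        assert cv == pytest.approx(10.93, abs=0.01)

    def test_constant_values_zero(self):
        assert coefficient_of_variation([5.0, 5.0, 5.0]) == 0.0

    def test_missing_values_dropped(self):
        vals = [0.40765, 0.28954, 0.34684, np.nan]
        cv = coefficient_of_variation(vals)
        clean = np.array(vals[:3])
        expected = np.std(clean, ddof=1) / clean.mean() * 100
        assert cv == pytest.approx(expected, rel=1e-12)

    def test_single_value_rejected(self):
        with pytest.raises(InsufficientDataError):
            coefficient_of_variation([1.0, np.nan, np.nan])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        values=st.lists(st.floats(1.0, 1000.0), min_size=2, max_size=8),
        k=st.floats(0.01, 100.0),
    )
    def test_scale_invariance(self, values, k):
        try:
            base = coefficient_of_variation(values)
        except InsufficientDataError:
            return
        scaled = coefficient_of_variation([k * v for v in values])
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-9)


class TestAverageCV:
    # one-decimal values reported for the six exactly-reproducible measures
    @pytest.mark.parametrize(
        "measure, expected",
        [
            ("surface_to_volume", 5.3),
            ("adc", 8.4),
            ("t1", 9.5),
            ("mtr", 39.3),
            ("panc_fat_fraction", 26.5),
            ("hep_fat_fraction", 30.2),
        ],
    )
    def test_fixture_measures_round_to_published_cv(self, volunteers, measure, expected):
        assert round(average_cv(volunteers, measure), 1) == expected

    def test_volume_and_pvi_close_to_published(self, volunteers):
        # printed-value rounding in the source table prevents exact agreement
        assert average_cv(volunteers, "volume") == pytest.approx(9.5, abs=0.15)
        assert average_cv(volunteers, "pvi") == pytest.approx(9.8, abs=0.15)

    def test_perfectly_repeated_values_give_zero(self):
        table = make_table({s: [3.0, 7.0, 9.0] for s in "ABCD"})
        assert average_cv(table, "m") == 0.0

    def test_subject_with_one_site_excluded_with_warning(self):
        table = make_table({"A": [3.0, 7.0], "B": [4.0, np.nan]})
        warnings = []
        cv = average_cv(table, "m", warnings)
        assert len(warnings) == 1 and "S2" in warnings[0]
        assert cv == pytest.approx(coefficient_of_variation([3.0, 4.0]))


class TestFriedman:
    def test_identical_sites_give_zero_statistic_p_one(self):
        table = make_table({s: [3.0, 7.0, 9.0] for s in "ABCD"})
        res = friedman_across_sites(table, "m")
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_one_dominant_site_matches_hand_ranked_oracle(self):
        # 5 subjects x 4 sites, site D uniformly largest, others exchangeable
        rng = np.random.default_rng(0)
        base = rng.uniform(1, 2, size=(5, 3))
        table_vals = {s: base[:, i] for i, s in enumerate("ABC")}
        table_vals["D"] = base.max(axis=1) + 1.0
        table = make_table(table_vals)
        res = friedman_across_sites(table, "m")
        # from-scratch oracle: rank within each subject, chi-square formula
        data = np.column_stack([table_vals[s] for s in "ABCD"])
        ranks = np.apply_along_axis(sps.rankdata, 1, data)
        rj = ranks.sum(axis=0)
        n, k = data.shape
        expected = 12 / (n * k * (k + 1)) * np.sum(rj**2) - 3 * n * (k + 1)
        assert res.statistic == pytest.approx(expected, rel=1e-12)
        assert res.n_complete_blocks == 5

    def test_agrees_with_scipy_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n, k = rng.integers(3, 8), rng.integers(3, 6)
            data = rng.random((n, k))
            table = make_table({f"site{j}": data[:, j] for j in range(k)})
            res = friedman_across_sites(table, "m")
            ref = sps.friedmanchisquare(*[data[:, j] for j in range(k)])
            assert res.statistic == pytest.approx(ref.statistic, rel=1e-10)
            assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_fixture_all_measures_nonsignificant(self, volunteers):
        for measure in sorted(volunteers["measure"].unique()):
            res = friedman_across_sites(volunteers, measure)
            assert res.p_value > 0.05, measure

    def test_incomplete_blocks_dropped_and_counted(self, volunteers):
        res = friedman_across_sites(volunteers, "mtr")
        assert res.n_complete_blocks == 4  # V3 lacks the Chicago MTR value

    def test_insufficient_blocks_rejected(self):
        table = make_table({"A": [1.0, np.nan], "B": [2.0, np.nan]})
        with pytest.raises(InsufficientDataError):
            friedman_across_sites(table, "m")


class TestPairwiseRankTests:
    def test_identical_samples_p_one(self):
        table = make_table({"A": [2.0, 2.0, 2.0], "B": [2.0, 2.0, 2.0]})
        out = pairwise_rank_tests(table, "m")
        assert out.loc[0, "p_value"] == 1.0

    def test_complete_separation_matches_exact_enumeration(self):
        table = make_table({"A": [1.0, 2, 3, 4, 5], "B": [6.0, 7, 8, 9, 10]})
        out = pairwise_rank_tests(table, "m")
        # oracle: enumerate all C(10,5) = 252 rank assignments
        pooled = np.arange(1, 11)
        observed = 15  # ranks of group A
        count = sum(
            1
            for combo in itertools.combinations(pooled, 5)
            if sum(combo) <= observed or sum(combo) >= (55 - observed)
        )
        assert out.loc[0, "p_value"] == pytest.approx(count / 252)
        assert out.loc[0, "p_value"] == pytest.approx(2 / 252)

    def test_matches_exact_enumeration_on_random_samples(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.random(5)
            y = rng.random(5) + rng.uniform(-0.3, 0.3)
            table = make_table({"A": x, "B": y})
            p = pairwise_rank_tests(table, "m").loc[0, "p_value"]
            # enumeration oracle on the rank sum of group A
            pooled = sps.rankdata(np.concatenate([x, y]))
            wx = pooled[:5].sum()
            sums = [sum(c) for c in itertools.combinations(pooled, 5)]
            lo = sum(s <= wx for s in sums)
            hi = sum(s >= wx for s in sums)
            expected = min(1.0, 2 * min(lo, hi) / len(sums))
            assert p == pytest.approx(expected, rel=1e-9)

    def test_all_site_pairs_reported(self, volunteers):
        out = pairwise_rank_tests(volunteers, "volume")
        assert len(out) == 6  # C(4, 2)

    def test_fixture_volume_pairs_nonsignificant(self, volunteers):
        out = pairwise_rank_tests(volunteers, "volume")
        assert (out["p_value"] > 0.05).all()

    def test_mtr_chicago_pairs_significant_raw_but_not_after_holm(self, volunteers):
        # the one assay the study found non-reproducible in vivo: the site
        # with suppressed MTR values separates completely from three others
        out = pairwise_rank_tests(volunteers, "mtr", holm=True)
        sig = out[out["p_value"] < 0.05]
        assert set(map(tuple, sig[["site_a", "site_b"]].values)) == {
            ("Austin", "Chicago"), ("Chicago", "Denver"), ("Chicago", "Nashville")
        }
        assert (out["p_holm"].dropna() > 0.05).all()

    def test_insufficient_pair_flagged_others_computed(self):
        table = make_table({"A": [1.0, 2, 3], "B": [np.nan, np.nan, 4.0], "C": [2.0, 3, 4]})
        out = pairwise_rank_tests(table, "m")
        flagged = out[out["note"] != ""]
        assert len(flagged) == 2  # both pairs involving site B
        assert out[out["note"] == ""]["p_value"].notna().all()


class TestVarianceComponents:
    def test_fixture_inter_individual_exceeds_inter_assay_except_mtr(self, volunteers):
        # MTR is the one measure whose site-to-site spread (driven by one
        # site's suppressed values) exceeds the spread between subjects
        for measure in sorted(volunteers["measure"].unique()):
            vc = variance_components(volunteers, measure)
            if measure == "mtr":
                assert vc.inter_assay_sd > vc.inter_individual_sd
            else:
                assert vc.inter_individual_sd > vc.inter_assay_sd, measure

    def test_constant_table_gives_zero_sds(self):
        table = make_table({s: [5.0, 5.0, 5.0] for s in "AB"})
        vc = variance_components(table, "m")
        assert vc.inter_individual_sd == 0.0
        assert vc.inter_assay_sd == 0.0
        assert vc.grand_mean == 5.0

    def test_oracle_arithmetic_small_table(self):
        table = make_table({"A": [1.0, 5.0], "B": [3.0, 9.0]})
        vc = variance_components(table, "m")
        # subject means 2 and 7; subject SDs sqrt(2) and 2*sqrt(2)
        assert vc.grand_mean == pytest.approx(4.5)
        assert vc.inter_individual_sd == pytest.approx(np.std([2.0, 7.0], ddof=1))
        assert vc.inter_assay_sd == pytest.approx(1.5 * np.sqrt(2))

    def test_zero_subject_sd_leaves_site_scale_residual(self):
        # with no true subject effect, the SD of subject means estimates
        # site_sd / sqrt(n_sites) (up to sampling error)
        from pancmri.phantom import StudyDesign, simulate_multisite_study

        design = StudyDesign(400, 4, {"m": 100.0}, {"m": 0.0}, {"m": 8.0}, seed=11)
        table, _ = simulate_multisite_study(design)
        vc = variance_components(table, "m")
        assert vc.inter_individual_sd == pytest.approx(8.0 / np.sqrt(4), rel=0.15)

    def test_insufficient_subjects_rejected(self):
        table = make_table({"A": [1.0], "B": [2.0]})
        with pytest.raises(InsufficientDataError):
            variance_components(table, "m")


class TestPhantomFixture:
    def test_t1_accuracy_rounds_to_six_percent(self, phantom):
        table, refs = phantom
        pivot = table.pivot(index="site", columns="measure", values="value")
        diffs = [
            percent_difference(v, refs[m])
            for m in ("t1_vial_1", "t1_vial_2", "t1_vial_3", "t1_vial_4")
            for v in pivot[m].dropna()
        ]
        assert len(diffs) == 20
        assert round(float(np.mean(diffs))) == 6

    def test_volume_max_difference_rounds_to_two_percent(self, phantom):
        table, refs = phantom
        vols = table[table["measure"] == "volume"]["value"]
        diffs = [percent_difference(v, refs["volume"]) for v in vols]
        assert len(diffs) == 5
        assert round(max(diffs)) == 2
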