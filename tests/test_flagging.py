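"""Site-wise Z-scoring, flagging, inlier matching, blinded batches."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scanqc import (CohortSpec, build_review_batch, flag_outliers,
                    sample_matched_inliers, simulate_feature_cohort,
                    site_zscores, unblind)
from scanqc.images import InputError


def cohort_frame(values, site="s1"):
    df = pd.DataFrame({"f": values})
    df.index = [f"scan{i:03d}" for i in range(len(values))]
    df["site"] = site
    return df


FEATURES = [c for c in simulate_feature_cohort(CohortSpec())[0].columns
            if c not in ("site", "age", "sex", "MMSE", "amyloid", "APOE")]


@pytest.fixture(scope="module")
def sim_cohort():
    cohort, truth = simulate_feature_cohort(CohortSpec(seed=5))
    return cohort, truth


class TestSiteZscores:
    def test_three_values_standardize_to_unit_steps(self):
        z = site_zscores(cohort_frame([1.0, 2.0, 3.0]), ["f"])
        np.testing.assert_allclose(z["f"].values, [-1, 0, 1])

    def test_constant_feature_gets_zero_z(self):
        z = site_zscores(cohort_frame([5.0, 5.0, 5.0]), ["f"])
        assert (z["f"] == 0).all()

    def test_site_offsets_removed_identical_patterns_identical_z(self):
        a = cohort_frame([1.0, 2.0, 3.0], site="A")
        b = cohort_frame([101.0, 102.0, 103.0], site="B")
        b.index = ["x1", "x2", "x3"]
        z = site_zscores(pd.concat([a, b]), ["f"])
        np.testing.assert_allclose(z["f"].values[:3], z["f"].values[3:])

    def test_single_scan_site_rejected_naming_site(self):
        df = pd.concat([cohort_frame([1.0, 2.0], site="A"),
                        cohort_frame([9.0], site="lonely").rename(index={"scan000": "q"})])
        with pytest.raises(InputError, match="lonely"):
            site_zscores(df, ["f"])

    def test_missing_values_stay_missing(self):
        df = cohort_frame([1.0, np.nan, 3.0])
        z = site_zscores(df, ["f"])
        assert np.isnan(z["f"].iloc[1]) and not np.isnan(z["f"].iloc[0])

    def test_within_site_mean_zero_sd_one(self, sim_cohort):
        cohort, _ = sim_cohort
        z = site_zscores(cohort, FEATURES)
        for _, zg in z.groupby(cohort["site"]):
            assert np.abs(zg.mean()).max() < 1e-10
            assert np.abs(zg.std(ddof=1) - 1).max() < 1e-10


class TestFlagOutliers:
    def test_site_of_20_at_15pct_flags_exactly_3(self):
        rng = np.random.default_rng(0)
        df = cohort_frame(rng.normal(size=20))
        flags = flag_outliers(site_zscores(df, ["f"]), df["site"], fraction=0.15)
        assert (flags.table["status"] == "flagged").sum() == 3

    def test_per_site_flag_fraction_within_ceil_bounds(self, sim_cohort):
        cohort, _ = sim_cohort
        z = site_zscores(cohort, FEATURES)
        flags = flag_outliers(z, cohort["site"], fraction=0.15)
        for site, g in flags.table.groupby("site"):
            frac = (g["status"] == "flagged").mean()
            assert 0.15 <= frac <= 0.15 + 1 / len(g) + 1e-12

    def test_uniform_scores_still_flag_required_count_deterministically(self):
        df = cohort_frame([5.0] * 10)
        z = site_zscores(df, ["f"])
        a = flag_outliers(z, df["site"], fraction=0.2)
        b = flag_outliers(z, df["site"], fraction=0.2)
        assert a.flagged_ids == b.flagged_ids
        assert len(a.flagged_ids) == 2
        # lexicographic tie-break
        assert a.flagged_ids == ["scan000", "scan001"]

    def test_gross_outlier_always_flagged_with_max_score(self, sim_cohort):
        cohort, _ = sim_cohort
        cohort = cohort.copy()
        target = cohort.index[0]
        site = cohort.loc[target, "site"]
        for f in FEATURES[:3]:
            site_sd = cohort.loc[cohort.site == site, f].std(ddof=1)
            cohort.loc[target, f] += 10 * site_sd
        z = site_zscores(cohort, FEATURES)
        # brute-force score: sum of |z| recomputed from raw values
        brute = z.abs().sum(axis=1)
        site_rows = cohort.site == site
        assert brute[target] == brute[site_rows].max()
        flags = flag_outliers(z, cohort["site"], fraction=0.15)
        assert target in flags.flagged_ids

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(c=st.floats(1e-3, 1e3, allow_nan=False))
    def test_flagging_equivariant_to_feature_rescaling(self, c):
        cohort, _ = simulate_feature_cohort(CohortSpec(n_sites=2, scans_per_site=10,
                                                       seed=8))
        scaled = cohort.copy()
        scaled[FEATURES[0]] = scaled[FEATURES[0]] * c
        z0 = site_zscores(cohort, FEATURES)
        z1 = site_zscores(scaled, FEATURES)
        np.testing.assert_allclose(z0.values, z1.values, atol=1e-10)
        f0 = flag_outliers(z0, cohort["site"])
        f1 = flag_outliers(z1, scaled["site"])
        assert f0.flagged_ids == f1.flagged_ids

    def test_missing_features_rescale_scores(self):
        df = cohort_frame([1.0, 2.0, 3.0, 4.0])
        df["g"] = [1.0, 2.0, 3.0, np.nan]
        z = site_zscores(df, ["f", "g"])
        flags = flag_outliers(z, df["site"], fraction=0.25)
        score = flags.table.loc["scan003", "score"]
        assert score == pytest.approx(z.loc["scan003", "f"].__abs__() * 2)

    def test_invalid_fraction_rejected(self):
        df = cohort_frame([1.0, 2.0, 3.0])
        with pytest.raises(InputError):
            flag_outliers(site_zscores(df, ["f"]), df["site"], fraction=1.5)

    def test_detection_of_4sd_corrupted_scans(self):
        recalls = []
        for seed in range(10):
            cohort, truth = simulate_feature_cohort(CohortSpec(seed=100 + seed))
            z = site_zscores(cohort, FEATURES)
            flags = flag_outliers(z, cohort["site"], fraction=0.15)
            corrupted = set(truth.index[truth.is_corrupted])
            if corrupted:
                recalls.append(len(corrupted & set(flags.flagged_ids)) / len(corrupted))
        assert np.mean(recalls) >= 0.9


class TestMatchedInliersAndBatch:
    @pytest.fixture()
    def flags(self, sim_cohort):
        cohort, _ = sim_cohort
        z = site_zscores(cohort, FEATURES)
        return flag_outliers(z, cohort["site"], fraction=0.15)

    def test_matched_counts_equal_flagged_counts_per_site(self, flags):
        res = sample_matched_inliers(flags, seed=3)
        t = res.table
        for site, g in t.groupby("site"):
            assert (g.status == "matched_inlier").sum() == (g.status == "flagged").sum()
        assert not set(res.flagged_ids) & set(res.matched_inlier_ids)

    def test_same_seed_reproduces_selection(self, flags):
        a = sample_matched_inliers(flags, seed=9).matched_inlier_ids
        b = sample_matched_inliers(flags, seed=9).matched_inlier_ids
        assert a == b

    def test_shortfall_takes_all_available_inliers(self):
        df = cohort_frame(list(range(4)))
        z = site_zscores(df, ["f"])
        flags = flag_outliers(z, df["site"], fraction=0.75)  # 3 of 4 flagged
        res = sample_matched_inliers(flags, seed=0)
        assert len(res.matched_inlier_ids) == 1

    def test_review_batch_blinds_status_and_round_trips(self, flags):
        res = sample_matched_inliers(flags, seed=3)
        batch, key = build_review_batch(res, seed=4)
        assert "status" not in batch.columns
        assert len(batch) == len(res.flagged_ids) + len(res.matched_inlier_ids)
        batch2, _ = build_review_batch(res, seed=4)
        assert list(batch2.scan_id) == list(batch.scan_id)
        joined = unblind(batch, key).set_index("scan_id")["status"]
        expected = res.table.loc[joined.index, "status"]
        assert (joined == expected).all()

    def test_empty_review_set_rejected(self, sim_cohort):
        cohort, _ = sim_cohort
        z = site_zscores(cohort, FEATURES)
        flags = flag_outliers(z, cohort["site"], fraction=0.15)
        flags.table["status"] = "unreviewed"
        with pytest.raises(InputError):
            build_review_batch(flags, seed=1)
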