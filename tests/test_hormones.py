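"""Sample selection, reproductive-state coding, outlier removal, frame building."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from droughtnorms import hormones as hp


def female(offspring=(), birth="1995-06-01", **kw):
    return hp.FemaleRecord(
        female_id=kw.pop("female_id", "F0"),
        group_id="G0",
        birth_date=pd.Timestamp(birth),
        rank=0.5,
        offspring=list(offspring),
        **kw,
    )


class TestReproductiveState:
    def test_early_pregnancy(self):
        f = female(offspring=[(pd.Timestamp("2010-06-07"), None)])
        # conception = birth - 158 d = 2009-12-31; 50 days in -> early
        assert hp.assign_reproductive_state(f, "2010-02-19") == "early_pregnancy"

    def test_late_pregnancy_boundary(self):
        f = female(offspring=[(pd.Timestamp("2010-06-07"), None)])
        conception = pd.Timestamp("2010-06-07") - pd.Timedelta(days=158)
        assert hp.assign_reproductive_state(f, conception + pd.Timedelta(days=78)) == "early_pregnancy"
        assert hp.assign_reproductive_state(f, conception + pd.Timedelta(days=79)) == "late_pregnancy"
        assert hp.assign_reproductive_state(f, conception + pd.Timedelta(days=157)) == "late_pregnancy"

    def test_nursing_until_one_year(self):
        f = female(offspring=[(pd.Timestamp("2010-01-01"), None)])
        assert hp.assign_reproductive_state(f, "2010-07-20") == "nursing"  # 200 d post-birth
        assert hp.assign_reproductive_state(f, "2011-01-10") == "nonpregnant_nonnursing"

    def test_nursing_ends_at_infant_death(self):
        f = female(offspring=[(pd.Timestamp("2010-01-01"), pd.Timestamp("2010-03-01"))])
        assert hp.assign_reproductive_state(f, "2010-02-15") == "nursing"
        assert hp.assign_reproductive_state(f, "2010-04-01") == "nonpregnant_nonnursing"

    def test_pre_reproductive(self):
        f = female(birth="2006-01-01")
        assert hp.assign_reproductive_state(f, "2010-07-01") == "pre_reproductive"  # age 4.5

    def test_overlapping_pregnancies_error(self):
        f = female(
            offspring=[
                (pd.Timestamp("2010-06-07"), None),
                (pd.Timestamp("2010-07-07"), None),
            ]
        )
        with pytest.raises(ValueError, match="overlapping"):
            hp.assign_reproductive_state(f, "2010-03-01")

    def test_merge_is_total_over_states(self):
        merged = {hp.merge_state(s) for s in hp.STATES}
        assert merged == set(hp.MERGED_STATES)
        with pytest.raises(ValueError):
            hp.merge_state("unknown")


def samples_on(days, female_id="F0", times=None, month="2010-06", **extra):
    dates = [pd.Timestamp(f"{month}-{d:02d}") for d in days]
    return pd.DataFrame(
        {
            "female_id": female_id,
            "date": dates,
            "collection_time_min": times if times is not None else [540] * len(dates),
            "gc_ng_per_g": 100.0,
            "dry_mass_g": 0.5,
            **extra,
        }
    )


def min_gap(days):
    days = sorted(days)
    return min(b - a for a, b in zip(days, days[1:]))


class TestSelectSamples:
    def test_three_consecutive_days_keep_first_and_last(self):
        out = hp.select_samples(samples_on([10, 11, 12]))
        assert out["date"].dt.day.tolist() == [10, 12]

    def test_two_consecutive_days_keep_first(self):
        out = hp.select_samples(samples_on([10, 11]))
        assert out["date"].dt.day.tolist() == [10]

    def test_same_day_earliest_kept(self):
        df = samples_on([10, 10], times=[840, 540])
        out = hp.select_samples(df)
        assert len(out) == 1 and out["collection_time_min"].iloc[0] == 540

    def test_monthly_cap_max_spread(self):
        out = hp.select_samples(samples_on([1, 5, 10, 15, 20, 25]))
        kept = out["date"].dt.day.tolist()
        assert len(kept) == 4 and 1 in kept and 25 in kept
        # exhaustive oracle over all 4-subsets
        best = max(min_gap(s) for s in itertools.combinations([1, 5, 10, 15, 20, 25], 4))
        assert min_gap(kept) == best

    @settings(max_examples=40, deadline=None)
    @given(st.sets(st.integers(min_value=1, max_value=28), min_size=5, max_size=10))
    def test_monthly_cap_matches_exhaustive_search(self, days):
        # apply the cap alone: pre-thin to non-consecutive days first
        days = sorted(days)
        thinned = []
        for d in days:
            if not thinned or d > thinned[-1] + 1:
                thinned.append(d)
        if len(thinned) <= 4:
            return
        out = hp.select_samples(samples_on(thinned))
        kept = out["date"].dt.day.tolist()
        best = max(min_gap(s) for s in itertools.combinations(thinned, 4))
        assert len(kept) == 4 and min_gap(kept) == best

    def test_study_window_and_mass_filters(self):
        df = pd.concat(
            [
                samples_on([5], month="2007-06"),  # outside window
                samples_on([10]),
                samples_on([20]).assign(dry_mass_g=0.05),  # too little material
            ]
        )
        out = hp.select_samples(df)
        assert out["date"].dt.day.tolist() == [10]

    def test_invariants_and_idempotence(self, default_config, index_table, population):
        rng = np.random.default_rng(7)
        days = sorted(rng.choice(np.arange(1, 29), size=20, replace=False))
        df = pd.concat([samples_on(list(days)), samples_on([3, 4, 5], month="2010-07")])
        out = hp.select_samples(df)
        per_month = out.groupby(out["date"].dt.to_period("M")).size()
        assert (per_month <= 4).all()
        day_gaps = np.diff(out["date"].map(pd.Timestamp.toordinal))
        assert (day_gaps >= 2).all()  # never consecutive, never duplicated
        again = hp.select_samples(out)
        pd.testing.assert_frame_equal(out.reset_index(drop=True), again.reset_index(drop=True))


class TestRemoveOutliers:
    def test_extreme_gc_removed(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(
            {
                "female_id": "F0",
                "date": pd.Timestamp("2010-06-01"),
                "collection_time_min": 540,
                "gc_ng_per_g": np.append(rng.normal(200, 20, 100), 5000.0),
                "dry_mass_g": 0.5,
            }
        )
        kept, log = hp.remove_outliers(df)
        assert len(kept) == 100
        assert log["reason"].tolist() == ["gc_above_10sd"]

    def test_high_cv_removed(self):
        df = samples_on([1, 5, 10], times=[540] * 3)
        df["assay_cv"] = [0.05, 0.25, np.nan]
        kept, log = hp.remove_outliers(df)
        assert len(kept) == 2 and log["reason"].tolist() == ["assay_cv"]

    def test_clean_data_untouched(self):
        rng = np.random.default_rng(9)
        df = samples_on(list(range(1, 21)))
        df["gc_ng_per_g"] = rng.normal(200, 20, 20)
        kept, log = hp.remove_outliers(df)
        assert len(kept) == 20 and len(log) == 0


class TestModelFrame:
    def test_log_transform_and_scaling(self, population, index_table):
        _, _, frame = population
        assert frame["log_gc"].notna().all()
        for col in ("collection_time_scaled", "age_scaled", "rank_scaled", "group_size_scaled"):
            assert abs(frame[col].mean()) < 1e-9
            assert frame[col].std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_row_count_preserved(self, population, index_table):
        females, _, frame = population
        # re-joining the same retained samples must not drop rows
        sub = frame.iloc[:50]
        assert len(sub) == 50

    def test_known_log_value(self, index_table):
        females = {"F0": female(birth="1990-01-01", group_size=10.0)}
        females["F1"] = female(female_id="F1", birth="1992-01-01", group_size=12.0)
        df = pd.DataFrame(
            {
                "female_id": ["F0", "F1"],
                "date": [pd.Timestamp("2010-06-10"), pd.Timestamp("2011-02-10")],
                "collection_time_min": [540, 600],
                "gc_ng_per_g": [100.0, 150.0],
                "dry_mass_g": [0.5, 0.5],
            }
        )
        frame = hp.build_model_frame(df, females, index_table)
        assert frame["log_gc"].iloc[0] == pytest.approx(np.log(100.0))

    def test_planted_outliers_758_of_763(self, index_table):
        """A 763-sample set with 5 planted problems yields 758 model rows."""
        rng = np.random.default_rng(10)
        n = 763
        dates = pd.to_datetime(
            rng.choice(
                pd.date_range("2008-02-01", "2013-12-01", freq="D"), size=n
            )
        )
        df = pd.DataFrame(
            {
                "female_id": [f"F{i % 28:03d}" for i in range(n)],
                "date": dates,
                "collection_time_min": rng.integers(300, 1080, n),
                "gc_ng_per_g": rng.normal(200, 20, n).clip(min=1.0),
                "dry_mass_g": 0.5,
                "assay_cv": 0.05,
            }
        )
        df.loc[df.index[:4], "gc_ng_per_g"] = 10_000.0
        df.loc[df.index[4], "assay_cv"] = 0.25
        females = {
            f"F{i:03d}": female(female_id=f"F{i:03d}", birth="1995-06-01", group_size=10.0)
            for i in range(28)
        }
        retained, log = hp.remove_outliers(df)
        assert len(retained) == 758
        assert sorted(log["reason"]) == ["assay_cv"] + ["gc_above_10sd"] * 4
        frame = hp.build_model_frame(retained, females, index_table)
        assert len(frame) == 758

    def test_unmatched_female_or_date_errors(self, index_table):
        females = {"F0": female(group_size=10.0), "F1": female(female_id="F1", group_size=9.0)}
        df = samples_on([10], female_id="F9")
        with pytest.raises(KeyError, match="F9"):
            hp.build_model_frame(df, females, index_table)
        df2 = samples_on([10], female_id="F0", month="2030-06")
        with pytest.raises(KeyError, match="2030"):
            hp.build_model_frame(df2, females, index_table)
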