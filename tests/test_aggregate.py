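import datetime as dt
import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from emotrend import aggregate as agg
from emotrend.config import MH, NMH, SimConfig, TEEN_COMMUNITY
from emotrend.synthetic import generate_corpus, write_ndjson


def _record(i, author, community="teen", created=1580000000, kind="comment", **kw):
    rec = {
        "id": f"r{i}",
        "author": author,
        "community": community,
        "created_utc": created,
        "title": "",
        "body": "hello world",
        "kind": kind,
    }
    rec.update(kw)
    return rec


def _frame(rows):
    return pd.DataFrame(rows, columns=list(agg.RECORD_FIELDS))


class TestAssignWeek:
    def test_jan_first_excluded(self):
        assert agg.assign_week(dt.datetime(2020, 1, 1, 12, 0), 2020) is None

    def test_dec_31_excluded(self):
        assert agg.assign_week(dt.datetime(2020, 12, 31, 12, 0), 2020) is None

    def test_first_complete_week(self):
        assert agg.assign_week(dt.datetime(2020, 1, 2), 2020) == 1
        assert agg.assign_week(dt.datetime(2020, 1, 8, 23, 59), 2020) == 1
        assert agg.assign_week(dt.datetime(2020, 1, 9), 2020) == 2

    def test_last_complete_week(self):
        assert agg.assign_week(dt.datetime(2020, 12, 30, 23, 59), 2020) == 52

    def test_2020_has_exactly_52_complete_weeks(self):
        assert len(agg.week_bounds(2020)) == 52

    def test_full_year_covers_all_52(self):
        start = dt.datetime(2020, 1, 1, tzinfo=dt.timezone.utc).timestamp()
        days = np.arange(366) * 86400 + start + 3600
        weeks = {agg.assign_week(ts, 2020) for ts in days}
        assert weeks - {None} == set(range(1, 53))

    def test_outside_year_raises(self):
        with pytest.raises(ValueError, match="outside year"):
            agg.assign_week(dt.datetime(2021, 1, 1), 2020)

    def test_vectorized_matches_scalar(self):
        start = dt.datetime(2020, 1, 1, tzinfo=dt.timezone.utc).timestamp()
        ts = start + np.linspace(0, 365 * 86400, 500)
        vec = agg.assign_weeks(ts, 2020)
        for t, w in zip(ts, vec):
            expected = agg.assign_week(t, 2020)
            assert (expected is None and pd.isna(w)) or expected == w


class TestIngest:
    def test_deleted_author_dropped(self, tmp_path):
        rows = [_record(0, "alice"), _record(1, "bob"), _record(2, "carol"),
                _record(3, "[deleted]")]
        path = tmp_path / "c.ndjson"
        path.write_text("\n".join(json.dumps(r) for r in rows) + "\n")
        df, report = agg.ingest_records(path)
        assert len(df) == 3
        assert report.n_deleted_dropped == 1
        assert report.n_read == 4

    def test_empty_file_warns(self, tmp_path):
        path = tmp_path / "empty.ndjson"
        path.write_text("")
        with pytest.warns(UserWarning, match="empty"):
            df, report = agg.ingest_records(path)
        assert df.empty and report.n_read == 0

    def test_malformed_lines_counted(self, tmp_path):
        rows = [json.dumps(_record(i, f"u{i}")) for i in range(20)]
        rows.insert(3, "{not json")
        path = tmp_path / "c.ndjson"
        path.write_text("\n".join(rows) + "\n")
        df, report = agg.ingest_records(path)
        assert report.n_malformed == 1 and len(df) == 20

    def test_too_many_malformed_fatal(self, tmp_path):
        rows = [json.dumps(_record(0, "a")), "oops", "nope"]
        path = tmp_path / "c.ndjson"
        path.write_text("\n".join(rows) + "\n")
        with pytest.raises(ValueError, match="malformed"):
            agg.ingest_records(path, max_malformed_fraction=0.05)

    def test_csv_roundtrip(self, tmp_path):
        records, _ = generate_corpus(SimConfig(n_users=20, seed=2))
        path = tmp_path / "c.csv"
        records.to_csv(path, index=False)
        df, report = agg.ingest_records(path)
        assert len(df) == len(records)
        assert report.n_malformed == 0

    def test_planted_deleted_fraction_recovered(self, tmp_path):
        cfg = SimConfig(n_users=200, deleted_fraction=0.02, seed=21)
        records, ledger = generate_corpus(cfg, with_text=False)
        path = tmp_path / "c.ndjson"
        write_ndjson(records, path)
        df, report = agg.ingest_records(path)
        assert report.n_deleted_dropped == ledger["n_deleted_marked"]
        lo, hi = stats.binom.interval(0.99, report.n_read, 0.02)
        assert lo <= report.n_deleted_dropped <= hi


class TestIdentifyCohort:
    def test_teen_plus_anxiety_is_mh(self):
        df = _frame([_record(0, "a", "teen"), _record(1, "a", "anxiety"), _record(2, "b", "teen")])
        assignment = agg.identify_cohort(df)
        assert assignment.labels == {"a": MH, "b": NMH}

    def test_mh_only_author_excluded(self):
        df = _frame([_record(0, "a", "depression"), _record(1, "b", "teen")])
        assignment = agg.identify_cohort(df)
        assert "a" not in assignment.labels
        assert assignment.n_excluded_mh_only == 1

    def test_partition_properties(self, small_corpus):
        records, _ = small_corpus
        assignment = agg.identify_cohort(records)
        teen_authors = set(records.loc[records["community"] == TEEN_COMMUNITY, "author"])
        assert set(assignment.labels) == teen_authors
        assert assignment.n_mh + assignment.n_nmh == len(assignment.labels)

    def test_matches_generator_ledger(self, small_corpus):
        records, ledger = small_corpus
        assignment = agg.identify_cohort(records)
        for username, info in ledger["users"].items():
            if username in assignment.labels:
                assert assignment.labels[username] == info["cohort"]


class TestWeeklySeries:
    def test_single_author_three_items(self):
        df = _frame([_record(i, "a", created=1580000000 + i) for i in range(3)])
        out = agg.weekly_series(df, "community", n_weeks=52)
        row = out[(out["key"] == "teen") & (out["n_items"] > 0)].iloc[0]
        assert row["n_participants"] == 1
        assert row["n_items"] == 3
        assert row["posts_per_participant"] == 3.0

    def test_two_authors_mean_compound(self):
        rows = [_record(0, "a"), _record(1, "a"), _record(2, "b")]
        df = _frame(rows)
        df["compound"] = [0.2, 0.4, 0.6]
        out = agg.weekly_series(df, "community", n_weeks=52)
        row = out[(out["key"] == "teen") & (out["n_items"] > 0)].iloc[0]
        assert row["n_participants"] == 2
        assert row["posts_per_participant"] == 1.5
        assert row["mean_compound"] == pytest.approx(0.4)

    def test_zero_weeks_flagged_missing(self):
        df = _frame([_record(0, "a")])
        out = agg.weekly_series(df, "community", n_weeks=52)
        teen = out[out["key"] == "teen"]
        assert len(teen) == 52
        empty = teen[teen["n_items"] == 0]
        assert (empty["n_participants"] == 0).all()
        assert empty["posts_per_participant"].isna().all()

    def test_participants_equal_bruteforce_distinct_sets(self, small_corpus):
        records, _ = small_corpus
        records = records.copy()
        records["week"] = agg.assign_weeks(records["created_utc"], 2020)
        out = agg.weekly_series(records, "community", n_weeks=52)
        teen = records[records["community"] == "teen"]
        for week, sub in teen.groupby("week"):
            expected = len({a for a in sub["author"]})
            got = out[(out["key"] == "teen") & (out["week"] == week)]["n_participants"].iloc[0]
            assert got == expected

    def test_ppp_at_least_one(self, small_corpus):
        records, _ = small_corpus
        out = agg.weekly_series(records, "cohort", n_weeks=52)
        active = out[out["n_participants"] > 0]
        assert (active["posts_per_participant"] >= 1.0).all()

    def test_unmatched_mh_authors_excluded(self):
        rows = [_record(0, "a", "teen"), _record(1, "a", "anxiety"), _record(2, "z", "anxiety")]
        out = agg.weekly_series(_frame(rows), "community", n_weeks=52)
        anx = out[out["key"] == "anxiety"]
        assert anx["n_items"].sum() == 1  # z's item excluded

    def test_weekly_mean_frequency_tracks_planted_intensity(self):
        cfg = SimConfig(n_users=600, fraction_mh=0.0, user_heterogeneity=0.0, seed=17)
        records, ledger = generate_corpus(cfg, with_text=False)
        out = agg.weekly_series(records, "cohort", n_weeks=52)
        nmh = out[out["key"] == NMH].sort_values("week")
        lam = cfg.rate_params[NMH].intensity(np.arange(1, 53), cfg.interruption_week)
        # posts-per-participant estimates lambda / (1 - exp(-lambda))
        expected = lam / (1 - np.exp(-lam))
        se = np.sqrt(lam / 600)
        z = (nmh["posts_per_participant"].to_numpy() - expected) / se
        assert np.abs(z).max() < 4

    def test_filtering_order_changes_counts_by_dropped_membership(self):
        rows = [_record(0, "a"), _record(1, "b"), _record(2, "[deleted]")]
        df_all = _frame(rows)
        df_filtered = df_all[df_all["author"] != "[deleted]"]
        s_all = agg.weekly_series(df_all, "community", n_weeks=52)
        s_f = agg.weekly_series(df_filtered, "community", n_weeks=52)
        week = s_all[(s_all["key"] == "teen") & (s_all["n_items"] > 0)].iloc[0]
        week_f = s_f[(s_f["key"] == "teen") & (s_f["n_items"] > 0)].iloc[0]
        assert week["n_items"] - week_f["n_items"] == 1
        assert week["n_participants"] - week_f["n_participants"] == 1


class TestPercentChange:
    def test_identity(self):
        assert agg.percent_change(5.0, 5.0) == 0

    def test_increase(self):
        assert agg.percent_change(4.56, 6.15) == 35

    def test_decline_magnitude(self):
        pct, direction = agg.describe_percent_change(5.49, 3.14)
        assert (pct, direction) == (43, "decline")

    def test_round_half_away_from_zero(self):
        assert agg.percent_change(200.0, 201.0) == 1  # 0.5 -> 1
        assert agg.percent_change(200.0, 199.0) == -1  # -0.5 -> -1

    def test_nonpositive_baseline(self):
        with pytest.raises(ValueError, match="positive"):
            agg.percent_change(0.0, 5.0)


class TestScaleForDisplay:
    def test_factor_30(self):
        assert list(agg.scale_for_display([1, 2, 3], 30)) == [30, 60, 90]

    def test_identity(self):
        np.testing.assert_allclose(agg.scale_for_display([1.5, 2.5], 1.0), [1.5, 2.5])

    def test_round_trip(self):
        x = np.array([0.1, 2.7, 9.9])
        back = agg.scale_for_display(agg.scale_for_display(x, 30.0), 1 / 30.0)
        np.testing.assert_allclose(back, x, rtol=1e-12)

    def test_records_factor_on_frames(self):
        df = pd.DataFrame({"v": [1.0, 2.0]})
        out = agg.scale_for_display(df, 30.0)
        assert out.attrs["display_scale"] == 30.0

    def test_rejects_nonpositive_factor(self):
        with pytest.raises(ValueError):
            agg.scale_for_display([1.0], 0.0)
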