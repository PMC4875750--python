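import logging

import pandas as pd
import pytest

from perilink.records import (
    CleaningRules,
    RecordSet,
    clean_records,
    derive_fields,
    missingness_summary,
    read_records,
    write_records,
)


def _write_csv(path, rows, header):
    path.write_text(header + "\n" + "\n".join(rows) + "\n")


class TestReadRecords:
    def test_identity_parse(self, tmp_path):
        p = tmp_path / "r.csv"
        _write_csv(
            p,
            [
                "a,1995-03-01,male,24,680",
                "b,1995-04-02,female,25,720",
                "c,1995-05-03,male,23,555",
            ],
            "id,date_of_birth,sex,gestational_age,birth_weight",
        )
        rs = read_records(p, "cohort")
        assert len(rs) == 3
        assert rs.df["date_of_birth"].iloc[0] == pd.Timestamp("1995-03-01")
        assert rs.df["gestational_age"].tolist() == [24, 25, 23]
        assert rs.df.notna().all().all()

    def test_empty_cell_becomes_missing(self, tmp_path):
        p = tmp_path / "r.csv"
        _write_csv(p, ["a,1995-03-01,", "b,,700"], "id,date_of_birth,birth_weight")
        rs = read_records(p, "cohort")
        assert pd.isna(rs.df["birth_weight"].iloc[0])
        assert pd.isna(rs.df["date_of_birth"].iloc[1])

    def test_missing_id_column_is_fatal(self, tmp_path):
        p = tmp_path / "r.csv"
        _write_csv(p, ["1995-03-01"], "date_of_birth")
        with pytest.raises(ValueError, match="id column"):
            read_records(p, "cohort")

    def test_unparseable_date_kept_as_missing_row(self, tmp_path, caplog):
        p = tmp_path / "r.csv"
        _write_csv(p, ["a,not-a-date,650"], "id,date_of_birth,birth_weight")
        with caplog.at_level(logging.WARNING):
            rs = read_records(p, "cohort")
        assert len(rs) == 1
        assert pd.isna(rs.df["date_of_birth"].iloc[0])
        assert rs.df["birth_weight"].iloc[0] == 650

    def test_unknown_columns_ignored(self, tmp_path):
        p = tmp_path / "r.csv"
        _write_csv(p, ["a,male,zzz"], "id,sex,mystery")
        rs = read_records(p, "cohort")
        assert "mystery" not in rs.df.columns

    def test_roundtrip(self, tmp_path, tiny_cohort):
        p = tmp_path / "out.csv"
        write_records(tiny_cohort, p)
        back = read_records(p, "cohort")
        assert back.df["date_of_birth"].equals(tiny_cohort.df["date_of_birth"])
        assert back.df["gestational_age"].tolist() == [24, 25, 23]


class TestCleanRecords:
    def _rs(self, rows):
        df = pd.DataFrame(rows)
        df["date_of_birth"] = pd.to_datetime(df["date_of_birth"])
        return RecordSet(df, "episodes")

    def test_duplicates_removed_and_counted(self):
        rows = [{"id": f"r{i}", "date_of_birth": "1995-06-01"} for i in range(3)]
        rows += [rows[0].copy(), rows[1].copy()]
        rs = self._rs(rows)
        cleaned, report = clean_records(rs, CleaningRules(drop_duplicates=True))
        assert len(cleaned) == 3
        assert report.duplicates_removed == 2

    def test_period_restriction_and_missing_dob_retention(self):
        rs = self._rs(
            [
                {"id": "a", "date_of_birth": "1995-01-15"},
                {"id": "b", "date_of_birth": "1995-03-01"},
                {"id": "c", "date_of_birth": "1995-12-31"},
                {"id": "d", "date_of_birth": None},
            ]
        )
        rules = CleaningRules(
            period_start="1995-03-01", period_end="1995-12-31", retain_missing_dob=True
        )
        cleaned, report = clean_records(rs, rules)
        # inclusive endpoints kept; pre-period removed; missing dob retained
        assert cleaned.ids.tolist() == ["b", "c", "d"]
        assert report.out_of_period_removed == 1

        rules_drop = CleaningRules(
            period_start="1995-03-01", period_end="1995-12-31", retain_missing_dob=False
        )
        cleaned2, _ = clean_records(rs, rules_drop)
        assert cleaned2.ids.tolist() == ["b", "c"]

    def test_identity_on_clean_input(self, tiny_cohort):
        cleaned, report = clean_records(tiny_cohort, CleaningRules())
        assert report.total_removed == 0
        assert cleaned.df.equals(tiny_cohort.df)

    def test_idempotent(self):
        rs = self._rs(
            [
                {"id": "a", "date_of_birth": "1995-01-15"},
                {"id": "b", "date_of_birth": "1995-06-01"},
                {"id": "b", "date_of_birth": "1995-06-01"},
            ]
        )
        rules = CleaningRules(period_start="1995-03-01", period_end="1995-12-31")
        once, r1 = clean_records(rs, rules)
        twice, r2 = clean_records(once, rules)
        assert twice.df.equals(once.df)
        assert r2.total_removed == 0

    def test_count_conservation(self):
        rs = self._rs(
            [
                {"id": "a", "date_of_birth": "1994-06-01", "vital_status": "live"},
                {"id": "b", "date_of_birth": "1995-06-01", "vital_status": "termination"},
                {"id": "c", "date_of_birth": "1995-06-01", "vital_status": "live"},
                {"id": "c", "date_of_birth": "1995-06-01", "vital_status": "live"},
            ]
        )
        rules = CleaningRules(
            period_start="1995-03-01",
            period_end="1995-12-31",
            exclusion_categories=["termination"],
        )
        cleaned, report = clean_records(rs, rules)
        assert len(cleaned) == len(rs) - report.total_removed == 1


class TestDeriveFields:
    def test_death_date_from_discharge(self):
        df = pd.DataFrame(
            {
                "id": ["a", "b"],
                "discharge_date": pd.to_datetime(["1995-06-01", "1995-06-10"]),
                "discharge_method": ["died", "discharged home"],
                "date_of_death": pd.to_datetime([pd.NaT, pd.NaT]),
            }
        )
        out = derive_fields(RecordSet(df, "episodes"))
        assert out.df["date_of_death"].iloc[0] == pd.Timestamp("1995-06-01")
        assert pd.isna(out.df["date_of_death"].iloc[1])

    def test_maternal_age_completed_years(self):
        df = pd.DataFrame(
            {
                "id": ["a", "b"],
                "mother_dob": pd.to_datetime(["1970-03-10", "1970-03-10"]),
                "date_of_birth": pd.to_datetime(["1995-03-09", "1995-03-10"]),
            }
        )
        out = derive_fields(RecordSet(df, "cohort"))
        # day before the 25th birthday -> 24 completed years; on it -> 25
        assert out.df["maternal_age"].tolist() == [24, 25]

    def test_negative_derived_age_set_missing(self, caplog):
        df = pd.DataFrame(
            {
                "id": ["a"],
                "mother_dob": pd.to_datetime(["1996-01-01"]),
                "date_of_birth": pd.to_datetime(["1995-06-01"]),
            }
        )
        with caplog.at_level(logging.WARNING):
            out = derive_fields(RecordSet(df, "cohort"))
        assert pd.isna(out.df["maternal_age"].iloc[0])

    def test_ethnicity_recode(self):
        df = pd.DataFrame({"id": ["a", "b"], "ethnicity": ["A1", "Z"]})
        out = derive_fields(RecordSet(df, "episodes"), ethnicity_map={"A1": "White British"})
        assert out.df["ethnicity"].tolist() == ["White British", "Z"]


class TestMissingness:
    def test_fraction_arithmetic(self):
        df = pd.DataFrame({"id": range(4), "sex": ["male", None, "female", "male"]})
        summary = missingness_summary(RecordSet(df, "cohort"), ["sex"])
        assert summary.loc["sex", "n_missing"] == 1
        assert summary.loc["sex", "pct_missing"] == 25.00

    def test_fully_populated(self, tiny_cohort):
        summary = missingness_summary(tiny_cohort, ["sex"])
        assert summary.loc["sex", "n_missing"] == 0
        assert summary.loc["sex", "pct_missing"] == 0.00

    def test_bounds_property(self, small_linked):
        from perilink.synthetic import inject_missingness

        episodes = inject_missingness(
            small_linked.episodes, {"sex": 0.3, "birth_weight": 0.7}, seed=3
        )
        summary = missingness_summary(episodes)
        assert ((summary["pct_missing"] >= 0) & (summary["pct_missing"] <= 100)).all()
        n = len(episodes)
        expected = (100 * summary["n_missing"] / n).round(2)
        assert (summary["pct_missing"] == expected).all()
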