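"""Cohort loading, phenotype derivation and descriptive summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from famprs import (
    derive_copd_status,
    harmonize_family_history,
    load_cohort,
    standardize_and_bin_prs,
    summarize_cohort,
    write_cohort,
)
from famprs.cohort import SchemaError


def _write(tmp_path, text, name="cohort.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestLoad:
    def test_identity_read(self, tmp_path):
        p = _write(tmp_path, (
            "subject_id,age,fev1_pp,fev1_fvc,fh_copd,prs_raw\n"
            "a,61,95,0.78,no,0.1\n"
            "b,55,45,0.40,yes,1.2\n"
            "c,70,85,0.65,unknown,-0.3\n"
            "d,48,70,0.75,no,0.0\n"
            "e,66,90,0.72,,0.5\n"))
        df = load_cohort(p)
        assert len(df) == 5
        assert df.attrs["provenance"]["n_rows"] == 5
        assert df["age"].tolist() == [61, 55, 70, 48, 66]

    def test_missing_required_column_names_it(self, tmp_path):
        p = _write(tmp_path, "subject_id,age\na,61\n")
        with pytest.raises(SchemaError, match="fev1_pp"):
            load_cohort(p, require=["fev1_pp"])

    def test_unknown_family_history_kept_as_level_not_missing(self, tmp_path):
        p = _write(tmp_path, "fh_copd\nyes\nunknown\nno\n")
        df = load_cohort(p)
        assert df["fh_copd"].tolist() == ["yes", "unknown", "no"]
        assert df["fh_copd"].notna().all()

    def test_unparseable_cell_reports_line(self, tmp_path):
        p = _write(tmp_path, "age\n61\nxx\n70\n")
        with pytest.raises(SchemaError, match=r"line.*\[3\]"):
            load_cohort(p)

    def test_column_mapping(self, tmp_path):
        p = _write(tmp_path, "ID,FEV1PP\na,95\n")
        df = load_cohort(p, column_map={"subject_id": "ID", "fev1_pp": "FEV1PP"})
        assert df["fev1_pp"].iloc[0] == 95

    def test_round_trip_preserves_values(self, tmp_path, cohort_small):
        out = tmp_path / "rt.csv"
        write_cohort(cohort_small.drop(
            columns=["copd_status", "copd_case", "family_history",
                     "frequent_exacerbations", "prs_z", "prs_top_tertile"]), out)
        back = load_cohort(out)
        for col in ("age", "fev1_pp", "fev1_fvc", "prs_raw", "pack_years"):
            np.testing.assert_allclose(
                back[col].to_numpy(dtype=float),
                cohort_small[col].to_numpy(dtype=float), rtol=0, atol=0)
        assert back["fh_copd"].tolist() == cohort_small["fh_copd"].tolist()
        assert back["sex"].tolist() == cohort_small["sex"].tolist()


class TestCopdStatus:
    @pytest.mark.parametrize("fev,ratio,expected", [
        (48.8, 0.48, "case"),       # typical moderate-severe case spirometry
        (85.0, 0.65, "excluded"),   # GOLD 1: obstructed but preserved FEV1
        (70.0, 0.75, "excluded"),   # PRISm: low FEV1, preserved ratio
        (94.9, 0.77, "control"),
        (80.0, 0.70, "control"),    # boundary: >= thresholds
        (79.999, 0.699, "case"),
    ])
    def test_classification(self, fev, ratio, expected):
        df = pd.DataFrame({"fev1_pp": [fev], "fev1_fvc": [ratio]})
        assert derive_copd_status(df).iloc[0] == expected

    def test_missing_spirometry_is_missing_status(self):
        df = pd.DataFrame({"fev1_pp": [np.nan, 90], "fev1_fvc": [0.5, np.nan]})
        assert derive_copd_status(df).isna().all()

    def test_requires_spirometry_columns(self):
        with pytest.raises(SchemaError, match="fev1_fvc"):
            derive_copd_status(pd.DataFrame({"fev1_pp": [90.0]}))

    @given(fev=st.floats(1, 150), ratio=st.floats(0, 1))
    def test_partition_complete_spirometry(self, fev, ratio):
        """Every complete-spirometry record maps to exactly one status."""
        df = pd.DataFrame({"fev1_pp": [fev], "fev1_fvc": [ratio]})
        status = derive_copd_status(df).iloc[0]
        assert status in ("case", "control", "excluded")

    @given(fev=st.floats(1, 79.99), ratio=st.floats(0, 0.6999))
    def test_case_monotone_in_severity(self, fev, ratio):
        """Worsening spirometry below both thresholds never leaves case."""
        df = pd.DataFrame({"fev1_pp": [fev, fev / 2], "fev1_fvc": [ratio, ratio / 2]})
        assert (derive_copd_status(df) == "case").all()


class TestFamilyHistory:
    def _df(self, copd, cb, emph):
        return pd.DataFrame({"fh_copd": [copd], "fh_chronic_bronchitis": [cb],
                             "fh_emphysema": [emph]})

    def test_any_yes_dominates_unknown(self):
        df = self._df("unknown", "no", "yes")
        assert harmonize_family_history(df, "copdgene_full").iloc[0] == True  # noqa: E712

    def test_unknown_counts_as_no(self):
        df = self._df("unknown", "no", "no")
        assert harmonize_family_history(df, "copdgene_full").iloc[0] == False  # noqa: E712

    def test_harmonized_mode_ignores_copd_item(self):
        df = self._df("yes", "no", "no")
        assert harmonize_family_history(df, "eclipse_harmonized").iloc[0] == False  # noqa: E712
        assert harmonize_family_history(df, "copdgene_full").iloc[0] == True  # noqa: E712

    def test_exclude_unknown_all_unknown_missing(self):
        df = self._df("unknown", "unknown", "unknown")
        assert harmonize_family_history(df, "exclude_unknown").isna().all()
        # primary coding maps the same record to negative
        assert harmonize_family_history(df, "copdgene_full").iloc[0] == False  # noqa: E712

    def test_idempotent_and_deterministic(self, cohort_small):
        a = harmonize_family_history(cohort_small, "copdgene_full")
        b = harmonize_family_history(cohort_small, "copdgene_full")
        pd.testing.assert_series_equal(a, b)

    def test_bad_mode(self, cohort_small):
        with pytest.raises(ValueError, match="mode"):
            harmonize_family_history(cohort_small, "nope")


class TestPrs:
    def test_standardized_within_group(self, cohort_small):
        out = standardize_and_bin_prs(cohort_small)
        assert abs(out["prs_z"].mean()) < 1e-9
        assert abs(out["prs_z"].std(ddof=1) - 1) < 1e-9

    def test_top_tertile_of_1_to_9(self):
        df = pd.DataFrame({"prs_raw": np.arange(1.0, 10.0)})
        out = standardize_and_bin_prs(df, group_col=None)
        assert out.loc[out["prs_top_tertile"].astype(bool), "prs_raw"].tolist() == [7, 8, 9]

    def test_tertile_count_near_third(self, cohort_small):
        out = standardize_and_bin_prs(cohort_small)
        n = len(out)
        k = int(out["prs_top_tertile"].sum())
        assert k in (int(np.floor(n / 3)), int(np.ceil(n / 3)))

    def test_groups_standardized_independently(self):
        df = pd.DataFrame({
            "cohort": ["a"] * 50 + ["b"] * 50,
            "prs_raw": np.r_[np.random.default_rng(1).normal(5, 2, 50),
                             np.random.default_rng(2).normal(-3, 0.5, 50)],
        })
        out = standardize_and_bin_prs(df)
        for g in ("a", "b"):
            sub = out[out["cohort"] == g]["prs_z"]
            assert abs(sub.mean()) < 1e-9 and abs(sub.std(ddof=1) - 1) < 1e-9

    def test_degenerate_prs_errors(self):
        df = pd.DataFrame({"prs_raw": [1.0, 1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="[Dd]egenerate|distinct"):
            standardize_and_bin_prs(df, group_col=None)


class TestSummary:
    def test_family_history_percentages(self):
        """Count/percent logic on a table shaped like a published cohort."""
        rows = []
        for status, n, k in (("control", 2506, 710), ("case", 2668, 991)):
            rows += [{"copd_status": status, "family_history": i < k}
                     for i in range(n)]
        tab = summarize_cohort(pd.DataFrame(rows),
                               continuous=[], categorical=["family_history"])
        fh = tab[tab["variable"] == "family_history"].iloc[0]
        assert round(fh["control_percent"], 1) == 28.3
        assert round(fh["case_percent"], 1) == 37.1
        assert fh["control_count"] == 710 and fh["case_count"] == 991

    def test_zero_positive_group(self):
        df = pd.DataFrame({"copd_status": ["control"] * 5 + ["case"] * 5,
                           "severe_exacerbation": [False] * 5 + [True] * 5})
        tab = summarize_cohort(df, continuous=[],
                               categorical=["severe_exacerbation"])
        row = tab.iloc[-1]
        assert row["control_percent"] == 0.0
        assert row["case_percent"] == 100.0

    def test_continuous_summary_and_test(self, cohort_small):
        tab = summarize_cohort(cohort_small, continuous=["age", "pack_years"],
                               categorical=["sex"])
        age = tab[tab["variable"] == "age"].iloc[0]
        assert age["kind"] in ("mean_sd", "median_iqr")
        assert 0 <= age["p_value"] <= 1
        sex = tab[tab["variable"] == "sex"].iloc[0]
        assert sex["test"] == "chi2"

    def test_missing_group_column(self, cohort_small):
        with pytest.raises(SchemaError):
            summarize_cohort(cohort_small.drop(columns="copd_status"))
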