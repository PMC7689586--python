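"""Cohort data model: loading, phenotype/predictor derivation, summaries.

The central object is a plain :class:`pandas.DataFrame` using canonical
column names (see :data:`SCHEMA`). Moderate-to-severe COPD case status is
derived from post-bronchodilator spirometry: cases have FEV1 % predicted
< 80 and FEV1/FVC < 0.7; controls have FEV1 % predicted >= 80 and
FEV1/FVC >= 0.7. Subjects with mild obstruction only (GOLD 1: ratio < 0.7
but preserved FEV1) or preserved-ratio impaired spirometry (PRISm:
ratio >= 0.7 but FEV1 < 80) are excluded from both groups.

Family history is a parent-report composite of COPD, chronic bronchitis and
emphysema; a response of "unknown" counts as "no" in the primary coding,
with an exclude-unknown sensitivity mode and a harmonized mode restricted
to chronic bronchitis / emphysema for cohorts whose questionnaire lacks a
COPD item.
"""

from __future__ import annotations

import json
import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: canonical column name -> semantic dtype ("float", "int", "bool", "str",
#: "fh" for yes/no/unknown enums). pcs are pc1..pcK, detected by prefix.
SCHEMA: dict[str, str] = {
    "subject_id": "str",
    "cohort": "str",
    "age": "float",
    "sex": "str",  # {female, male}
    "pack_years": "float",
    "current_smoker": "bool",
    "height": "float",
    "weight": "float",
    "bmi": "float",
    "fev1_pp": "float",
    "fev1_fvc": "float",
    "fh_copd": "fh",
    "fh_chronic_bronchitis": "fh",
    "fh_emphysema": "fh",
    "prs_raw": "float",
    "exacerbations_12mo": "int",
    "severe_exacerbation": "bool",
    "dead": "bool",
    "bode": "float",
    "sgrq_total": "float",
    "sixmwd": "float",
    "pct_laa950": "float",
    "perc15": "float",
    "pi10": "float",
    "wa_pct": "float",
    "visual_ct_subtype": "str",
    "ct_scanner": "str",
}

FH_FIELDS = ("fh_copd", "fh_chronic_bronchitis", "fh_emphysema")
FH_LEVELS = frozenset({"yes", "no", "unknown"})

_BOOL_MAP = {
    "true": True, "false": False, "1": True, "0": False,
    "yes": True, "no": False, "t": True, "f": False,
}


class SchemaError(ValueError):
    """A required column is absent or a cell cannot be parsed."""


def _coerce_column(s: pd.Series, kind: str, name: str) -> pd.Series:
    """Coerce one raw column to its semantic dtype, reporting bad rows.

    Row numbers in error messages are 1-based file line numbers assuming a
    single header line.
    """
    if kind in ("float", "int"):
        out = pd.to_numeric(s, errors="coerce")
        bad = out.isna() & s.notna() & (s.astype(str).str.strip() != "")
        if bad.any():
            lines = [int(i) + 2 for i in np.flatnonzero(bad.to_numpy())][:5]
            raise SchemaError(
                f"column {name!r}: unparseable numeric cell(s) at file line(s) {lines}"
            )
        # re-parse through the correctly-rounded parser so write/load
        # round-trips bit-exactly (pandas' fast parser can be off one ulp)
        mask = out.notna().to_numpy()
        exact = np.full(len(s), np.nan)
        exact[mask] = [float(v) for v in s[mask]]
        out = pd.Series(exact, index=s.index)
        if kind == "int":
            vals = out.dropna()
            if not np.allclose(vals, np.round(vals)):
                raise SchemaError(f"column {name!r}: non-integer count values")
            out = out.round().astype("Int64")
        return out
    if kind == "bool":
        low = s.astype(str).str.strip().str.lower()
        out = low.map(_BOOL_MAP)
        bad = out.isna() & s.notna() & (low != "") & (low != "nan")
        if bad.any():
            lines = [int(i) + 2 for i in np.flatnonzero(bad.to_numpy())][:5]
            raise SchemaError(
                f"column {name!r}: unparseable boolean cell(s) at file line(s) {lines}"
            )
        return out.astype("boolean")
    if kind == "fh":
        low = s.astype(str).str.strip().str.lower().replace({"nan": None, "": None})
        bad = low.notna() & ~low.isin(FH_LEVELS)
        if bad.any():
            lines = [int(i) + 2 for i in np.flatnonzero(bad.to_numpy())][:5]
            raise SchemaError(
                f"column {name!r}: family-history responses must be yes/no/unknown; "
                f"bad cell(s) at file line(s) {lines}"
            )
        return low
    return s.astype("string").astype(object)


def load_cohort(
    path,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
    na_values: Iterable[str] = ("", "NA", "NaN"),
    require: Iterable[str] = (),
) -> pd.DataFrame:
    """Read a delimited cohort table into canonical form.

    Parameters
    ----------
    path
        CSV/TSV file. The delimiter is inferred from the extension unless
        ``sep`` is given.
    column_map
        Mapping ``canonical_name -> column name in the file`` for columns
        whose headers differ from :data:`SCHEMA`.
    require
        Canonical columns that must be present (e.g. ``["fev1_pp",
        "fev1_fvc"]`` when COPD status will be derived).

    Returns
    -------
    DataFrame with canonical columns, typed per :data:`SCHEMA`;
    ``df.attrs["provenance"]`` records the row count and per-column
    missingness.
    """
    path = str(path)
    if sep is None:
        sep = "\t" if path.endswith((".tsv", ".txt")) else ","
    raw = pd.read_csv(
        path, sep=sep, dtype=str, na_values=list(na_values), keep_default_na=False
    )
    rename = {}
    if column_map:
        for canonical, source in column_map.items():
            if source not in raw.columns:
                raise SchemaError(f"mapped column {source!r} (for {canonical!r}) not in file")
            rename[source] = canonical
    raw = raw.rename(columns=rename)

    missing = [c for c in require if c not in raw.columns]
    if missing:
        raise SchemaError(f"required column(s) missing from {path}: {missing}")

    out = {}
    for name in raw.columns:
        if name in SCHEMA:
            out[name] = _coerce_column(raw[name], SCHEMA[name], name)
        elif name.startswith("pc") and name[2:].isdigit():
            out[name] = _coerce_column(raw[name], "float", name)
        else:
            out[name] = raw[name]
    df = pd.DataFrame(out)
    prov = {
        "path": path,
        "n_rows": int(len(df)),
        "missing_per_column": {c: int(df[c].isna().sum()) for c in df.columns},
    }
    df.attrs["provenance"] = prov
    logger.info("loaded cohort %s", json.dumps(prov))
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort table to CSV (round-trips through :func:`load_cohort`)."""
    out = df.copy()
    for c in out.columns:
        if isinstance(out[c].dtype, pd.BooleanDtype) or out[c].dtype == bool:
            out[c] = out[c].map({True: "true", False: "false"})
    out.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------- derivation

def derive_copd_status(df: pd.DataFrame) -> pd.Series:
    """Classify each subject as COPD case / control / excluded.

    Requires ``fev1_pp`` and ``fev1_fvc``. Rows missing either are returned
    as missing (dropped from COPD analyses only) and counted in the log.
    """
    for col in ("fev1_pp", "fev1_fvc"):
        if col not in df.columns:
            raise SchemaError(f"COPD status derivation requires column {col!r}")
    fev = pd.to_numeric(df["fev1_pp"], errors="coerce")
    ratio = pd.to_numeric(df["fev1_fvc"], errors="coerce")
    status = pd.Series(pd.NA, index=df.index, dtype=object)
    ok = fev.notna() & ratio.notna()
    case = ok & (fev < 80) & (ratio < 0.7)
    control = ok & (fev >= 80) & (ratio >= 0.7)
    status[case] = "case"
    status[control] = "control"
    status[ok & ~case & ~control] = "excluded"  # GOLD 1 or PRISm
    n_missing = int((~ok).sum())
    if n_missing:
        logger.info("derive_copd_status: %d record(s) missing spirometry", n_missing)
    return pd.Series(
        pd.Categorical(status, categories=["control", "case", "excluded"]),
        index=df.index,
        name="copd_status",
    )


def harmonize_family_history(df: pd.DataFrame, mode: str = "copdgene_full") -> pd.Series:
    """Collapse the parent-report questionnaire fields into one binary exposure.

    Modes
    -----
    ``copdgene_full``
        Positive iff any of COPD / chronic bronchitis / emphysema is "yes";
        "unknown" counts as "no" (primary coding).
    ``eclipse_harmonized``
        Same rule over chronic bronchitis and emphysema only, matching
        cohorts whose questionnaire has no COPD item.
    ``exclude_unknown``
        Sensitivity coding: subjects whose every contributing response is
        "unknown" become missing instead of negative.
    """
    if mode not in ("copdgene_full", "eclipse_harmonized", "exclude_unknown"):
        raise ValueError(f"unknown family-history mode {mode!r}")
    fields = FH_FIELDS if mode != "eclipse_harmonized" else FH_FIELDS[1:]
    present = [f for f in fields if f in df.columns]
    if not present:
        raise SchemaError(f"no family-history columns among {fields}")
    sub = df[present]
    # already-harmonized input: a boolean family_history column passes through
    any_yes = sub.isin(["yes"]).any(axis=1)
    any_answer = sub.notna().any(axis=1)
    all_unknown = any_answer & sub.apply(
        lambda s: s.isin(["unknown"]) | s.isna()
    ).all(axis=1)
    out = pd.Series(pd.NA, index=df.index, dtype="boolean")
    out[any_answer] = any_yes[any_answer]
    if mode == "exclude_unknown":
        out[all_unknown] = pd.NA
    n_missing = int(out.isna().sum())
    if n_missing:
        logger.info("harmonize_family_history(%s): %d missing", mode, n_missing)
    out.name = "family_history"
    return out


def standardize_and_bin_prs(
    df: pd.DataFrame, group_col: str | None = "cohort"
) -> pd.DataFrame:
    """Add ``prs_z`` (per-group SD units) and ``prs_top_tertile``.

    Standardization uses the group's sample mean and SD (ddof=1) over every
    subject with a raw score, before any outcome filtering, so odds ratios
    per SD refer to the full cohort's scale. The top tertile is scores
    strictly above the empirical 2/3 quantile (linear-interpolation
    quantile; ties at the cut fall below).
    """
    out = df.copy()
    if "prs_raw" not in out.columns:
        raise SchemaError("standardize_and_bin_prs requires column 'prs_raw'")
    if group_col is not None and group_col in out.columns:
        groups = out.groupby(group_col, observed=True).groups
    else:
        groups = {"_all": out.index}
    out["prs_z"] = np.nan
    out["prs_top_tertile"] = pd.Series(pd.NA, index=out.index, dtype="boolean")
    for label, idx in groups.items():
        vals = pd.to_numeric(out.loc[idx, "prs_raw"], errors="coerce")
        obs = vals.dropna()
        if obs.nunique() < 3:
            raise ValueError(f"group {label!r}: need >=3 distinct PRS values")
        sd = obs.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"group {label!r}: degenerate PRS (zero variance)")
        out.loc[idx, "prs_z"] = (vals - obs.mean()) / sd
        cut = float(np.quantile(obs.to_numpy(), 2.0 / 3.0))
        out.loc[idx, "prs_top_tertile"] = pd.array(vals > cut, dtype="boolean")
        out.loc[idx[vals.isna()], "prs_top_tertile"] = pd.NA
    return out


def derive_cohort(
    df: pd.DataFrame,
    fh_mode: str = "copdgene_full",
    group_col: str | None = "cohort",
) -> pd.DataFrame:
    """Attach all derived analysis columns.

    Adds ``copd_status``, ``copd_case`` (1/0 for case/control, missing for
    excluded), ``family_history``, ``frequent_exacerbations``
    (>1 exacerbation in the prior 12 months, equivalently >=2 for integer
    counts), ``prs_z`` and ``prs_top_tertile``.
    """
    out = standardize_and_bin_prs(df, group_col=group_col)
    out["copd_status"] = derive_copd_status(out)
    case = pd.Series(np.nan, index=out.index)
    case[out["copd_status"] == "case"] = 1.0
    case[out["copd_status"] == "control"] = 0.0
    out["copd_case"] = case
    out["family_history"] = harmonize_family_history(out, mode=fh_mode)
    if "exacerbations_12mo" in out.columns:
        ex = out["exacerbations_12mo"]
        out["frequent_exacerbations"] = (ex > 1).astype("boolean").where(ex.notna())
    return out


# ----------------------------------------------------------------- summaries

_DEF_CONTINUOUS = (
    "age", "bmi", "pack_years", "sgrq_total", "sixmwd", "bode",
    "fev1_pp", "fev1_fvc", "prs_raw",
)
_DEF_CATEGORICAL = (
    "sex", "current_smoker", "frequent_exacerbations", "severe_exacerbation",
    "family_history",
)


def _is_normal(x: np.ndarray, alpha: float = 0.05, cap: int = 5000) -> bool:
    """Shapiro-Wilk normality screen, capped at a fixed-seed 5000 subsample."""
    x = x[np.isfinite(x)]
    if len(x) < 8 or np.ptp(x) == 0:
        return True
    if len(x) > cap:
        x = np.random.default_rng(0).choice(x, size=cap, replace=False)
    return stats.shapiro(x).pvalue >= alpha


def summarize_cohort(
    df: pd.DataFrame,
    by: str = "copd_status",
    continuous: Iterable[str] | None = None,
    categorical: Iterable[str] | None = None,
    groups: Iterable[str] = ("control", "case"),
) -> pd.DataFrame:
    """Produce a two-group descriptive table with comparison p-values.

    Continuous variables are reported mean (SD) when both groups pass a
    Shapiro-Wilk screen (alpha=0.05, capped at a 5000 subsample), otherwise
    median (IQR); the group comparison is a Welch t-test or Wilcoxon
    rank-sum accordingly. Binary/categorical variables get count (percent)
    and a chi-square test. P-values are for reporting only.
    """
    if by not in df.columns:
        raise SchemaError(f"grouping column {by!r} not present")
    continuous = [c for c in (continuous or _DEF_CONTINUOUS) if c in df.columns]
    categorical = [c for c in (categorical or _DEF_CATEGORICAL) if c in df.columns]
    grp = {g: df[df[by] == g] for g in groups}
    rows = []
    rows.append({
        "variable": "n", "kind": "n",
        **{f"{g}_n": len(d) for g, d in grp.items()},
    })
    for var in continuous:
        arrs = {g: pd.to_numeric(d[var], errors="coerce").dropna().to_numpy()
                for g, d in grp.items()}
        normal = all(_is_normal(a) for a in arrs.values() if len(a))
        usable = [a for a in arrs.values() if len(a) > 1]
        if len(usable) == 2:
            if normal:
                p = stats.ttest_ind(*usable, equal_var=False).pvalue
                test = "t"
            else:
                p = stats.mannwhitneyu(*usable, alternative="two-sided").pvalue
                test = "wilcoxon"
        else:
            p, test = np.nan, "none"
        row = {"variable": var, "kind": "mean_sd" if normal else "median_iqr",
               "test": test, "p_value": p}
        for g, a in arrs.items():
            row[f"{g}_n"] = len(a)
            if len(a):
                row[f"{g}_mean"] = float(np.mean(a))
                row[f"{g}_sd"] = float(np.std(a, ddof=1)) if len(a) > 1 else np.nan
                row[f"{g}_median"] = float(np.median(a))
                row[f"{g}_q1"], row[f"{g}_q3"] = (
                    float(q) for q in np.percentile(a, [25, 75])
                )
        rows.append(row)
    for var in categorical:
        row = {"variable": var, "kind": "count_percent"}
        counts = {}
        for g, d in grp.items():
            s = d[var]
            if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
                pos = s.isin(["yes", "male", True]).sum()
                n = s.notna().sum()
            else:
                pos = int((s == True).sum())  # noqa: E712  (nullable boolean)
                n = int(s.notna().sum())
            counts[g] = (int(pos), int(n))
            row[f"{g}_n"] = int(n)
            row[f"{g}_count"] = int(pos)
            row[f"{g}_percent"] = 100.0 * pos / n if n else np.nan
        tab = np.array([[c, n - c] for c, n in counts.values() if n > 0])
        if tab.shape == (2, 2) and tab.sum(axis=1).min() > 0 and tab.sum(axis=0).min() > 0:
            row["p_value"] = stats.chi2_contingency(tab, correction=False).pvalue
            row["test"] = "chi2"
        else:
            row["p_value"], row["test"] = np.nan, "none"
        rows.append(row)
    return pd.DataFrame(rows)
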