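"""Demographics ingestion/aggregation and cluster-level clinical models.

The patient demographics schema mirrors the published cohort table: age,
sex, lateralisation, onset and duration of epilepsy, febrile-convulsion
history, IQ, radiological gray-white blurring, surgery, histology and Engel
outcome. ``fixtures/table1.csv`` in the repository is a verbatim
transcription of that table and drives the exact-reproduction tests.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = ["SubjectRecord", "ingest_subjects", "records_to_frame",
           "aggregate_demographics", "cluster_clinical_model",
           "cluster_correlation", "blurring_subgroup_test", "table1_path"]


@dataclass
class SubjectRecord:
    """One participant's demographic/clinical row (missing values None)."""

    id: str
    group: str                            # 'patient' | 'control'
    age_years: float
    sex: str | None = None
    lesion_side: str = "none"             # 'left' | 'right' | 'none'
    onset_years: float | None = None
    duration_years: float | None = None
    febrile_convulsions: bool | None = None
    viq: float | None = None
    piq: float | None = None
    radiological_blurring: bool | None = None
    surgery: bool | None = None
    engel_class: str | None = None
    hippocampal_histology: str | None = None
    temporal_histology: str | None = None
    icv_mm3: float | None = None

    def check(self) -> list[str]:
        """Consistency warnings (never fatal): onset + duration ~ age."""
        w = []
        if self.group == "patient" and None not in (self.onset_years,
                                                    self.duration_years):
            if self.duration_years > self.age_years:
                w.append(f"{self.id}: duration exceeds age")
            elif abs(self.onset_years + self.duration_years
                     - self.age_years) > 0.2:
                w.append(f"{self.id}: onset + duration != age (>0.2 y)")
        if self.group == "control" and self.lesion_side != "none":
            w.append(f"{self.id}: control with a lesion side")
        return w


def table1_path() -> Path:
    """Locate the shipped verbatim demographics transcription."""
    here = Path(__file__).resolve()
    for base in [*here.parents, Path.cwd()]:
        p = base / "fixtures" / "table1.csv"
        if p.exists():
            return p
    raise FileNotFoundError("fixtures/table1.csv not found")


def _parse_value(x, kind):
    if pd.isna(x) or str(x).strip().lower() in ("", "n.a.", "na", "none"):
        return None
    s = str(x).strip()
    if kind == "float":
        return float(s)
    if kind == "bool":
        if s.lower() in ("y", "yes", "true", "1"):
            return True
        if s.lower() in ("n", "no", "false", "0"):
            return False
        raise ValueError(f"cannot parse boolean {s!r}")
    return s


def ingest_subjects(csv_path: str | Path) -> list[SubjectRecord]:
    """Typed records from a demographics CSV ('n.a.' -> missing, Y/N -> bool).

    Malformed rows raise with the offending row number; consistency issues
    (e.g. duration > age) are warnings attached by :meth:`SubjectRecord.check`.
    """
    df = pd.read_csv(csv_path, dtype=str)
    required = {"id", "age", "sex", "hemi", "onset", "duration", "fc"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"demographics CSV lacks columns: {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        try:
            side = _parse_value(row.get("hemi"), "str")
            side = {"L": "left", "R": "right", None: "none",
                    "left": "left", "right": "right"}[side]
            rec = SubjectRecord(
                id=str(row["id"]),
                group=_parse_value(row.get("group"), "str") or "patient",
                age_years=_parse_value(row["age"], "float"),
                sex=_parse_value(row["sex"], "str"),
                lesion_side=side,
                onset_years=_parse_value(row["onset"], "float"),
                duration_years=_parse_value(row["duration"], "float"),
                febrile_convulsions=_parse_value(row["fc"], "bool"),
                viq=_parse_value(row.get("viq"), "float"),
                piq=_parse_value(row.get("piq"), "float"),
                radiological_blurring=_parse_value(row.get("blurring"),
                                                   "bool"),
                surgery=_parse_value(row.get("surgery"), "bool"),
                engel_class=_parse_value(row.get("engel"), "str"),
                hippocampal_histology=_parse_value(
                    row.get("hippocampal_histology"), "str"),
                temporal_histology=_parse_value(
                    row.get("temporal_histology"), "str"),
                icv_mm3=_parse_value(row.get("icv_mm3"), "float"),
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"malformed demographics row {i + 2}: {exc}")
        records.append(rec)
    return records


def records_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


def _mean_sd(x: pd.Series) -> tuple[float | None, float | None]:
    x = pd.to_numeric(x, errors="coerce").dropna()
    if len(x) == 0:
        return None, None
    return float(x.mean()), (float(x.std(ddof=1)) if len(x) > 1 else None)


def aggregate_demographics(records: list[SubjectRecord]) -> dict:
    """Missing-aware group summary shaped like a cohort demographics table."""
    df = records_to_frame(records)
    pat = df[df.group == "patient"]
    out: dict = {"n_patients": int(len(pat)),
                 "n_controls": int((df.group == "control").sum())}
    for col, key in (("age_years", "age"), ("onset_years", "onset"),
                     ("duration_years", "duration"), ("viq", "viq"),
                     ("piq", "piq")):
        m, s = _mean_sd(pat[col])
        out[f"{key}_mean"], out[f"{key}_sd"] = m, s
    out["n_viq"] = int(pat.viq.notna().sum())
    out["sex_female"] = int((pat.sex == "F").sum())
    out["sex_male"] = int((pat.sex == "M").sum())
    for side, key in (("left", "ltle"), ("right", "rtle")):
        sub = pat[pat.lesion_side == side]
        out[f"{key}_n"] = int(len(sub))
        out[f"{key}_age_mean"], out[f"{key}_age_sd"] = _mean_sd(sub.age_years)
    for col, key in (("radiological_blurring", "blurring"),
                     ("febrile_convulsions", "fc"), ("surgery", "surgery")):
        k = int((pat[col] == True).sum())  # noqa: E712 - None-aware
        out[f"{key}_n"] = k
        out[f"{key}_pct"] = 100.0 * k / len(pat) if len(pat) else None
    operated = pat[pat.surgery == True]  # noqa: E712
    out["operated_n"] = int(len(operated))
    engel1 = operated.engel_class.fillna("").str.match(r"^I[ab]?$")
    out["engel_class1_n"] = int(engel1.sum())
    out["engel_class1_pct"] = (100.0 * engel1.sum() / len(operated)
                               if len(operated) else None)
    hist = pat.hippocampal_histology.fillna("")
    # \b stops 'Type I' from matching 'Type II'
    out["ilae_type1_n"] = int(hist.str.contains(r"type\s*I\b", case=False,
                                                regex=True).sum())
    return out


def cluster_clinical_model(table: pd.DataFrame, response: str,
                           predictors: tuple[str, ...] = (
                               "febrile_convulsions", "onset_years",
                               "duration_years")) -> dict:
    """OLS of a cluster feature mean on clinical predictors (patients only).

    Reports two-sided p by default and the one-sided p for the first
    predictor's hypothesised positive direction alongside, so no sidedness
    choice is silent.
    """
    df = table.dropna(subset=[response, *predictors]).copy()
    if len(df) < 5:
        raise ValueError("need >= 5 complete patients")
    X = np.column_stack([np.ones(len(df))]
                        + [pd.to_numeric(df[p].astype(float)) for p in
                           predictors])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear clinical predictors")
    fit = sm.OLS(df[response].to_numpy(float), X).fit()
    out = {"n": int(len(df)), "df": int(fit.df_resid), "terms": {}}
    for k, name in enumerate(predictors, start=1):
        t = float(fit.tvalues[k])
        out["terms"][name] = {
            "beta": float(fit.params[k]), "t": t,
            "p_two_sided": float(fit.pvalues[k]),
            "p_one_sided_pos": float(stats.t.sf(t, fit.df_resid)),
        }
    return out


def cluster_correlation(table: pd.DataFrame, x: str, y: str) -> dict:
    """Pearson correlation with the classical t-based p."""
    df = table.dropna(subset=[x, y])
    if len(df) < 3:
        raise ValueError("need >= 3 complete pairs")
    xv = df[x].to_numpy(float)
    yv = df[y].to_numpy(float)
    if xv.std() == 0 or yv.std() == 0:
        raise ValueError("zero variance in correlation input")
    r, p = stats.pearsonr(xv, yv)
    return {"r": float(r), "p": float(p), "n": int(len(df))}


def blurring_subgroup_test(table: pd.DataFrame, response: str,
                           grouping: str = "radiological_blurring",
                           pooled: bool = True) -> dict:
    """Two-sample t between patients with/without radiological blurring.

    Pooled-variance t by default (mirrors classical reporting); Welch
    available via ``pooled=False``.
    """
    df = table.dropna(subset=[response, grouping])
    g1 = df[df[grouping] == True][response].to_numpy(float)   # noqa: E712
    g0 = df[df[grouping] == False][response].to_numpy(float)  # noqa: E712
    if len(g1) < 2 or len(g0) < 2:
        raise ValueError("each subgroup needs >= 2 patients")
    t, p = stats.ttest_ind(g1, g0, equal_var=pooled)
    return {"t": float(t), "p": float(p), "n_yes": int(len(g1)),
            "n_no": int(len(g0)), "pooled": pooled}
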