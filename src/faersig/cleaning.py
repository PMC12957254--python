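"""Cleaning of linked FAERS-style data.

Covers case deduplication (latest report per caseid), drug-name
standardization via a synonym table, age normalization to years, outcome
and reporter classification, construction of the (report, drug, PT)
records that feed disproportionality analysis, and the descriptive
summaries (demographics, indications, concomitant medication).
"""

from __future__ import annotations

import logging
import math
import re
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from faersig.faers_io import QuarterDataset, date_precision

log = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_SYNONYMS",
    "TARGET_DRUGS",
    "dedup_cases",
    "apply_dedup",
    "standardize_drug",
    "normalize_age",
    "classify_outcomes",
    "build_records",
    "case_table",
    "demographic_summary",
    "indication_concomitant_summary",
]

#: Canonical synonym table: normalized keyword -> canonical drug label.
DEFAULT_SYNONYMS: dict[str, str] = {
    "guselkumab": "guselkumab",
    "tremfya": "guselkumab",
    "risankizumab": "risankizumab",
    "skyrizi": "risankizumab",
    "abbv 066": "risankizumab",
}

TARGET_DRUGS = ("risankizumab", "guselkumab")

#: Years per unit for each FAERS age code.
AGE_UNIT_FACTORS: dict[str, float] = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.14,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

AGE_RANGE = (0.0, 120.0)

SEX_MAP = {"F": "female", "M": "male"}

REPORTER_MAP = {
    "CN": "consumer",
    "PH": "pharmacist",
    "MD": "physician",
    "HP": "other-health-professional",
    "OT": "other-health-professional",
    "LW": "lawyer",
}

OUTCOME_MAP = {
    "DE": "death",
    "LT": "life-threatening",
    "HO": "hospitalization",
    "DS": "disability",
    "CA": "congenital-anomaly",
    "RI": "required-intervention",
    "OT": "other-serious",
}

#: Outcomes that make a report "serious" for the severe-outcome flag.
SERIOUS_OUTCOMES = frozenset({"death", "disability", "life-threatening", "hospitalization"})

AGE_BANDS = (("<18", 0.0, 18.0), ("18-65", 18.0, 65.0), (">=65", 65.0, math.inf))


# ---------------------------------------------------------------------------
# deduplication


def _numeric_key(series: pd.Series) -> pd.Series:
    return pd.to_numeric(series, errors="coerce").fillna(-1.0)


def dedup_cases(demo: pd.DataFrame) -> pd.DataFrame:
    """Keep one demo row per caseid: the one with the latest ``fda_dt``.

    Ties on ``fda_dt`` are broken by the largest ``primaryid`` (the most
    recent submission sequence).  Rows with a missing caseid are excluded
    and counted in the log.  The result is independent of input row order
    and the operation is idempotent.
    """
    if "caseid" not in demo.columns or "fda_dt" not in demo.columns:
        raise ValueError("demo table must have 'caseid' and 'fda_dt' columns")
    n_missing = int(demo["caseid"].isna().sum())
    if n_missing:
        log.info("dedup_cases: excluded %d rows with missing caseid", n_missing)
    kept = demo[demo["caseid"].notna()].copy()
    kept["_fda_key"] = _numeric_key(kept["fda_dt"])
    kept["_pid_key"] = _numeric_key(kept["primaryid"])
    kept = kept.sort_values(
        ["caseid", "_fda_key", "_pid_key"], kind="mergesort"
    ).drop_duplicates("caseid", keep="last")
    return kept.drop(columns=["_fda_key", "_pid_key"]).reset_index(drop=True)


def apply_dedup(dataset: QuarterDataset) -> QuarterDataset:
    """Deduplicate demo and restrict every other table to the survivors."""
    demo = dedup_cases(dataset.demo)
    survivors = demo["primaryid"].dropna()
    out = dataset.restrict(survivors)
    out.demo = demo.reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# drug-name standardization

_NON_ALNUM = re.compile(r"[^a-z0-9]+")


def _norm_text(text) -> str:
    if text is None or (isinstance(text, float) and pd.isna(text)) or text is pd.NA:
        return ""
    return _NON_ALNUM.sub(" ", str(text).lower()).strip()


def _norm_synonyms(synonyms: Mapping[str, str] | None) -> dict[str, str]:
    table = DEFAULT_SYNONYMS if synonyms is None else synonyms
    return {_norm_text(k): v for k, v in table.items()}


def standardize_drug(
    drugname, prod_ai=None, synonyms: Mapping[str, str] | None = None
) -> str | None:
    """Map a free-text drug name to its canonical label, or ``None``.

    Matching is case-insensitive, punctuation-insensitive substring search
    of each synonym in ``drugname`` and ``prod_ai`` — FAERS free-text names
    carry dose/form suffixes ("SKYRIZI 150MG/ML").
    """
    syn = _norm_synonyms(synonyms)
    hay = f"{_norm_text(drugname)} {_norm_text(prod_ai)}"
    for keyword, label in syn.items():
        if keyword and keyword in hay:
            return label
    return None


# ---------------------------------------------------------------------------
# demographics / outcomes


def normalize_age(age, age_cod) -> float:
    """Convert an (age, unit-code) pair to years; NaN when unusable.

    Unknown unit codes and converted values outside [0, 120] years are
    treated as missing.  A missing unit code is interpreted as years (the
    dominant FAERS convention).
    """
    value = pd.to_numeric(age, errors="coerce")
    if pd.isna(value):
        return float("nan")
    code = "" if age_cod is None or pd.isna(age_cod) else str(age_cod).strip().upper()
    if code == "":
        code = "YR"
    factor = AGE_UNIT_FACTORS.get(code)
    if factor is None:
        log.debug("normalize_age: unknown unit code %r", code)
        return float("nan")
    years = float(value) * factor
    if not (AGE_RANGE[0] <= years <= AGE_RANGE[1]):
        return float("nan")
    return years


def normalize_age_series(age: pd.Series, age_cod: pd.Series) -> pd.Series:
    """Vectorized :func:`normalize_age`."""
    values = pd.to_numeric(age, errors="coerce").astype(float)
    codes = age_cod.astype("string").str.strip().str.upper().fillna("YR").replace("", "YR")
    factors = codes.map(AGE_UNIT_FACTORS).astype(float)
    years = values * factors.to_numpy()
    years = years.where((years >= AGE_RANGE[0]) & (years <= AGE_RANGE[1]))
    return years


def classify_outcomes(outc_codes: Iterable) -> tuple[frozenset, bool]:
    """Map OUTC codes to outcome labels and flag severe reports.

    Severe = any of death, disability, life-threatening, hospitalization.
    Unknown codes are retained verbatim (lower-cased) and logged.
    """
    labels = set()
    for code in outc_codes:
        if code is None or pd.isna(code):
            continue
        c = str(code).strip().upper()
        if not c:
            continue
        mapped = OUTCOME_MAP.get(c)
        if mapped is None:
            log.debug("classify_outcomes: unknown outcome code %r retained", c)
            mapped = c.lower()
        labels.add(mapped)
    return frozenset(labels), bool(labels & SERIOUS_OUTCOMES)


def age_band(age_years: float) -> str:
    if age_years is None or (isinstance(age_years, float) and math.isnan(age_years)):
        return "unknown"
    for name, lo, hi in AGE_BANDS:
        if lo <= age_years < hi:
            return name
    return "unknown"


# ---------------------------------------------------------------------------
# record construction


def _drug_labels(drug: pd.DataFrame, synonyms: Mapping[str, str] | None) -> pd.DataFrame:
    """Attach canonical labels to the DRUG table.

    Target drugs get their canonical synonym-table label; every other drug
    keeps its normalized free-text name so it can serve as background.
    """
    out = drug.copy()
    pairs = out[["drugname", "prod_ai"]].fillna("")
    uniq = pairs.drop_duplicates()
    mapping = {}
    for dn, ai in uniq.itertuples(index=False):
        label = standardize_drug(dn, ai, synonyms)
        if label is None:
            label = _norm_text(dn) or _norm_text(ai) or "unknown-drug"
            is_target = False
        else:
            is_target = True
        mapping[(dn, ai)] = (label, is_target)
    keys = list(zip(pairs["drugname"], pairs["prod_ai"]))
    out["drug"] = [mapping[k][0] for k in keys]
    out["is_target"] = [mapping[k][1] for k in keys]
    return out


def build_records(
    dataset: QuarterDataset,
    synonyms: Mapping[str, str] | None = None,
    ps_only: bool = True,
) -> pd.DataFrame:
    """Build the (primaryid, drug, pt) counting records for signal analysis.

    One record per unique (primaryid, drug, pt) triple.  With ``ps_only``
    only primary-suspect (PS) drug rows enter — for target and background
    drugs alike, so the comparator is counted on the same footing.  PTs are
    normalized to lower case.  Reports whose drug rows have no reactions
    contribute nothing (logged).

    Returns a DataFrame with columns primaryid, drug, pt, role, is_target.
    """
    drug = _drug_labels(dataset.drug, synonyms)
    if ps_only:
        roles = drug["role_cod"].astype("string").str.strip().str.upper()
        drug = drug[roles == "PS"]
    reac = dataset.reac[["primaryid", "pt"]].copy()
    reac["pt"] = reac["pt"].astype("string").str.strip().str.lower()
    reac = reac[reac["pt"].notna() & (reac["pt"] != "")]
    merged = drug[["primaryid", "drug", "role_cod", "is_target"]].merge(
        reac, on="primaryid", how="inner"
    )
    n_no_reac = drug["primaryid"].nunique() - merged["primaryid"].nunique()
    if n_no_reac > 0:
        log.info("build_records: %d report(s) with a suspect drug but no reactions", n_no_reac)
    records = (
        merged.drop_duplicates(["primaryid", "drug", "pt"])
        .rename(columns={"role_cod": "role"})
        .reset_index(drop=True)
    )
    return records[["primaryid", "drug", "pt", "role", "is_target"]]


# ---------------------------------------------------------------------------
# case-level table and descriptive summaries


def case_table(dataset: QuarterDataset) -> pd.DataFrame:
    """One row per report with normalized demographics and outcomes.

    Expects a deduplicated dataset.  Columns: primaryid, caseid, fda_dt,
    event_dt, age_years, age_band, sex, reporter, country, outcomes
    (frozenset), serious, quarter.
    """
    demo = dataset.demo
    out = pd.DataFrame()
    out["primaryid"] = demo["primaryid"]
    out["caseid"] = demo["caseid"]
    out["fda_dt"] = demo["fda_dt"]
    out["event_dt"] = demo.get("event_dt", pd.Series(pd.NA, index=demo.index))
    out["age_years"] = normalize_age_series(demo["age"], demo["age_cod"])
    out["age_band"] = [age_band(a) for a in out["age_years"]]
    sex = demo["sex"].astype("string").str.strip().str.upper()
    out["sex"] = sex.map(SEX_MAP).fillna("unknown")
    occ = demo["occp_cod"].astype("string").str.strip().str.upper()
    out["reporter"] = occ.map(REPORTER_MAP).fillna("unknown")
    out["country"] = demo["reporter_country"].astype("string").str.strip().fillna("unknown")
    if "quarter" in demo.columns:
        out["quarter"] = demo["quarter"]
    by_report = dataset.outc.groupby("primaryid")["outc_cod"].apply(list)
    classified = {pid: classify_outcomes(codes) for pid, codes in by_report.items()}
    out["outcomes"] = [
        classified.get(pid, (frozenset(), False))[0] for pid in out["primaryid"]
    ]
    out["serious"] = [
        classified.get(pid, (frozenset(), False))[1] for pid in out["primaryid"]
    ]
    return out


def _report_drug_map(records: pd.DataFrame) -> pd.DataFrame:
    """(primaryid, drug) pairs for target drugs only, one row each."""
    target = records[records["is_target"]]
    return target[["primaryid", "drug"]].drop_duplicates()


def demographic_summary(
    cases: pd.DataFrame, records: pd.DataFrame, top_countries: int = 4
) -> pd.DataFrame:
    """Per-drug descriptive table: counts and percentages by category.

    Returns a long table with columns drug, section, level, count, pct.
    Percentages use the per-drug report total as denominator; an extra
    ``age-summary`` section carries the median (IQR) of known ages.
    """
    assoc = _report_drug_map(records).merge(cases, on="primaryid", how="left")
    rows: list[dict] = []
    for drug, grp in assoc.groupby("drug"):
        n_reports = len(grp)
        n_records = int((records["drug"] == drug).sum())
        rows.append(
            {"drug": drug, "section": "totals", "level": "reports", "count": n_reports, "pct": 100.0}
        )
        rows.append(
            {
                "drug": drug,
                "section": "totals",
                "level": "adverse-events",
                "count": n_records,
                "pct": float("nan"),
            }
        )

        def tally(section: str, series: pd.Series, order: list[str] | None = None):
            counts = series.value_counts()
            levels = order if order is not None else list(counts.index)
            for level in levels:
                cnt = int(counts.get(level, 0))
                rows.append(
                    {
                        "drug": drug,
                        "section": section,
                        "level": level,
                        "count": cnt,
                        "pct": 100.0 * cnt / n_reports if n_reports else float("nan"),
                    }
                )

        tally("sex", grp["sex"], ["female", "male", "unknown"])
        tally("age-band", grp["age_band"], ["<18", "18-65", ">=65", "unknown"])
        known_age = grp["age_years"].dropna()
        if len(known_age):
            med = float(known_age.median())
            q1, q3 = (float(known_age.quantile(q)) for q in (0.25, 0.75))
        else:
            med = q1 = q3 = float("nan")
        rows.append(
            {
                "drug": drug,
                "section": "age-summary",
                "level": f"median={med:.2f};q1={q1:.2f};q3={q3:.2f}",
                "count": int(len(known_age)),
                "pct": float("nan"),
            }
        )
        tally(
            "reporter",
            grp["reporter"],
            ["consumer", "pharmacist", "physician", "other-health-professional", "lawyer", "unknown"],
        )
        for outcome in ("death", "disability", "life-threatening", "hospitalization", "other-serious"):
            cnt = int(grp["outcomes"].apply(lambda s: outcome in s).sum())
            rows.append(
                {
                    "drug": drug,
                    "section": "outcome",
                    "level": outcome,
                    "count": cnt,
                    "pct": 100.0 * cnt / n_reports if n_reports else float("nan"),
                }
            )
        country_counts = grp["country"].value_counts()
        for level in list(country_counts.index[:top_countries]):
            cnt = int(country_counts[level])
            rows.append(
                {
                    "drug": drug,
                    "section": "country",
                    "level": level,
                    "count": cnt,
                    "pct": 100.0 * cnt / n_reports if n_reports else float("nan"),
                }
            )
        other = int(country_counts.iloc[top_countries:].sum())
        rows.append(
            {
                "drug": drug,
                "section": "country",
                "level": "other-countries",
                "count": other,
                "pct": 100.0 * other / n_reports if n_reports else float("nan"),
            }
        )
    return pd.DataFrame(rows, columns=["drug", "section", "level", "count", "pct"])


def indication_concomitant_summary(
    dataset: QuarterDataset,
    records: pd.DataFrame,
    synonyms: Mapping[str, str] | None = None,
    top_indications: int = 3,
    top_concomitant: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank target-drug indications and role-C concomitant medications.

    Both tables carry drug, rank, name, count, pct (of the drug's report
    total).  Ties in count are broken alphabetically and both are listed.
    """
    drug = _drug_labels(dataset.drug, synonyms)
    roles = drug["role_cod"].astype("string").str.strip().str.upper()
    target_ps = drug[drug["is_target"] & (roles == "PS")][["primaryid", "drug_seq", "drug"]]
    report_totals = _report_drug_map(records).groupby("drug")["primaryid"].nunique()

    indi = dataset.indi[["primaryid", "indi_drug_seq", "indi_pt"]].copy()
    indi["indi_pt"] = indi["indi_pt"].astype("string").str.strip().str.lower()
    ind = target_ps.merge(
        indi, left_on=["primaryid", "drug_seq"], right_on=["primaryid", "indi_drug_seq"]
    )
    ind = ind[ind["indi_pt"].notna()]
    ind_rows = []
    for dlabel, grp in ind.groupby("drug"):
        counts = (
            grp.drop_duplicates(["primaryid", "indi_pt"])["indi_pt"].value_counts().reset_index()
        )
        counts.columns = ["name", "count"]
        counts = counts.sort_values(["count", "name"], ascending=[False, True], kind="mergesort")
        total = int(report_totals.get(dlabel, 0))
        for rank, (_, r) in enumerate(counts.head(top_indications).iterrows(), 1):
            ind_rows.append(
                {
                    "drug": dlabel,
                    "rank": rank,
                    "name": r["name"],
                    "count": int(r["count"]),
                    "pct": 100.0 * r["count"] / total if total else float("nan"),
                }
            )
    indications = pd.DataFrame(ind_rows, columns=["drug", "rank", "name", "count", "pct"])

    conc = drug[(roles == "C") & ~drug["is_target"]][["primaryid", "drug"]].rename(
        columns={"drug": "name"}
    )
    conc_rows = []
    for dlabel in sorted(target_ps["drug"].unique()):
        pids = set(target_ps.loc[target_ps["drug"] == dlabel, "primaryid"])
        sub = conc[conc["primaryid"].isin(pids)].drop_duplicates(["primaryid", "name"])
        counts = sub["name"].value_counts().reset_index()
        counts.columns = ["name", "count"]
        counts = counts.sort_values(["count", "name"], ascending=[False, True], kind="mergesort")
        total = int(report_totals.get(dlabel, 0))
        for rank, (_, r) in enumerate(counts.head(top_concomitant).iterrows(), 1):
            conc_rows.append(
                {
                    "drug": dlabel,
                    "rank": rank,
                    "name": r["name"],
                    "count": int(r["count"]),
                    "pct": 100.0 * r["count"] / total if total else float("nan"),
                }
            )
    concomitants = pd.DataFrame(conc_rows, columns=["drug", "rank", "name", "count", "pct"])
    return indications, concomitants
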