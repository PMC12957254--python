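"""Disproportionality statistics for drug-event pairs.

For each (drug, event) pair a 2x2 table is formed against the all-other-
drugs background:

    a  drug & event        b  drug, other events
    c  others & event      d  others, other events

Three frequentist/Bayesian measures are computed:

* ROR = ad/bc with the Woolf 95% CI exp(ln ROR +/- 1.96*sqrt(1/a+1/b+1/c+1/d))
* PRR = [a/(a+b)] / [c/(c+d)] with the analogous CI using
  sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d)), plus the uncorrected Pearson chi2
* BCPNN information component IC = log2(a*N / ((a+b)(a+c))) with the
  shrinkage-style lower bound IC025 = IC - 3.3*a^(-1/2) - 2*a^(-3/2)

Zero cells yield flagged NaNs, never infinities; an optional Haldane 0.5
continuity correction is available but off by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "SignalStats",
    "SignalCriteria",
    "SignalFlags",
    "build_contingency",
    "disproportionality_stats",
    "stats_frame",
    "evaluate_signal",
    "complete_table",
    "screen_all_pts",
    "soc_profile",
    "soc_bubble_table",
    "format_signal_table",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 cells for one (drug, event) pair against the background."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"cell {name} is negative: {v}")
        if self.n_total <= 0:
            raise ValueError("contingency table is empty")

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def drug_total(self) -> int:
        return self.a + self.b

    @property
    def event_total(self) -> int:
        return self.a + self.c


@dataclass(frozen=True)
class SignalStats:
    """All disproportionality statistics for one pair (NaN = undefined)."""

    n: int
    ror: float
    ror_low: float
    ror_high: float
    prr: float
    prr_low: float
    prr_high: float
    chisq: float
    ic: float
    ic025: float
    table: ContingencyTable | None = None


@dataclass(frozen=True)
class SignalCriteria:
    """Positive-signal thresholds; defaults are the conventional ones.

    A pair is positive when N >= min_n and at least one of:
    ROR 95% CI lower bound > ror_ci_low; PRR >= prr_min and chi2 >=
    chisq_min; IC025 > ic025_min.  PRR/chi2 thresholds are inclusive.
    """

    min_n: int = 3
    ror_ci_low: float = 1.0
    prr_min: float = 2.0
    chisq_min: float = 4.0
    ic025_min: float = 0.0


@dataclass(frozen=True)
class SignalFlags:
    ror: bool
    prr: bool
    ic: bool
    positive: bool


def build_contingency(records: pd.DataFrame, drug: str, pt: str) -> ContingencyTable:
    """Count the 2x2 cells for (drug, pt) from cleaned records.

    ``records`` must hold one row per (primaryid, drug, pt); the background
    is every record of every other drug in the dataset.
    """
    pt = str(pt).strip().lower()
    is_drug = (records["drug"] == drug).to_numpy()
    is_pt = (records["pt"] == pt).to_numpy()
    a = int(np.sum(is_drug & is_pt))
    b = int(np.sum(is_drug & ~is_pt))
    c = int(np.sum(~is_drug & is_pt))
    d = int(np.sum(~is_drug & ~is_pt))
    if a + b == 0:
        log.warning("build_contingency: drug %r absent from records", drug)
    return ContingencyTable(a, b, c, d)


def stats_frame(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray, haldane: bool = False
) -> pd.DataFrame:
    """Vectorized disproportionality statistics for arrays of 2x2 cells."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    d = np.asarray(d, dtype=float)
    n_obs = a.copy()
    if haldane:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    n = a + b + c + d
    with np.errstate(divide="ignore", invalid="ignore"):
        ror = np.where((a > 0) & (b > 0) & (c > 0) & (d > 0), (a * d) / (b * c), np.nan)
        se_ror = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        ror_low = np.exp(np.log(ror) - Z95 * se_ror)
        ror_high = np.exp(np.log(ror) + Z95 * se_ror)

        prr = np.where(
            (a + b > 0) & (c > 0), (a / (a + b)) / (c / (c + d)), np.nan
        )
        se_prr = np.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
        prr_ok = (a > 0) & (c > 0)
        prr_low = np.where(prr_ok, np.exp(np.log(prr) - Z95 * se_prr), np.nan)
        prr_high = np.where(prr_ok, np.exp(np.log(prr) + Z95 * se_prr), np.nan)

        margins_ok = (a + b > 0) & (c + d > 0) & (a + c > 0) & (b + d > 0)
        chisq = np.where(
            margins_ok,
            n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d)),
            np.nan,
        )

        ic = np.where(
            (a > 0) & (a + b > 0) & (a + c > 0),
            np.log2(a * n / ((a + b) * (a + c))),
            np.nan,
        )
        ic025 = ic - 3.3 * a ** (-0.5) - 2.0 * a ** (-1.5)
    return pd.DataFrame(
        {
            "n": n_obs.astype(int),
            "ror": ror,
            "ror_low": ror_low,
            "ror_high": ror_high,
            "prr": prr,
            "prr_low": prr_low,
            "prr_high": prr_high,
            "chisq": chisq,
            "ic": ic,
            "ic025": ic025,
        }
    )


def disproportionality_stats(table: ContingencyTable, haldane: bool = False) -> SignalStats:
    """Compute ROR, PRR, chi2 and IC for one 2x2 table."""
    row = stats_frame(
        np.array([table.a]), np.array([table.b]), np.array([table.c]), np.array([table.d]),
        haldane=haldane,
    ).iloc[0]
    return SignalStats(
        n=int(table.a),
        ror=float(row["ror"]),
        ror_low=float(row["ror_low"]),
        ror_high=float(row["ror_high"]),
        prr=float(row["prr"]),
        prr_low=float(row["prr_low"]),
        prr_high=float(row["prr_high"]),
        chisq=float(row["chisq"]),
        ic=float(row["ic"]),
        ic025=float(row["ic025"]),
        table=table,
    )


def _rule_flags(
    n, ror_low, prr, chisq, ic025, criteria: SignalCriteria
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    n = np.asarray(n)
    enough = n >= criteria.min_n
    with np.errstate(invalid="ignore"):
        f_ror = enough & (np.nan_to_num(ror_low, nan=-np.inf) > criteria.ror_ci_low)
        f_prr = (
            enough
            & (np.nan_to_num(prr, nan=-np.inf) >= criteria.prr_min)
            & (np.nan_to_num(chisq, nan=-np.inf) >= criteria.chisq_min)
        )
        f_ic = enough & (np.nan_to_num(ic025, nan=-np.inf) > criteria.ic025_min)
    positive = f_ror | f_prr | f_ic
    return f_ror, f_prr, f_ic, positive


def evaluate_signal(stats: SignalStats, criteria: SignalCriteria | None = None) -> SignalFlags:
    """Apply the per-algorithm signal rules; overall = any rule fires.

    The minimum record count gates every rule: with n < min_n nothing is
    positive no matter how extreme the statistics.
    """
    criteria = criteria or SignalCriteria()
    f_ror, f_prr, f_ic, positive = _rule_flags(
        np.array([stats.n]),
        np.array([stats.ror_low]),
        np.array([stats.prr]),
        np.array([stats.chisq]),
        np.array([stats.ic025]),
        criteria,
    )
    return SignalFlags(bool(f_ror[0]), bool(f_prr[0]), bool(f_ic[0]), bool(positive[0]))


def screen_all_pts(
    records: pd.DataFrame,
    drug: str,
    criteria: SignalCriteria | None = None,
    exclusions: Iterable[str] = (),
    haldane: bool = False,
) -> pd.DataFrame:
    """Screen every PT reported with ``drug`` against the background.

    Returns one row per non-excluded PT with n >= min_n, sorted by ROR
    descending (ties: larger n first, then PT ascending; NaN RORs last).
    Columns: pt, n, the statistics of :func:`stats_frame`, the three rule
    flags and the overall ``positive`` flag.
    """
    criteria = criteria or SignalCriteria()
    excl = {str(e).strip().lower() for e in exclusions}
    target = records[records["drug"] == drug]
    n_drug = len(target)
    n_total = len(records)
    a_counts = target["pt"].value_counts()
    all_counts = records["pt"].value_counts()
    pts = [p for p in a_counts.index if p not in excl and a_counts[p] >= criteria.min_n]
    if not pts:
        cols = [
            "pt", "n", "ror", "ror_low", "ror_high", "prr", "prr_low", "prr_high",
            "chisq", "ic", "ic025", "sig_ror", "sig_prr", "sig_ic", "positive",
        ]
        return pd.DataFrame(columns=cols)
    a = a_counts.loc[pts].to_numpy(dtype=float)
    tot = all_counts.loc[pts].to_numpy(dtype=float)
    b = n_drug - a
    c = tot - a
    d = n_total - n_drug - c
    out = stats_frame(a, b, c, d, haldane=haldane)
    out.insert(0, "pt", pts)
    f_ror, f_prr, f_ic, positive = _rule_flags(
        out["n"], out["ror_low"], out["prr"], out["chisq"], out["ic025"], criteria
    )
    out["sig_ror"] = f_ror
    out["sig_prr"] = f_prr
    out["sig_ic"] = f_ic
    out["positive"] = positive
    out["_ror_key"] = np.nan_to_num(out["ror"].to_numpy(), nan=-np.inf)
    out = out.sort_values(
        ["_ror_key", "n", "pt"], ascending=[False, False, True], kind="mergesort"
    ).drop(columns="_ror_key")
    return out.reset_index(drop=True)


def complete_table(
    a: int, drug_total: int, prr: float, chisq: float | None = None
) -> ContingencyTable:
    """Complete a 2x2 table from summary statistics.

    Given the pair count ``a``, the drug's record margin ``a + b`` and the
    PRR point estimate, the background event proportion is
    ``p = (a/drug_total)/PRR``.  If ``chisq`` is given, the background
    total ``M = c + d`` is solved numerically so the uncorrected Pearson
    statistic of the completed table matches it; otherwise a unit-odds
    background is not recoverable and a ValueError is raised.  Useful for
    internal-consistency checks against reference result rows.
    """
    from scipy.optimize import brentq

    if chisq is None:
        raise ValueError("need the chi-square statistic to pin down the background total")
    b = drug_total - a
    p = (a / drug_total) / prr

    def gap(m: float) -> float:
        c, d = p * m, (1 - p) * m
        n = a + b + c + d
        return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d)) - chisq

    m = brentq(gap, float(a + b), 1e12, xtol=1e-6)
    return ContingencyTable(a, b, int(round(p * m)), int(round((1 - p) * m)))


def soc_profile(
    records: pd.DataFrame,
    pt_to_soc: Mapping[str, str],
    drugs: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Distribution of a drug's records over system organ classes.

    PTs missing from the mapping fall into an ``unmapped`` bucket (logged).
    Returns drug, soc, count, proportion; proportions sum to 1 per drug.
    """
    mapping = {str(k).strip().lower(): str(v) for k, v in pt_to_soc.items()}
    if not mapping:
        log.warning("soc_profile: empty PT->SOC mapping; everything will be unmapped")
    if drugs is None:
        drugs = sorted(records.loc[records["is_target"], "drug"].unique())
    rows = []
    for drug in drugs:
        sub = records[records["drug"] == drug]
        socs = sub["pt"].map(lambda p: mapping.get(p, "unmapped"))
        n_unmapped = int((socs == "unmapped").sum())
        if n_unmapped:
            log.info("soc_profile: %d unmapped record(s) for %s", n_unmapped, drug)
        counts = socs.value_counts()
        total = counts.sum()
        for soc, cnt in counts.items():
            rows.append(
                {
                    "drug": drug,
                    "soc": soc,
                    "count": int(cnt),
                    "proportion": cnt / total if total else float("nan"),
                }
            )
    return pd.DataFrame(rows, columns=["drug", "soc", "count", "proportion"])


def soc_bubble_table(results: pd.DataFrame, pt_to_soc: Mapping[str, str]) -> pd.DataFrame:
    """Plot-ready per-PT table (log2 ROR, sqrt chi2, n, SOC) for bubble charts."""
    mapping = {str(k).strip().lower(): str(v) for k, v in pt_to_soc.items()}
    out = results[["pt", "n", "ror", "chisq"]].copy()
    out["soc"] = out["pt"].map(lambda p: mapping.get(p, "unmapped"))
    with np.errstate(invalid="ignore", divide="ignore"):
        out["log2_ror"] = np.log2(out["ror"].to_numpy(dtype=float))
        out["sqrt_chisq"] = np.sqrt(out["chisq"].to_numpy(dtype=float))
    return out[["pt", "soc", "n", "log2_ror", "sqrt_chisq"]]


def _fmt_ci(point: float, low: float, high: float) -> str:
    if np.isnan(point):
        return "NA"
    return f"{point:.2f} ({low:.2f}, {high:.2f})"


def format_signal_table(results: pd.DataFrame) -> pd.DataFrame:
    """Render a screen result in the conventional published column layout:
    PT | N | ROR (95% CI) | PRR (95% CI) | chisq | IC(IC025)."""
    rows = []
    for r in results.itertuples(index=False):
        rows.append(
            {
                "pt": r.pt,
                "n": int(r.n),
                "ror_ci": _fmt_ci(r.ror, r.ror_low, r.ror_high),
                "prr_ci": _fmt_ci(r.prr, r.prr_low, r.prr_high),
                "chisq": f"{r.chisq:.2f}" if not np.isnan(r.chisq) else "NA",
                "ic_ic025": (
                    f"{r.ic:.2f} ({r.ic025:.2f})" if not np.isnan(r.ic) else "NA"
                ),
            }
        )
    return pd.DataFrame(rows, columns=["pt", "n", "ror_ci", "prr_ci", "chisq", "ic_ic025"])
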