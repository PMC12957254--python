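"""Time-to-onset extraction and modelling.

Onset time is the number of days from the earliest therapy start date of
the target drug to the adverse-event date.  Reports with missing, partial
or inconsistent dates are excluded (with per-reason counts); same-day
onsets are recoded to 0.5 days so the Weibull likelihood stays finite.

The Weibull shape parameter classifies the failure pattern: a shape whose
95% CI lies entirely below 1 indicates a decreasing hazard (early
failure), a CI containing 1 a roughly constant hazard, a CI above 1 an
increasing hazard (wear-out).  Two-group comparisons use the log-rank test
and a univariate Cox model (Efron tie handling) via ``lifelines``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from faersig.cleaning import _drug_labels
from faersig.faers_io import QuarterDataset, parse_date

log = logging.getLogger(__name__)

__all__ = [
    "WeibullFit",
    "CoxResult",
    "extract_tto",
    "fit_weibull",
    "km_cumulative_incidence",
    "onset_interval_table",
    "logrank_test",
    "cox_hazard_ratio",
    "onset_summary_table",
]

#: Same-day onsets are recoded to this instead of being dropped.
MIN_ONSET_DAYS = 0.5

Z95 = 1.959963984540054


@dataclass(frozen=True)
class WeibullFit:
    """Two-parameter Weibull MLE (scale alpha in days, shape beta)."""

    alpha: float
    alpha_low: float
    alpha_high: float
    beta: float
    beta_low: float
    beta_high: float
    n: int
    loglik: float
    pattern: str  # early-failure | random-failure | wear-out

    @property
    def median(self) -> float:
        return self.alpha * np.log(2.0) ** (1.0 / self.beta)


@dataclass(frozen=True)
class CoxResult:
    hr: float
    hr_low: float
    hr_high: float
    coef: float
    se: float
    n: int


def extract_tto(
    dataset: QuarterDataset,
    drug: str,
    synonyms: Mapping[str, str] | None = None,
    ps_only: bool = True,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Extract onset times (days) for one target drug.

    Onset = event_dt minus the earliest full-precision start_dt among the
    drug's therapy rows (linked by primaryid + drug sequence).  Excluded,
    with per-reason counts: missing/partial event or start dates, negative
    onsets, and events dated after the report's fda_dt.

    Returns ``(DataFrame[primaryid, drug, tto_days], exclusion_counts)``.
    """
    labeled = _drug_labels(dataset.drug, synonyms)
    if ps_only:
        roles = labeled["role_cod"].astype("string").str.strip().str.upper()
        labeled = labeled[roles == "PS"]
    target = labeled[labeled["drug"] == drug][["primaryid", "drug_seq"]]

    ther = dataset.ther[["primaryid", "dsg_drug_seq", "start_dt"]]
    merged = target.merge(
        ther, left_on=["primaryid", "drug_seq"], right_on=["primaryid", "dsg_drug_seq"], how="left"
    )
    merged["start"] = merged["start_dt"].map(parse_date)
    starts = merged.dropna(subset=["start"]).groupby("primaryid")["start"].min()

    demo = dataset.demo.set_index("primaryid")
    excl = {
        "missing_or_partial_start": 0,
        "missing_or_partial_event": 0,
        "negative_onset": 0,
        "event_after_report_date": 0,
    }
    rows = []
    for pid in target["primaryid"].drop_duplicates():
        start = starts.get(pid)
        if start is None or pd.isna(start):
            excl["missing_or_partial_start"] += 1
            continue
        if pid not in demo.index:
            excl["missing_or_partial_event"] += 1
            continue
        demo_row = demo.loc[pid]
        if isinstance(demo_row, pd.DataFrame):  # duplicated primaryid: take first
            demo_row = demo_row.iloc[0]
        event = parse_date(demo_row.get("event_dt"))
        if event is None:
            excl["missing_or_partial_event"] += 1
            continue
        tto = (event - start).days
        if tto < 0:
            excl["negative_onset"] += 1
            continue
        fda = parse_date(demo_row.get("fda_dt"))
        if fda is not None and event > fda:
            excl["event_after_report_date"] += 1
            continue
        rows.append({"primaryid": pid, "drug": drug, "tto_days": float(tto) or MIN_ONSET_DAYS})
    for reason, count in excl.items():
        if count:
            log.info("extract_tto[%s]: excluded %d report(s): %s", drug, count, reason)
    return pd.DataFrame(rows, columns=["primaryid", "drug", "tto_days"]), excl


# ---------------------------------------------------------------------------
# Weibull


def _weibull_negloglik(log_alpha: float, log_beta: float, t: np.ndarray) -> float:
    alpha, beta = np.exp(log_alpha), np.exp(log_beta)
    n = t.size
    z = (t / alpha) ** beta
    return -(n * np.log(beta) - n * beta * np.log(alpha) + (beta - 1) * np.log(t).sum() - z.sum())


def _weibull_mle(t: np.ndarray) -> tuple[float, float]:
    """Exact MLE via the one-dimensional profile equation for the shape."""
    logt = np.log(t)
    mean_logt = logt.mean()

    def score(beta: float) -> float:
        tb = np.exp(beta * (logt - logt.max()))  # scaled to avoid overflow
        return (tb * logt).sum() / tb.sum() - 1.0 / beta - mean_logt

    lo, hi = 1e-3, 1.0
    while score(hi) < 0 and hi < 1e3:
        hi *= 2.0
    beta = optimize.brentq(score, lo, hi, xtol=1e-12, rtol=1e-14)
    alpha = ((t ** beta).mean()) ** (1.0 / beta)
    return alpha, beta


def fit_weibull(times: Sequence[float], conf: float = 0.95) -> WeibullFit:
    """Fit an uncensored two-parameter Weibull by maximum likelihood.

    CIs come from the observed information matrix on the log-parameter
    scale (delta method), so they are guaranteed positive.

    Raises ``ValueError`` for n < 10, non-positive times, or a degenerate
    (all-identical) sample where the shape estimate diverges.
    """
    t = np.asarray(times, dtype=float)
    if t.size < 10:
        raise ValueError(f"need at least 10 onset times, got {t.size}")
    if np.any(~np.isfinite(t)) or np.any(t <= 0):
        raise ValueError("onset times must be finite and positive")
    if np.ptp(t) == 0:
        raise ValueError("all onset times identical; shape parameter diverges")

    alpha, beta = _weibull_mle(t)
    la, lb = np.log(alpha), np.log(beta)

    # numerical Hessian of the negative log-likelihood at (log alpha, log beta)
    h = 1e-5
    def f(x, y):
        return _weibull_negloglik(x, y, t)
    hess = np.empty((2, 2))
    hess[0, 0] = (f(la + h, lb) - 2 * f(la, lb) + f(la - h, lb)) / h**2
    hess[1, 1] = (f(la, lb + h) - 2 * f(la, lb) + f(la, lb - h)) / h**2
    hess[0, 1] = hess[1, 0] = (
        f(la + h, lb + h) - f(la + h, lb - h) - f(la - h, lb + h) + f(la - h, lb - h)
    ) / (4 * h**2)
    cov = np.linalg.inv(hess)
    se_la, se_lb = np.sqrt(np.diag(cov))
    from scipy.stats import norm

    z = norm.ppf(0.5 + conf / 2.0)
    beta_low, beta_high = np.exp(lb - z * se_lb), np.exp(lb + z * se_lb)
    if beta_high < 1.0:
        pattern = "early-failure"
    elif beta_low > 1.0:
        pattern = "wear-out"
    else:
        pattern = "random-failure"
    return WeibullFit(
        alpha=float(alpha),
        alpha_low=float(np.exp(la - z * se_la)),
        alpha_high=float(np.exp(la + z * se_la)),
        beta=float(beta),
        beta_low=float(beta_low),
        beta_high=float(beta_high),
        n=int(t.size),
        loglik=float(-f(la, lb)),
        pattern=pattern,
    )


# ---------------------------------------------------------------------------
# Kaplan-Meier / intervals


def km_cumulative_incidence(times_by_group: Mapping[str, Sequence[float]]) -> dict[str, pd.DataFrame]:
    """Kaplan-Meier cumulative incidence per group (all times are events).

    With no censoring this equals the empirical CDF.  Returns, per group, a
    DataFrame with columns ``time`` and ``cum_incidence``.
    """
    out = {}
    for group, times in times_by_group.items():
        t = np.asarray(times, dtype=float)
        if t.size == 0:
            raise ValueError(f"group {group!r} has no onset times")
        kmf = KaplanMeierFitter()
        kmf.fit(t, event_observed=np.ones_like(t))
        surv = kmf.survival_function_
        out[group] = pd.DataFrame(
            {"time": surv.index.to_numpy(dtype=float), "cum_incidence": 1.0 - surv.iloc[:, 0].to_numpy()}
        )
    return out


def onset_interval_table(
    times_by_group: Mapping[str, Sequence[float]], bin_width: int = 30, n_bins: int = 12
) -> pd.DataFrame:
    """Histogram of onset times in fixed-width day intervals, plus overflow.

    Columns: drug, interval, count, pct (percent of the group's total).
    """
    rows = []
    edges = [i * bin_width for i in range(n_bins + 1)]
    for group, times in times_by_group.items():
        t = np.asarray(times, dtype=float)
        total = t.size
        for i in range(n_bins):
            lo, hi = edges[i], edges[i + 1]
            cnt = int(np.sum((t > lo) & (t <= hi))) if i else int(np.sum(t <= hi))
            label = f"{lo + 1 if i else 0}-{hi}"
            rows.append(
                {"drug": group, "interval": label, "count": cnt, "pct": 100.0 * cnt / total}
            )
        over = int(np.sum(t > edges[-1]))
        rows.append(
            {"drug": group, "interval": f">{edges[-1]}", "count": over, "pct": 100.0 * over / total}
        )
    return pd.DataFrame(rows, columns=["drug", "interval", "count", "pct"])


# ---------------------------------------------------------------------------
# two-group comparison


def logrank_test(times_a: Sequence[float], times_b: Sequence[float]) -> tuple[float, float]:
    """Log-rank test between two fully observed event-time samples."""
    a = np.asarray(times_a, dtype=float)
    b = np.asarray(times_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = _ll_logrank(a, b, event_observed_A=np.ones_like(a), event_observed_B=np.ones_like(b))
    return float(res.test_statistic), float(res.p_value)


def cox_hazard_ratio(
    times: Sequence[float],
    groups: Sequence[str],
    reference: str = "risankizumab",
    max_steps: int = 50,
) -> CoxResult:
    """Univariate Cox model comparing two onset-time groups.

    The single covariate is 1 for the non-reference group, so with
    ``reference='risankizumab'`` an HR above 1 means earlier onset for the
    other drug.  Ties are handled by Efron's method (lifelines default).
    """
    t = np.asarray(times, dtype=float)
    g = np.asarray(groups)
    levels = sorted(set(g))
    if len(levels) != 2:
        raise ValueError(f"expected exactly two groups, got {levels}")
    if reference not in levels:
        raise ValueError(f"reference {reference!r} not among groups {levels}")
    other = next(l for l in levels if l != reference)
    x = (g == other).astype(float)
    if (x == 1).sum() < 2 or (x == 0).sum() < 2:
        raise ValueError("need at least 2 events per group")
    df = pd.DataFrame({"duration": t, "event": 1, "x": x})
    cph = CoxPHFitter()
    cph.fit(
        df,
        duration_col="duration",
        event_col="event",
        fit_options={"max_steps": max_steps},
    )
    coef = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    return CoxResult(
        hr=float(np.exp(coef)),
        hr_low=float(np.exp(coef - Z95 * se)),
        hr_high=float(np.exp(coef + Z95 * se)),
        coef=coef,
        se=se,
        n=int(t.size),
    )


def onset_summary_table(fits: Mapping[str, WeibullFit], times_by_group: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Table-shaped summary: drug, n, median (IQR), alpha CI, beta CI, pattern."""
    rows = []
    for drug, fit in fits.items():
        t = np.asarray(times_by_group[drug], dtype=float)
        med = float(np.median(t))
        q1, q3 = (float(np.quantile(t, q)) for q in (0.25, 0.75))
        rows.append(
            {
                "drug": drug,
                "n": fit.n,
                "median_days": med,
                "iqr_low": q1,
                "iqr_high": q3,
                "alpha": fit.alpha,
                "alpha_low": fit.alpha_low,
                "alpha_high": fit.alpha_high,
                "beta": fit.beta,
                "beta_low": fit.beta_low,
                "beta_high": fit.beta_high,
                "pattern": fit.pattern,
            }
        )
    return pd.DataFrame(rows)
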