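"""Age-stratified signal screening with multiplicity adjustment.

Records are partitioned into the <18, 18-65 and >=65 strata by normalized
age; reports with unknown age enter no stratum.  Within each stratum the
screen is rerun against the stratum-matched background (other drugs in the
same stratum), a chi-square p-value (1 df) is attached, and p-values are
adjusted per stratum x drug (Benjamini-Hochberg by default, Bonferroni
optional).  The output includes volcano-plot coordinates
(log2 ROR, -log10 adjusted p).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from faersig.cleaning import AGE_BANDS
from faersig.disproportionality import SignalCriteria, screen_all_pts

log = logging.getLogger(__name__)

__all__ = ["STRATA", "stratify", "stratified_screen"]

STRATA = tuple(name for name, _, _ in AGE_BANDS)


def stratify(records: pd.DataFrame, cases: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Partition records by the report's age band; unknown ages drop out."""
    ages = cases.set_index("primaryid")["age_band"]
    banded = records.merge(
        ages.rename("age_band"), left_on="primaryid", right_index=True, how="left"
    )
    out = {}
    for name in STRATA:
        out[name] = banded[banded["age_band"] == name].drop(columns="age_band").reset_index(
            drop=True
        )
    return out


def stratified_screen(
    records: pd.DataFrame,
    cases: pd.DataFrame,
    drug: str,
    criteria: SignalCriteria | None = None,
    exclusions: Iterable[str] = (),
    method: str = "fdr_bh",
) -> pd.DataFrame:
    """Screen each age stratum separately and adjust p-values within it.

    Returns one row per (stratum, PT): stratum, pt, n, ror, ic, chisq,
    p_raw, p_adj, log2_ror, neg_log10_p_adj, positive.
    """
    criteria = criteria or SignalCriteria()
    frames = []
    for stratum, recs in stratify(records, cases).items():
        if not len(recs) or not (recs["drug"] == drug).any():
            log.warning("stratified_screen: no %s records in stratum %s", drug, stratum)
            continue
        res = screen_all_pts(recs, drug, criteria=criteria, exclusions=exclusions)
        if not len(res):
            continue
        chisq = res["chisq"].to_numpy(dtype=float)
        p_raw = np.where(np.isnan(chisq), 1.0, chi2.sf(chisq, df=1))
        p_adj = multipletests(p_raw, method=method)[1]
        out = res[["pt", "n", "ror", "ic", "chisq", "positive"]].copy()
        out.insert(0, "stratum", stratum)
        out["p_raw"] = p_raw
        out["p_adj"] = p_adj
        with np.errstate(divide="ignore", invalid="ignore"):
            out["log2_ror"] = np.log2(out["ror"].to_numpy(dtype=float))
            out["neg_log10_p_adj"] = -np.log10(np.maximum(p_adj, np.finfo(float).tiny))
        frames.append(out)
    cols = [
        "stratum", "pt", "n", "ror", "ic", "chisq", "positive",
        "p_raw", "p_adj", "log2_ror", "neg_log10_p_adj",
    ]
    if not frames:
        return pd.DataFrame(columns=cols)
    return pd.concat(frames, ignore_index=True)[cols]
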