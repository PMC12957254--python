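"""Synthetic FAERS-dialect data with known ground truth.

Each synthetic report belongs to an arm (one of the two target drugs or
the pooled background), carries one primary-suspect drug row, a set of
reaction PTs drawn independently per term, demographics with configurable
missingness, outcome codes, an optional indication row, optional role-C
concomitant drugs, and a therapy start date whose distance to the event
date follows a per-arm Weibull distribution.  Injected (drug, PT)
associations multiply the term's background probability by a configured
relative risk, so the generative truth of every disproportionality and
onset estimate is known exactly.

A fraction of cases is re-reported: the duplicate copies every table row
under a perturbed primaryid with a later fda_dt, which is exactly what the
deduplication stage must undo.

Fixed seed implies byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from faersig.faers_io import QuarterDataset, write_quarter

__all__ = ["SynthConfig", "default_pt_probs", "generate", "generate_files"]

TARGET_NAME_VARIANTS = {
    "risankizumab": ["SKYRIZI", "SKYRIZI 150MG/ML", "RISANKIZUMAB", "Skyrizi (risankizumab)", "ABBV-066"],
    "guselkumab": ["TREMFYA", "TREMFYA 100MG/ML", "GUSELKUMAB", "Tremfya (guselkumab)"],
}
TARGET_PROD_AI = {"risankizumab": "RISANKIZUMAB", "guselkumab": "GUSELKUMAB"}


def default_pt_probs(n_pts: int = 60, mean_pts_per_report: float = 2.1) -> dict[str, float]:
    """Zipf-like per-report occurrence probabilities summing to the target mean."""
    raw = 1.0 / (np.arange(n_pts) + 3.0)
    probs = raw * (mean_pts_per_report / raw.sum())
    probs = np.minimum(probs, 0.5)
    return {f"pt {i:04d}": float(p) for i, p in enumerate(probs)}


@dataclass
class SynthConfig:
    """Knobs for one synthetic dataset; every probability is per report."""

    n_reports: Mapping[str, int] = field(
        default_factory=lambda: {"risankizumab": 500, "guselkumab": 500, "background": 1500}
    )
    n_background_drugs: int = 50
    pt_probs: Mapping[str, float] | None = None
    n_pts: int = 60
    mean_pts_per_report: float = 2.1
    #: (drug, pt, relative risk) triples; RR multiplies the PT's background prob.
    injected_signals: Sequence[tuple[str, str, float]] = ()
    duplicate_rate: float = 0.05
    sex_probs: Mapping[str, float] = field(
        default_factory=lambda: {"F": 0.50, "M": 0.40, "": 0.10}
    )
    age_missing_rate: float = 0.30
    age_mean: float = 55.0
    age_sd: float = 14.0
    reporter_probs: Mapping[str, float] = field(
        default_factory=lambda: {"CN": 0.55, "PH": 0.20, "MD": 0.12, "OT": 0.05, "": 0.08}
    )
    country_probs: Mapping[str, float] = field(
        default_factory=lambda: {"US": 0.8, "CA": 0.07, "GB": 0.05, "DE": 0.04, "FR": 0.04}
    )
    outcome_probs: Mapping[str, float] = field(
        default_factory=lambda: {"HO": 0.20, "DE": 0.04, "LT": 0.02, "DS": 0.01, "OT": 0.35}
    )
    #: per-arm Weibull (scale days, shape) for time to onset
    onset: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "risankizumab": (241.61, 0.69),
            "guselkumab": (109.71, 0.44),
            "background": (180.0, 1.0),
        }
    )
    onset_missing_rate: float = 0.15
    concomitant_rate: float = 0.30
    indication_probs: Mapping[str, float] = field(
        default_factory=lambda: {"psoriasis": 0.5, "crohn's disease": 0.2, "psoriatic arthritis": 0.1}
    )
    start_date: str = "20230101"
    window_days: int = 360
    seed: int = 0

    def resolved_pt_probs(self) -> dict[str, float]:
        if self.pt_probs is not None:
            return {str(k): float(v) for k, v in self.pt_probs.items()}
        return default_pt_probs(self.n_pts, self.mean_pts_per_report)

    def validate(self) -> None:
        probs = self.resolved_pt_probs()
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"pt probability out of range for {name!r}: {p}")
        for drug, pt, rr in self.injected_signals:
            if rr < 0:
                raise ValueError(f"negative relative risk for ({drug}, {pt})")
            if pt not in probs:
                raise ValueError(f"injected pt {pt!r} not in the vocabulary")
            if rr * probs[pt] > 1.0:
                raise ValueError(
                    f"RR x background exceeds 1 for ({drug}, {pt}): "
                    f"{rr} x {probs[pt]:.4f}; renormalize the vocabulary"
                )
        if not 0.0 <= self.duplicate_rate < 1.0:
            raise ValueError("duplicate_rate must be in [0, 1)")


def _choice(rng: np.random.Generator, probs: Mapping[str, float]) -> str:
    keys = list(probs)
    p = np.asarray([probs[k] for k in keys], dtype=float)
    p = p / p.sum()
    return keys[int(rng.choice(len(keys), p=p))]


def _fmt(ts: pd.Timestamp) -> str:
    return ts.strftime("%Y%m%d")


def _quarter_label(ts: pd.Timestamp) -> str:
    return f"{ts.year}q{(ts.month - 1) // 3 + 1}"


def generate(config: SynthConfig) -> tuple[list[QuarterDataset], dict[str, pd.DataFrame]]:
    """Generate quarters plus a ground-truth manifest.

    Returns ``(quarters, manifest)`` where the manifest holds the injected
    relative risks (``signals``), per-arm onset Weibull parameters
    (``onset``), intended duplicate groups (``duplicates``), arm sizes
    (``arms``) and the PT vocabulary (``pt_probs``).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    pt_probs = config.resolved_pt_probs()
    pt_names = list(pt_probs)
    base_p = np.asarray([pt_probs[p] for p in pt_names], dtype=float)
    rr_by_drug: dict[str, np.ndarray] = {}
    for drug, pt, rr in config.injected_signals:
        vec = rr_by_drug.setdefault(drug, np.ones_like(base_p))
        vec[pt_names.index(pt)] = rr

    bg_drugs = [f"BGDRUG-{i:03d}" for i in range(config.n_background_drugs)]
    start0 = pd.Timestamp(f"{config.start_date[:4]}-{config.start_date[4:6]}-{config.start_date[6:8]}")

    demo_rows, drug_rows, reac_rows, outc_rows, rpsr_rows, ther_rows, indi_rows = (
        [] for _ in range(7)
    )
    caseid_counter = 100000

    def emit_report(arm: str, caseid: int, primaryid_version: int, fda_shift_days: int):
        pid = str(caseid * 10 + primaryid_version)
        cid = str(caseid)
        scale, shape = config.onset[arm]
        start = start0 + pd.Timedelta(days=int(rng.integers(0, config.window_days)))
        tto = float(scale * rng.weibull(shape))
        event = start + pd.Timedelta(days=int(round(tto)))
        fda = event + pd.Timedelta(days=int(rng.integers(3, 60)) + fda_shift_days)

        onset_mode = "full"
        if rng.random() < config.onset_missing_rate:
            onset_mode = ["no_ther", "partial_start", "missing_event"][int(rng.integers(0, 3))]

        sex = _choice(rng, config.sex_probs)
        if rng.random() < config.age_missing_rate:
            age, age_cod = "", ""
        else:
            age_val = float(np.clip(rng.normal(config.age_mean, config.age_sd), 1.0, 100.0))
            if rng.random() < 0.05:
                age, age_cod = f"{age_val * 12:.0f}", "MON"
            else:
                age, age_cod = f"{age_val:.0f}", "YR"
        demo_rows.append(
            {
                "primaryid": pid,
                "caseid": cid,
                "fda_dt": _fmt(fda),
                "event_dt": "" if onset_mode == "missing_event" else _fmt(event),
                "age": age,
                "age_cod": age_cod,
                "sex": sex,
                "occp_cod": _choice(rng, config.reporter_probs),
                "reporter_country": _choice(rng, config.country_probs),
            }
        )

        if arm in TARGET_NAME_VARIANTS:
            dn = TARGET_NAME_VARIANTS[arm][int(rng.integers(0, len(TARGET_NAME_VARIANTS[arm])))]
            ai = TARGET_PROD_AI[arm]
        else:
            dn = bg_drugs[int(rng.integers(0, len(bg_drugs)))]
            ai = dn
        drug_rows.append(
            {"primaryid": pid, "drug_seq": "1", "role_cod": "PS", "drugname": dn, "prod_ai": ai}
        )
        next_seq = 2
        if rng.random() < config.concomitant_rate:
            for _ in range(int(rng.integers(1, 3))):
                cdn = bg_drugs[int(rng.integers(0, len(bg_drugs)))]
                drug_rows.append(
                    {
                        "primaryid": pid,
                        "drug_seq": str(next_seq),
                        "role_cod": "C",
                        "drugname": cdn,
                        "prod_ai": cdn,
                    }
                )
                next_seq += 1

        p_vec = base_p * rr_by_drug.get(arm, 1.0) if arm in rr_by_drug else base_p
        hits = np.nonzero(rng.random(len(pt_names)) < p_vec)[0]
        if hits.size == 0:
            hits = np.array([int(rng.choice(len(pt_names), p=p_vec / p_vec.sum()))])
        for idx in hits:
            reac_rows.append({"primaryid": pid, "pt": pt_names[idx]})

        for code, p in config.outcome_probs.items():
            if rng.random() < p:
                outc_rows.append({"primaryid": pid, "outc_cod": code})
        rpsr_rows.append({"primaryid": pid, "rpsr_cod": "EXP" if rng.random() < 0.5 else "CSM"})

        if onset_mode == "partial_start":
            start_str = _fmt(start)[:6]  # month precision only
        elif onset_mode == "no_ther":
            start_str = None
        else:
            start_str = _fmt(start)
        if start_str is not None:
            ther_rows.append({"primaryid": pid, "dsg_drug_seq": "1", "start_dt": start_str})

        total_ind = sum(config.indication_probs.values())
        if rng.random() < total_ind:
            indi_rows.append(
                {
                    "primaryid": pid,
                    "indi_drug_seq": "1",
                    "indi_pt": _choice(rng, config.indication_probs),
                }
            )
        return pid

    all_lists = [demo_rows, drug_rows, reac_rows, outc_rows, rpsr_rows, ther_rows, indi_rows]
    duplicates = []
    for arm in sorted(config.n_reports):
        for _ in range(int(config.n_reports[arm])):
            caseid_counter += 1
            caseid = caseid_counter
            marks = [len(lst) for lst in all_lists]
            pid1 = emit_report(arm, caseid, 1, fda_shift_days=0)
            if rng.random() < config.duplicate_rate:
                # a re-report is a copy of the original under a new primaryid
                # with a later fda_dt; everything else is identical
                pid2 = str(caseid * 10 + 2)
                shift = int(rng.integers(60, 240))
                for lst, mark in zip(all_lists, marks):
                    for row in list(lst[mark:]):
                        copy = dict(row, primaryid=pid2)
                        if "fda_dt" in copy:
                            old = pd.Timestamp(
                                f"{copy['fda_dt'][:4]}-{copy['fda_dt'][4:6]}-{copy['fda_dt'][6:8]}"
                            )
                            copy["fda_dt"] = _fmt(old + pd.Timedelta(days=shift))
                        lst.append(copy)
                duplicates.append(
                    {"caseid": str(caseid), "primaryid_original": pid1, "primaryid_duplicate": pid2}
                )

    tables = {
        "demo": pd.DataFrame(demo_rows),
        "drug": pd.DataFrame(drug_rows),
        "reac": pd.DataFrame(reac_rows),
        "outc": pd.DataFrame(outc_rows),
        "rpsr": pd.DataFrame(rpsr_rows),
        "ther": pd.DataFrame(ther_rows),
        "indi": pd.DataFrame(indi_rows),
    }
    for name, tab in tables.items():
        tables[name] = tab.astype("string").replace("", pd.NA)

    # split by the quarter of fda_dt
    quarter_of = {
        pid: _quarter_label(pd.Timestamp(f"{d[:4]}-{d[4:6]}-{d[6:8]}"))
        for pid, d in zip(tables["demo"]["primaryid"], tables["demo"]["fda_dt"])
    }
    labels = sorted(set(quarter_of.values()))
    quarters = []
    for label in labels:
        pids = {p for p, q in quarter_of.items() if q == label}
        qtabs = {
            name: tab[tab["primaryid"].isin(pids)].reset_index(drop=True)
            for name, tab in tables.items()
        }
        quarters.append(QuarterDataset(**qtabs, quarter=label))

    manifest = {
        "signals": pd.DataFrame(
            [{"drug": d, "pt": p, "rr": r} for d, p, r in config.injected_signals],
            columns=["drug", "pt", "rr"],
        ),
        "onset": pd.DataFrame(
            [{"drug": d, "scale": s, "shape": b} for d, (s, b) in sorted(config.onset.items())]
        ),
        "duplicates": pd.DataFrame(
            duplicates, columns=["caseid", "primaryid_original", "primaryid_duplicate"]
        ),
        "arms": pd.DataFrame(
            [{"drug": d, "n_reports": int(n)} for d, n in sorted(config.n_reports.items())]
        ),
        "pt_probs": pd.DataFrame(
            [{"pt": p, "prob": v} for p, v in pt_probs.items()]
        ),
    }
    return quarters, manifest


def generate_files(config: SynthConfig, outdir: str | Path) -> list[Path]:
    """Write the generated quarters (one subdirectory each) plus manifest CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    quarters, manifest = generate(config)
    written = []
    for q in quarters:
        qdir = outdir / q.quarter
        written.extend(write_quarter(q, qdir))
    mdir = outdir / "manifest"
    mdir.mkdir(exist_ok=True)
    for name, tab in manifest.items():
        path = mdir / f"{name}.csv"
        tab.to_csv(path, index=False)
        written.append(path)
    return written
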