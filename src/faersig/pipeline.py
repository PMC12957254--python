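"""Staged orchestration: simulate -> clean -> screen -> onset -> subgroup -> report.

Every stage is a pure function of (inputs, config, seed); rerunning the
same configuration reproduces identical outputs.  ``run`` computes all
result tables first and only then writes them, so a stage failure (raised
as :class:`StageError` naming the stage) leaves no partial outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from faersig import cleaning, disproportionality as dpa, onset as onset_mod, subgroup as subgroup_mod
from faersig.cleaning import TARGET_DRUGS
from faersig.disproportionality import SignalCriteria
from faersig.faers_io import QuarterDataset, link_quarters, read_quarter
from faersig.synthgen import SynthConfig, generate

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "StageError", "load_quarters", "run"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class PipelineConfig:
    input_dir: str | Path | None = None
    synth: SynthConfig | None = None
    out_dir: str | Path = "faersig_out"
    drugs: Sequence[str] = TARGET_DRUGS
    synonyms: Mapping[str, str] | None = None
    criteria: SignalCriteria = field(default_factory=SignalCriteria)
    exclusions: Sequence[str] = ()
    pt_to_soc: Mapping[str, str] | None = None
    adjust_method: str = "fdr_bh"
    seed: int = 0


def load_quarters(input_dir: str | Path) -> list[QuarterDataset]:
    """Read quarters from a directory of quarter subdirectories.

    A directory that itself holds the seven ``*.txt`` tables is treated as
    a single quarter.
    """
    input_dir = Path(input_dir)
    subdirs = sorted(
        d for d in input_dir.iterdir() if d.is_dir() and any(d.glob("DEMO*.txt"))
    )
    if not subdirs:
        return [read_quarter(input_dir, quarter=input_dir.name)]
    return [read_quarter(d, quarter=d.name) for d in subdirs]


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise StageError(name, exc) from exc
        return inner
    return wrap


def run(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Execute the whole pipeline and write CSV artifacts to ``out_dir``.

    Returns the result tables keyed by artifact name.  The run log
    (exclusion counts and decision parameters) is written as
    ``run_log.json``.
    """
    run_log: dict = {"seed": config.seed, "criteria": vars(config.criteria).copy()}
    results: dict[str, pd.DataFrame] = {}

    @_stage("ingest")
    def ingest() -> QuarterDataset:
        if config.input_dir is not None:
            quarters = load_quarters(config.input_dir)
        elif config.synth is not None:
            quarters, _ = generate(config.synth)
        else:
            raise ValueError("either input_dir or a synthetic config is required")
        run_log["n_quarters"] = len(quarters)
        return link_quarters(quarters)

    linked = ingest()

    @_stage("clean")
    def clean(linked: QuarterDataset):
        n_before = len(linked.demo)
        deduped = cleaning.apply_dedup(linked)
        run_log["reports_before_dedup"] = n_before
        run_log["reports_after_dedup"] = len(deduped.demo)
        cases = cleaning.case_table(deduped)
        records = cleaning.build_records(deduped, config.synonyms, ps_only=True)
        run_log["n_records_total"] = len(records)
        run_log["n_records_target"] = int(records["is_target"].sum())
        return deduped, cases, records

    deduped, cases, records = clean(linked)

    @_stage("report")
    def descriptive():
        results["demographics"] = cleaning.demographic_summary(cases, records)
        ind, conc = cleaning.indication_concomitant_summary(deduped, records, config.synonyms)
        results["indications"] = ind
        results["concomitants"] = conc

    descriptive()

    @_stage("screen")
    def screen():
        for drug in config.drugs:
            res = dpa.screen_all_pts(
                records, drug, criteria=config.criteria, exclusions=config.exclusions
            )
            results[f"signals_{drug}"] = res
            results[f"signals_{drug}_formatted"] = dpa.format_signal_table(res)
            run_log[f"n_signals_{drug}"] = int(res["positive"].sum()) if len(res) else 0
            if config.pt_to_soc:
                results[f"soc_bubble_{drug}"] = dpa.soc_bubble_table(res, config.pt_to_soc)
        if config.pt_to_soc:
            results["soc_profile"] = dpa.soc_profile(
                records, config.pt_to_soc, drugs=list(config.drugs)
            )

    screen()

    @_stage("onset")
    def onset_stage():
        frames, fits, times = [], {}, {}
        for drug in config.drugs:
            tto, excl = onset_mod.extract_tto(deduped, drug, config.synonyms)
            run_log[f"tto_exclusions_{drug}"] = excl
            frames.append(tto)
            if len(tto) >= 10:
                times[drug] = tto["tto_days"].to_numpy()
                fits[drug] = onset_mod.fit_weibull(times[drug])
            else:
                log.warning("onset: only %d usable onsets for %s; skipping fit", len(tto), drug)
        results["onset_records"] = (
            pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
        )
        if fits:
            results["onset_summary"] = onset_mod.onset_summary_table(fits, times)
            results["onset_intervals"] = onset_mod.onset_interval_table(times)
        if len(times) == 2:
            (da, ta), (db, tb) = times.items()
            stat, p = onset_mod.logrank_test(ta, tb)
            all_t = list(ta) + list(tb)
            groups = [da] * len(ta) + [db] * len(tb)
            ref = config.drugs[0]
            cox = onset_mod.cox_hazard_ratio(all_t, groups, reference=ref)
            results["cox"] = pd.DataFrame(
                [
                    {
                        "reference": ref,
                        "hr": cox.hr,
                        "hr_low": cox.hr_low,
                        "hr_high": cox.hr_high,
                        "logrank_stat": stat,
                        "logrank_p": p,
                        "n": cox.n,
                    }
                ]
            )

    onset_stage()

    @_stage("subgroup")
    def subgroup_stage():
        for drug in config.drugs:
            results[f"volcano_{drug}"] = subgroup_mod.stratified_screen(
                records,
                cases,
                drug,
                criteria=config.criteria,
                exclusions=config.exclusions,
                method=config.adjust_method,
            )

    subgroup_stage()

    @_stage("write")
    def write():
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, tab in results.items():
            tab.to_csv(out / f"{name}.csv", index=False)
        (out / "run_log.json").write_text(json.dumps(run_log, indent=2, sort_keys=True))

    write()
    return results
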