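"""Hand-construction helpers for small FAERS-dialect fixtures."""

from __future__ import annotations

import pandas as pd

from faersig.faers_io import SCHEMAS, QuarterDataset


def table(rows: list[dict], name: str) -> pd.DataFrame:
    cols = list(SCHEMAS[name])
    df = pd.DataFrame(rows, columns=cols)
    return df.astype("string")


def dataset(
    demo=(), drug=(), reac=(), outc=(), rpsr=(), ther=(), indi=(), quarter=None
) -> QuarterDataset:
    return QuarterDataset(
        demo=table(list(demo), "demo"),
        drug=table(list(drug), "drug"),
        reac=table(list(reac), "reac"),
        outc=table(list(outc), "outc"),
        rpsr=table(list(rpsr), "rpsr"),
        ther=table(list(ther), "ther"),
        indi=table(list(indi), "indi"),
        quarter=quarter,
    )


def demo_row(primaryid, caseid=None, fda_dt="20240101", **kw) -> dict:
    row = {
        "primaryid": str(primaryid),
        "caseid": str(caseid if caseid is not None else primaryid),
        "fda_dt": fda_dt,
        "reporter_country": "US",
    }
    row.update({k: (None if v is None else str(v)) for k, v in kw.items()})
    return row


def drug_row(primaryid, drug_seq="1", role_cod="PS", drugname="SKYRIZI", prod_ai=None) -> dict:
    return {
        "primaryid": str(primaryid),
        "drug_seq": str(drug_seq),
        "role_cod": role_cod,
        "drugname": drugname,
        "prod_ai": prod_ai,
    }


def reac_row(primaryid, pt) -> dict:
    return {"primaryid": str(primaryid), "pt": pt}


def ther_row(primaryid, dsg_drug_seq="1", start_dt="20230101") -> dict:
    return {"primaryid": str(primaryid), "dsg_drug_seq": str(dsg_drug_seq), "start_dt": start_dt}


def records_frame(triples, target_drugs=("risankizumab", "guselkumab")) -> pd.DataFrame:
    """Build a cleaned records table from (primaryid, drug, pt) triples."""
    rows = [
        {
            "primaryid": str(pid),
            "drug": drug,
            "pt": pt,
            "role": "PS",
            "is_target": drug in target_drugs,
        }
        for pid, drug, pt in triples
    ]
    return pd.DataFrame(rows, columns=["primaryid", "drug", "pt", "role", "is_target"])
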