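"""I/O for the FAERS quarterly ASCII dialect.

The only supported dialect is the one the FDA distributes: "$"-delimited
fields, no quoting, newline-terminated rows, a header line first, UTF-8
decoded with replacement on errors.  Seven tables make up one quarter:
DEMO, DRUG, REAC, OUTC, RPSR, THER, INDI.

All fields are kept as strings on read (missing = empty field = NA) so that
``write_quarter`` followed by ``read_table`` is a bit-exact identity; type
coercion is the cleaning stage's job.  Dates are 8-digit ``YYYYMMDD``
strings when complete; partial dates (``YYYYMM`` / ``YYYY``) are retained
verbatim and classified by :func:`date_precision` rather than imputed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "TABLE_NAMES",
    "SCHEMAS",
    "SchemaError",
    "QuarterDataset",
    "read_table",
    "read_quarter",
    "write_quarter",
    "link_quarters",
    "date_precision",
    "parse_date",
]

TABLE_NAMES = ("demo", "drug", "reac", "outc", "rpsr", "ther", "indi")

#: Mandatory columns per table.  Files may carry extra columns; they are kept.
SCHEMAS: dict[str, tuple[str, ...]] = {
    "demo": (
        "primaryid",
        "caseid",
        "fda_dt",
        "event_dt",
        "age",
        "age_cod",
        "sex",
        "occp_cod",
        "reporter_country",
    ),
    "drug": ("primaryid", "drug_seq", "role_cod", "drugname", "prod_ai"),
    "reac": ("primaryid", "pt"),
    "outc": ("primaryid", "outc_cod"),
    "rpsr": ("primaryid", "rpsr_cod"),
    "ther": ("primaryid", "dsg_drug_seq", "start_dt"),
    "indi": ("primaryid", "indi_drug_seq", "indi_pt"),
}

DELIMITER = "$"


class SchemaError(ValueError):
    """A table file does not conform to the expected FAERS schema."""


def _empty_table(schema_name: str) -> pd.DataFrame:
    cols = SCHEMAS[schema_name]
    return pd.DataFrame({c: pd.Series(dtype="string") for c in cols})


def read_table(path: str | os.PathLike, schema_name: str) -> pd.DataFrame:
    """Read one "$"-delimited FAERS table.

    Parameters
    ----------
    path
        Path to the ASCII file; first line must be the "$"-delimited header.
    schema_name
        One of :data:`TABLE_NAMES`.

    Returns
    -------
    pandas.DataFrame
        All columns with ``string`` dtype, lower-cased names, empty fields
        as NA.  Row count equals the file's line count minus the header.

    Raises
    ------
    SchemaError
        If a mandatory column of ``schema_name`` is absent from the header.
    """
    if schema_name not in SCHEMAS:
        raise ValueError(f"unknown schema {schema_name!r}; expected one of {TABLE_NAMES}")
    raw = Path(path).read_bytes().decode("utf-8", errors="replace")
    # split strictly on newlines: unlike str.splitlines this must not treat
    # other control characters (\x1c-\x1e,  , ...) as row boundaries
    lines = [l.rstrip("\r") for l in raw.split("\n")]
    if lines and lines[-1] == "":
        lines.pop()
    if not lines or (len(lines) == 1 and lines[0].strip() == ""):
        return _empty_table(schema_name)
    header = [h.strip().lower() for h in lines[0].split(DELIMITER)]
    missing = [c for c in SCHEMAS[schema_name] if c not in header]
    if missing:
        raise SchemaError(
            f"{Path(path).name}: missing mandatory column(s) {missing} for table {schema_name!r}"
        )
    ncol = len(header)
    rows = []
    for line in lines[1:]:
        parts = line.split(DELIMITER)
        if len(parts) < ncol:
            parts = parts + [""] * (ncol - len(parts))
        elif len(parts) > ncol:
            parts = parts[:ncol]
        rows.append(parts)
    df = pd.DataFrame(rows, columns=header, dtype="string")
    df = df.replace("", pd.NA)
    return df


def write_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write one table in the FAERS dialect (header + "$"-delimited rows)."""
    cols = list(df.columns)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(DELIMITER.join(cols) + "\n")
        if len(df):
            body = df.astype("string").fillna("")
            for row in body.itertuples(index=False):
                fh.write(DELIMITER.join(str(v) for v in row) + "\n")


@dataclass
class QuarterDataset:
    """The seven linked FAERS tables for one quarter (or a linked span)."""

    demo: pd.DataFrame = field(default_factory=lambda: _empty_table("demo"))
    drug: pd.DataFrame = field(default_factory=lambda: _empty_table("drug"))
    reac: pd.DataFrame = field(default_factory=lambda: _empty_table("reac"))
    outc: pd.DataFrame = field(default_factory=lambda: _empty_table("outc"))
    rpsr: pd.DataFrame = field(default_factory=lambda: _empty_table("rpsr"))
    ther: pd.DataFrame = field(default_factory=lambda: _empty_table("ther"))
    indi: pd.DataFrame = field(default_factory=lambda: _empty_table("indi"))
    quarter: str | None = None

    def tables(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in TABLE_NAMES}

    def validate(self) -> None:
        """Raise if a non-demo row references a primaryid absent from demo."""
        known = set(self.demo["primaryid"].dropna())
        for name in TABLE_NAMES:
            if name == "demo":
                continue
            tab = getattr(self, name)
            if not len(tab):
                continue
            orphans = set(tab["primaryid"].dropna()) - known
            if orphans:
                some = sorted(orphans)[:5]
                raise ValueError(
                    f"table {name!r} references primaryid(s) missing from demo, e.g. {some}"
                )

    def restrict(self, primaryids: Iterable[str]) -> "QuarterDataset":
        """Return a copy with every table restricted to the given primaryids."""
        keep = set(primaryids)
        out = {}
        for name, tab in self.tables().items():
            out[name] = tab[tab["primaryid"].isin(keep)].reset_index(drop=True)
        return QuarterDataset(**out, quarter=self.quarter)


def write_quarter(dataset: QuarterDataset, directory: str | os.PathLike) -> list[Path]:
    """Write all seven tables as ``DEMO.txt`` ... ``INDI.txt`` under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name, tab in dataset.tables().items():
        path = directory / f"{name.upper()}.txt"
        write_table(tab, path)
        written.append(path)
    return written


def _find_table_file(directory: Path, name: str) -> Path:
    # accept DEMO.txt as well as quarterly names like DEMO23Q1.txt, any case
    cands = [
        p
        for p in directory.iterdir()
        if p.is_file() and p.suffix.lower() == ".txt" and p.stem.lower().startswith(name)
    ]
    if not cands:
        raise FileNotFoundError(f"no {name.upper()}*.txt file in {directory}")
    if len(cands) > 1:
        raise SchemaError(f"ambiguous {name.upper()} files in {directory}: {sorted(cands)}")
    return cands[0]


def read_quarter(directory: str | os.PathLike, quarter: str | None = None) -> QuarterDataset:
    """Read the seven tables of one quarter from ``directory``."""
    directory = Path(directory)
    tabs = {name: read_table(_find_table_file(directory, name), name) for name in TABLE_NAMES}
    return QuarterDataset(**tabs, quarter=quarter)


def link_quarters(quarters: Sequence[QuarterDataset]) -> QuarterDataset:
    """Concatenate quarters into one dataset, tagging rows with their quarter.

    Duplicate primaryids across quarters are retained: deduplication is the
    cleaning stage's responsibility, not I/O's.
    """
    if not quarters:
        raise ValueError("link_quarters requires at least one quarter")
    merged: dict[str, pd.DataFrame] = {}
    for name in TABLE_NAMES:
        frames = []
        ref_cols: list[str] | None = None
        for i, q in enumerate(quarters):
            tab = getattr(q, name)
            cols = [c for c in tab.columns if c != "quarter"]
            if ref_cols is None:
                ref_cols = cols
            elif cols != ref_cols:
                raise SchemaError(
                    f"conflicting schemas for table {name!r}: {ref_cols} vs {cols}"
                )
            tagged = tab.copy()
            tagged["quarter"] = pd.Series(
                [q.quarter if q.quarter is not None else f"q{i}"] * len(tab), dtype="string"
            )
            frames.append(tagged)
        merged[name] = pd.concat(frames, ignore_index=True) if frames else _empty_table(name)
    return QuarterDataset(**merged, quarter=None)


def date_precision(value) -> str:
    """Classify a raw FAERS date string.

    Returns one of ``"day"`` (valid YYYYMMDD), ``"month"`` (YYYYMM),
    ``"year"`` (YYYY), ``"missing"``, or ``"invalid"``.  Nothing is coerced:
    a value like ``"2024Q1"`` stays in the data and is reported invalid.
    """
    if value is None or (isinstance(value, float) and pd.isna(value)) or value is pd.NA:
        return "missing"
    s = str(value).strip()
    if not s:
        return "missing"
    if not s.isdigit():
        return "invalid"
    if len(s) == 4:
        return "year" if 1900 <= int(s) <= 2100 else "invalid"
    if len(s) == 6:
        y, m = int(s[:4]), int(s[4:6])
        return "month" if 1900 <= y <= 2100 and 1 <= m <= 12 else "invalid"
    if len(s) == 8:
        try:
            pd.Timestamp(f"{s[:4]}-{s[4:6]}-{s[6:8]}")
        except ValueError:
            return "invalid"
        return "day"
    return "invalid"


def parse_date(value) -> pd.Timestamp | None:
    """Parse a full-precision (YYYYMMDD) FAERS date; anything else -> None."""
    if date_precision(value) != "day":
        return None
    s = str(value).strip()
    return pd.Timestamp(f"{s[:4]}-{s[4:6]}-{s[6:8]}")
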