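"""Reading, validating, writing and summarizing cohort tables.

A cohort table is one row per participant with canonical column names:
``prs_pt_<t>`` for the PRS at threshold t, ``ctq_total`` and the five CTQ
subscales, ``cape_total``, ``cannabis_case``/``tobacco_case`` (0/1),
``neuroticism``, ``age``, ``gender`` (1 = male), ``pc1..pc3``.  Missing
cells are NaN in memory and a configurable token (default: empty field)
on disk.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import CTQ_SUBSCALES

__all__ = [
    "ColumnMap",
    "read_cohort",
    "write_cohort",
    "summarize",
    "dichotomize_cannabis",
    "validate_cohort",
]

BINARY_COLUMNS = ("gender", "cannabis_case", "tobacco_case")
NON_NUMERIC = ("id",)


@dataclass
class ColumnMap:
    """Mapping from canonical variable names to source column labels."""

    columns: dict[str, str] = field(default_factory=dict)  # canonical -> source
    missing_token: str = ""
    delimiter: str = ","

    def __post_init__(self) -> None:
        sources = list(self.columns.values())
        if len(set(sources)) != len(sources):
            raise ValueError("two canonical names map to the same source column")

    @classmethod
    def from_file(cls, path: str | Path) -> "ColumnMap":
        text = Path(path).read_text()
        if str(path).endswith((".yml", ".yaml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)


def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Type-coerce and check domain constraints; raise on violations."""
    out = table.copy()
    for col in out.columns:
        if col in NON_NUMERIC:
            continue
        coerced = pd.to_numeric(out[col], errors="coerce")
        bad = coerced.isna() & out[col].notna() & (out[col].astype(str).str.strip() != "")
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"non-numeric value {out.loc[row, col]!r} in column {col!r}, row {row}"
            )
        out[col] = coerced
    for col in BINARY_COLUMNS:
        if col not in out.columns:
            continue
        vals = out[col].dropna()
        ok = vals.isin([0, 1])
        if not ok.all():
            row = int(ok.idxmin())
            raise ValueError(
                f"column {col!r} must be 0/1; found {out.loc[row, col]!r} in row {row}"
            )
    return out


def read_cohort(path: str | Path, colmap: ColumnMap | None = None) -> pd.DataFrame:
    """Read a delimited cohort file and return a validated table."""
    colmap = colmap or ColumnMap()
    na = [colmap.missing_token] if colmap.missing_token else ["", "NA"]
    table = pd.read_csv(
        path, sep=colmap.delimiter, na_values=na, keep_default_na=False
    )
    if colmap.columns:
        rename = {src: canon for canon, src in colmap.columns.items()}
        missing = [src for src in rename if src not in table.columns]
        if missing:
            raise ValueError(f"input file lacks required columns: {missing}")
        table = table.rename(columns=rename)
    return validate_cohort(table)


def write_cohort(
    table: pd.DataFrame, path: str | Path, colmap: ColumnMap | None = None
) -> None:
    colmap = colmap or ColumnMap()
    table.to_csv(
        path, sep=colmap.delimiter, index=False, na_rep=colmap.missing_token
    )


# ----------------------------------------------------------------------
# cannabis dichotomization (>= 10 lifetime uses is a case)
# ----------------------------------------------------------------------

_UCC_CATEGORIES = {
    "never": 0, "1": 0, "2": 0, "5-9": 0, "5–9": 0,
    "≥10": 1, ">=10": 1, "10+": 1, "≥10 times": 1,
}
_ESPAD_CATEGORIES = {
    "never": 0, "1-2": 0, "3-5": 0, "6-9": 0,
    "10-19": 1, "≥20": 1, ">=20": 1, "20+": 1,
    "1–2": 0, "3–5": 0, "6–9": 0, "10–19": 1,
}


def dichotomize_cannabis(raw_category, scale: str = "ucc"):
    """Map an ordered lifetime-use category to case (1) / control (0).

    A case is >= 10 lifetime uses on either cohort's scale; missing
    inputs stay missing.
    """
    if raw_category is None or (isinstance(raw_category, float) and np.isnan(raw_category)):
        return np.nan
    table = {"ucc": _UCC_CATEGORIES, "espad": _ESPAD_CATEGORIES}.get(scale)
    if table is None:
        raise ValueError(f"unknown scale {scale!r} (expected 'ucc' or 'espad')")
    key = str(raw_category).strip().lower()
    if key not in table:
        raise ValueError(f"unknown {scale.upper()} category {raw_category!r}")
    return table[key]


# ----------------------------------------------------------------------
# descriptive summary (cohort-characteristics table analogue)
# ----------------------------------------------------------------------

def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Per-variable descriptives over observed cells only.

    Continuous variables get mean and SD; binary ones count and percent.
    ``missing_fraction`` is the observed share of missing cells, i.e.
    1 - n_observed/n_rows.
    """
    if len(table) == 0:
        raise ValueError("cannot summarize an empty table")
    n_rows = len(table)
    rows = []
    for col in table.columns:
        if col in NON_NUMERIC:
            continue
        vals = table[col].dropna()
        entry = {
            "variable": col,
            "n_observed": len(vals),
            "missing_fraction": 1.0 - len(vals) / n_rows,
        }
        if col in BINARY_COLUMNS:
            count = int(vals.sum())
            entry["count"] = count
            entry["percent"] = 100.0 * count / len(vals) if len(vals) else np.nan
        else:
            entry["mean"] = float(vals.mean()) if len(vals) else np.nan
            entry["sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
        rows.append(entry)
    return pd.DataFrame(rows).set_index("variable")


def ctq_total_consistency(table: pd.DataFrame) -> bool:
    """True when ctq_total equals the subscale sum wherever all observed."""
    subs = [s for s in CTQ_SUBSCALES if s in table.columns]
    if len(subs) < 5 or "ctq_total" not in table.columns:
        return True
    complete = table[subs + ["ctq_total"]].dropna()
    return bool(
        np.allclose(complete[subs].sum(axis=1), complete["ctq_total"], atol=1e-6)
    )
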