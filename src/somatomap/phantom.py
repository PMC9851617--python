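"""Phantom-sensation questionnaire scoring and cohort demographics.

The questionnaire table codes frequency on a 0-5 scale (0 = no sensation or
pain, 5 = all the time) while the chronic-score formula uses the opposite
coding (1 = all the time, 5 = once or less per month); the recode is
``formula_code = 6 - table_code``. The chronic score divides the worst
intensity (0-100) by the recoded frequency and is reported to one decimal
(half away from zero). A bundled worked-example table ships with the
package (``load_reference_table``).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .exceptions import InvalidCodeError, SchemaError

REQUIRED_COLUMNS = ("Participants", "Age", "Gender")
SCORE_COLUMNS = ("PLS intensity", "PLS frequency", "PLP intensity", "PLP frequency")


def _round_half_up(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def recode_frequency(table_code: float) -> Optional[float]:
    """Map the table frequency coding onto the formula coding (6 - code).

    Fractional codes are allowed (e.g. 2.5 -> 3.5). Code 0 (never) has no
    formula counterpart and returns None.
    """
    if not 0 <= table_code <= 5:
        raise InvalidCodeError(f"frequency code {table_code} outside [0, 5]")
    if table_code == 0:
        return None
    return 6.0 - float(table_code)


@dataclass
class ChronicScore:
    intensity: float
    table_code: float
    value: float
    degenerate: bool


def chronic_score(intensity: float, table_code: float) -> ChronicScore:
    """Worst intensity divided by the recoded frequency, to one decimal.

    Defined as 0 (degenerate) when the frequency code is 0 or the intensity
    is 0: a sensation that never occurs contributes no chronic burden.
    """
    if not 0 <= intensity <= 100:
        raise InvalidCodeError(f"intensity {intensity} outside [0, 100]")
    formula = recode_frequency(table_code)
    if formula is None or intensity == 0:
        return ChronicScore(intensity, table_code, 0.0, degenerate=True)
    return ChronicScore(intensity, table_code,
                        _round_half_up(intensity / formula, 1), degenerate=False)


def classify_plp(chronic_plp: float) -> str:
    """Split participants by current chronic phantom-limb pain."""
    return "with_plp" if chronic_plp > 0 else "without_plp"


def _to_number(cell) -> float:
    """Parse a numeric table cell, tolerating footnote asterisks and blanks."""
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return np.nan
    s = str(cell).strip().rstrip("*")
    return float(s) if s else np.nan


def load_reference_table() -> pd.DataFrame:
    """Packaged worked-example demographics/questionnaire table.

    Adds a ``Group`` column derived from the participant-id prefix (AA =
    amputee-like, CA = one-hander-like) and numeric ``*_num`` columns for
    the score fields with footnote markers stripped.
    """
    with resources.files("somatomap.data").joinpath("table1.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    df["Group"] = np.where(df["Participants"].str.startswith("AA"),
                           "amputees", "one_handers")
    df["Age"] = df["Age"].astype(float)
    for col in df.columns:
        if "intensity" in col or "frequency" in col or col.startswith("Chronic"):
            df[f"{col}_num"] = df[col].map(_to_number)
    return df


def score_table(df: pd.DataFrame) -> pd.DataFrame:
    """Recompute chronic PLS/PLP scores and the PLP class for every row.

    Adds ``Computed chronic PLS/PLP``, ``PLP class`` and, where a printed
    chronic column exists, a ``Chronic PLS/PLP mismatch`` flag marking cells
    the recode-and-divide rule cannot reproduce (never forced to match).
    """
    out = df.copy()
    for prefix in ("PLS", "PLP"):
        icol, fcol = f"{prefix} intensity", f"{prefix} frequency"
        if icol not in out.columns or fcol not in out.columns:
            raise SchemaError(f"missing {icol!r}/{fcol!r} columns")
        computed = []
        for _, row in out.iterrows():
            i, f = _to_number(row[icol]), _to_number(row[fcol])
            computed.append(np.nan if np.isnan(i) or np.isnan(f)
                            else chronic_score(i, f).value)
        out[f"Computed chronic {prefix}"] = computed
        printed_col = f"Chronic {prefix}"
        if printed_col in out.columns:
            printed = out[printed_col].map(_to_number)
            out[f"{printed_col} mismatch"] = [
                (not np.isnan(p)) and (not np.isnan(c)) and abs(p - c) > 0.05
                for p, c in zip(printed, computed)]
    out["PLP class"] = [classify_plp(v) if not np.isnan(v) else ""
                        for v in out["Computed chronic PLP"]]
    return out


def cohort_demographics(df: pd.DataFrame) -> pd.DataFrame:
    """Per-group mean age (2 dp), SE of age (sample SD / sqrt(n), 2 dp) and
    counts by gender and affected side. SE is missing for single-row groups."""
    for col in ("Group", "Age"):
        if col not in df.columns:
            raise SchemaError(f"missing column {col!r}")
    rows = []
    for group, sub in df.groupby("Group", sort=False):
        ages = sub["Age"].astype(float).to_numpy()
        n = len(ages)
        se = (np.nan if n < 2
              else _round_half_up(float(np.std(ages, ddof=1) / np.sqrt(n)), 2))
        row = {
            "group": group,
            "n": n,
            "mean_age": _round_half_up(float(np.mean(ages)), 2),
            "se_age": se,
            "n_female": int((sub["Gender"].astype(str).str.upper() == "F").sum()),
        }
        if "Affected limb" in sub.columns:
            side = sub["Affected limb"].astype(str).str.strip().str.upper()
            row["n_affected_right"] = int((side == "R").sum())
            row["n_affected_left"] = int((side == "L").sum())
        rows.append(row)
    return pd.DataFrame(rows)
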