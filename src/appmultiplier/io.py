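"""Reading survey flat files and writing result artifacts.

Accepts two survey layouts:

* the generator's layout — explicit ``recruiter_id`` links; and
* the conventional RDS coupon layout — each row carries the coupon the
  respondent redeemed plus the coupons issued to them; links are derived by
  matching redeemed coupons to issuers.

Reading applies the survey's two-step eligibility logic: a respondent is
eligible if they report sex with another man in the last year, or — having
answered no — do not prefer sex with women only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import to_json
from .errors import EstimationError
from .rds import RdsSample

__all__ = ["read_rds_survey", "read_rds_coupon_survey", "ReadReport", "write_json"]

MAX_BAD_ROW_FRAC = 0.05


@dataclass
class ReadReport:
    n_rows: int = 0
    n_kept: int = 0
    n_ineligible: int = 0
    row_errors: list[str] = field(default_factory=list)


def _apply_eligibility(df: pd.DataFrame, report: ReadReport) -> pd.DataFrame:
    if "sex_12m" not in df.columns:
        return df
    sex = df["sex_12m"]
    if "prefer_women_only" in df.columns:
        pref = df["prefer_women_only"]
    else:
        pref = pd.Series(0, index=df.index)
    eligible = (sex == 1) | ((sex == 0) & (pref == 0))
    report.n_ineligible = int((~eligible).sum())
    return df[eligible]


def _validate_rows(df: pd.DataFrame, report: ReadReport) -> pd.DataFrame:
    bad = pd.Series(False, index=df.index)
    if (df["degree"] < 1).any():
        for i in df.index[df["degree"] < 1]:
            report.row_errors.append(f"line {i + 2}: degree < 1")
        bad |= df["degree"] < 1
    if "age" in df.columns:
        underage = df["age"] < 18
        for i in df.index[underage]:
            report.row_errors.append(f"line {i + 2}: age < 18")
        bad |= underage
    ids = set(df.loc[~bad, "id"])
    nonseed = df["recruiter_id"].notna()
    unknown = nonseed & ~df["recruiter_id"].isin(ids)
    for i in df.index[unknown]:
        report.row_errors.append(f"line {i + 2}: unknown recruiter {df.loc[i, 'recruiter_id']!r}")
    bad |= unknown
    if bad.sum() > MAX_BAD_ROW_FRAC * max(len(df), 1):
        raise EstimationError(
            f"{int(bad.sum())} of {len(df)} rows invalid (> {MAX_BAD_ROW_FRAC:.0%}): "
            + "; ".join(report.row_errors[:10])
        )
    if bad.any():
        warnings.warn(f"dropping {int(bad.sum())} invalid rows", stacklevel=3)
    return df[~bad]


def _derive_structure(df: pd.DataFrame) -> pd.DataFrame:
    """Fill in order and seed_id when a flat file lacks them."""
    df = df.copy()
    if "order" not in df.columns:
        df["order"] = np.arange(len(df))
    df = df.sort_values("order", kind="stable").reset_index(drop=True)
    if "seed_id" not in df.columns:
        seed_of: dict = {}
        recruiter = dict(zip(df["id"], df["recruiter_id"]))
        for rid in df["id"]:
            path = [rid]
            cur = rid
            while pd.notna(recruiter.get(cur)) and recruiter[cur] not in seed_of:
                cur = recruiter[cur]
                if cur in path:
                    raise EstimationError(f"cycle in recruiter links at {cur!r}")
                path.append(cur)
            root = seed_of.get(recruiter.get(cur), cur) if pd.notna(recruiter.get(cur)) else cur
            for p in path:
                seed_of[p] = root
        df["seed_id"] = [seed_of[r] for r in df["id"]]
    return df


def read_rds_survey(
    path: str | Path,
    eligibility_filter: bool = True,
    validate: bool = True,
) -> tuple[RdsSample, ReadReport]:
    """Read an RDS survey flat file with explicit recruiter links."""
    df = pd.read_csv(path)
    required = {"id", "recruiter_id", "degree"}
    missing = required - set(df.columns)
    if missing:
        raise EstimationError(f"survey file missing columns: {sorted(missing)}")
    report = ReadReport(n_rows=len(df))
    if eligibility_filter:
        df = _apply_eligibility(df, report)
    df = _validate_rows(df.reset_index(drop=True), report)
    df = _derive_structure(df)
    report.n_kept = len(df)
    return RdsSample(df, validate=validate), report


def read_rds_coupon_survey(
    path: str | Path,
    eligibility_filter: bool = True,
    coupon_col: str = "coupon",
    issued_prefix: str = "coupon_",
) -> tuple[RdsSample, ReadReport]:
    """Read a coupon-format RDS flat file, deriving recruiter links.

    Each row has the coupon the respondent redeemed (``coupon``, empty for
    seeds) and the coupons issued to them (``coupon_1``..).  A coupon issued
    by two different respondents is ambiguous and rejected.
    """
    df = pd.read_csv(path)
    issued_cols = [c for c in df.columns if c.startswith(issued_prefix)]
    if coupon_col not in df.columns or not issued_cols:
        raise EstimationError("coupon-format file needs a redeemed-coupon column and issued-coupon columns")
    issuer: dict[str, object] = {}
    for _, row in df.iterrows():
        for c in issued_cols:
            code = row[c]
            if pd.isna(code) or code == "":
                continue
            if code in issuer:
                raise EstimationError(f"coupon {code!r} issued by more than one respondent")
            issuer[code] = row["id"]
    recruiter = [
        issuer.get(c) if pd.notna(c) and c != "" else None for c in df[coupon_col]
    ]
    out = df.drop(columns=[coupon_col] + issued_cols).assign(recruiter_id=recruiter)
    report = ReadReport(n_rows=len(out))
    if eligibility_filter:
        out = _apply_eligibility(out, report)
    out = _validate_rows(out.reset_index(drop=True), report)
    out = _derive_structure(out)
    report.n_kept = len(out)
    return RdsSample(out), report


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(to_json(obj) + "\n")
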