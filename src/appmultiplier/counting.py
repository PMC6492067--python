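"""Counting active app users — the multiplier's numerator.

Three approaches, mirroring field practice for enumerating users of a
social app over a fixed window:

1. ``dedup_count`` — enumerate sighted profiles over the window and keep
   only those seen repeatedly with enough spacing to exclude short-term
   visitors;
2. ``capture_recapture_count`` — match active profiles at two time points
   and apply Lincoln–Petersen or Chapman two-sample abundance estimation;
3. ``provider_count`` — an aggregate, unduplicated figure obtained directly
   from the app operator.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import round_half_up
from .errors import EstimationError

__all__ = [
    "ActivityLog",
    "CountResult",
    "dedup_count",
    "capture_recapture_count",
    "provider_count",
]


@dataclass
class ActivityLog:
    """Timestamped profile sightings over an observation window.

    ``sightings`` has columns ``profile_id`` (opaque fingerprint from public
    profile information) and ``date`` (:class:`datetime.date`); one row per
    (profile, day) sighting.
    """

    sightings: pd.DataFrame
    period_start: _dt.date
    period_end: _dt.date

    def __post_init__(self) -> None:
        df = self.sightings
        if not {"profile_id", "date"}.issubset(df.columns):
            raise ValueError("ActivityLog needs columns profile_id, date")
        if len(df):
            if df["profile_id"].astype(str).str.len().eq(0).any():
                raise ValueError("empty profile fingerprints present")
            dates = pd.to_datetime(df["date"]).dt.date
            if (dates < self.period_start).any() or (dates > self.period_end).any():
                raise ValueError("sightings outside the observation window")
            self.sightings = df.assign(date=dates)

    @property
    def period_days(self) -> int:
        return (self.period_end - self.period_start).days + 1

    @property
    def n_distinct_profiles(self) -> int:
        return int(self.sightings["profile_id"].nunique())

    @classmethod
    def from_csv(cls, path: str | Path) -> "ActivityLog":
        df = pd.read_csv(path)
        dates = pd.to_datetime(df["date"]).dt.date
        return cls(df.assign(date=dates), period_start=dates.min(), period_end=dates.max())

    def to_csv(self, path: str | Path) -> None:
        out = self.sightings.assign(date=self.sightings["date"].astype(str))
        out.to_csv(path, index=False)

    def profiles_on(self, date: _dt.date) -> set[str]:
        """Set of fingerprints sighted on one day (a capture occasion)."""
        sel = self.sightings["date"] == date
        return set(self.sightings.loc[sel, "profile_id"].astype(str))


@dataclass
class CountResult:
    """A count of active app users over a window, with its provenance."""

    count: int
    method: Literal["dedup", "capture_recapture", "provider"]
    ci: tuple[float, float] | None = None
    period_days: int = 30

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be non-negative")
        if self.ci is not None and not (self.ci[0] <= self.count <= self.ci[1]):
            raise ValueError(f"CI {self.ci} does not bracket count {self.count}")


def dedup_count(
    log: ActivityLog, min_appearances: int = 2, min_spacing_days: int = 3
) -> CountResult:
    """Deduplicated active-user count with the repeat-and-spacing filter.

    A profile is counted iff it was sighted on at least ``min_appearances``
    distinct days and at least two of its sightings are ``min_spacing_days``
    or more apart — excluding one-off or tightly clustered appearances
    typical of short-term visitors.
    """
    if min_appearances < 1 or min_spacing_days < 0:
        raise ValueError("min_appearances >= 1 and min_spacing_days >= 0 required")
    df = log.sightings
    if df.empty:
        warnings.warn("empty activity log: count is 0", stacklevel=2)
        return CountResult(0, "dedup", period_days=log.period_days)
    per = df.drop_duplicates(["profile_id", "date"]).groupby("profile_id")["date"]
    agg = per.agg(n_days="nunique", first="min", last="max")
    span = (pd.to_datetime(agg["last"]) - pd.to_datetime(agg["first"])).dt.days
    ok = (agg["n_days"] >= min_appearances) & (span >= min_spacing_days)
    return CountResult(int(ok.sum()), "dedup", period_days=log.period_days)


def capture_recapture_count(
    capture1: Iterable[str],
    capture2: Iterable[str],
    correction: Literal["lincoln_petersen", "chapman"] = "lincoln_petersen",
    level: float = 0.95,
    period_days: int = 30,
) -> CountResult:
    """Two-sample abundance estimate of active users from two capture days.

    Lincoln–Petersen: ``N = n1*n2/m``; Chapman (bias-corrected, defined even
    at ``m = 0``): ``N = (n1+1)(n2+1)/(m+1) - 1``.  The CI is a normal
    approximation from the chosen estimator's standard variance, with the
    lower bound floored at ``max(n1, n2)`` (the population cannot be smaller
    than either capture).
    """
    s1, s2 = set(capture1), set(capture2)
    if not s1 or not s2:
        raise EstimationError("both captures must be non-empty")
    n1, n2, m = len(s1), len(s2), len(s1 & s2)
    if correction == "lincoln_petersen":
        if m == 0:
            raise EstimationError(
                "no overlap between captures: Lincoln-Petersen undefined; use correction='chapman'"
            )
        n_hat = n1 * n2 / m
        var = n1 * n2 * (n1 - m) * (n2 - m) / m**3
    elif correction == "chapman":
        n_hat = (n1 + 1) * (n2 + 1) / (m + 1) - 1
        var = (n1 + 1) * (n2 + 1) * (n1 - m) * (n2 - m) / ((m + 1) ** 2 * (m + 2))
    else:
        raise ValueError(f"unknown correction {correction!r}")
    z = stats.norm.ppf(0.5 + level / 2)
    se = float(np.sqrt(var))
    lo = max(n_hat - z * se, float(max(n1, n2)))
    hi = n_hat + z * se
    count = round_half_up(n_hat)
    lo = min(lo, count)  # keep the CI bracketing the rounded point
    return CountResult(count, "capture_recapture", ci=(lo, hi), period_days=period_days)


def provider_count(value: int, period_days: int = 30) -> CountResult:
    """An aggregate, unduplicated user count supplied by the app operator."""
    if value < 0:
        raise ValueError("provider count must be non-negative")
    return CountResult(int(value), "provider", period_days=period_days)
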