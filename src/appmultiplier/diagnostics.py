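"""RDS estimator-quality battery: homophily, convergence, bottlenecks,
sensitivity, estimator selection, and group-comparison tests.

Chain-referral samples are only as good as the mixing of the recruitment
process.  This module quantifies that mixing and encodes the decision rule
used to pick between the RDS-I and Gile's SS estimators:

* RDS-I tends to underestimate when the cumulative estimate has not
  converged;
* the SS bootstrap tends to underestimate when recruitment homophily is
  below 1 or seeds were chosen with bias.

With per-province diagnostics in hand, the rule picks RDS-I when more
provinces show homophily < 1 than fail to converge, and Gile's SS otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Literal

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EstimationError
from .rds import RdsSample

__all__ = [
    "DiagnosticsReport",
    "SelectionResult",
    "homophily",
    "convergence_check",
    "bottleneck_series",
    "sensitivity_check",
    "select_estimator",
    "compare_groups",
    "diagnose",
]


@dataclass
class DiagnosticsReport:
    """Bundle of the diagnostic battery for one sample/trait."""

    homophily_value: float
    converged: bool
    convergence_series: list[tuple[int, float]] = field(default_factory=list)
    bottleneck_series: dict = field(default_factory=dict)
    bottleneck_gap: float | None = None
    sensitive: bool | None = None
    province: str | None = None
    notes: str = ""


@dataclass
class SelectionResult:
    estimator: Literal["rds_i", "giles_ss"]
    n_homophily_lt1: int
    n_not_converged: int
    rationale: str


def homophily(sample: RdsSample, trait: str) -> float:
    """Recruitment homophily: observed / expected same-group recruitments.

    The expectation is under random mixing given the composition of the
    recruit pool: a recruiter from group g is expected to match with
    probability equal to g's share among all recruits.  1 = random mixing;
    > 1 = assortative recruitment; < 1 = disassortative.
    """
    pairs = sample.recruitment_pairs(trait)
    if pairs.empty:
        raise EstimationError("no recruitment pairs with the trait observed on both ends")
    obs = int((pairs["recruiter_value"] == pairs["recruit_value"]).sum())
    p_recruit_A = float((pairs["recruit_value"] == 1).mean())
    n_from_A = int((pairs["recruiter_value"] == 1).sum())
    n_from_B = len(pairs) - n_from_A
    expected = n_from_A * p_recruit_A + n_from_B * (1 - p_recruit_A)
    if expected == 0:
        raise EstimationError("expected same-group recruitments is zero; homophily undefined")
    return obs / expected


def _cumulative_series(
    sample: RdsSample,
    trait: str,
    estimator: str | Callable[[RdsSample, str], float],
    min_n: int = 25,
    step: int = 1,
    **est_kwargs,
) -> list[tuple[int, float]]:
    """Cumulative estimate in recruitment order, prefix sizes min_n..n.

    RDS-I and the crude proportion have O(n) vectorised paths; other
    estimators (or callables) are recomputed per prefix.  Prefixes where the
    estimator is undefined are omitted.
    """
    df = sample.data
    n = len(df)
    sizes = list(range(min(min_n, n), n + 1, step))
    if sizes and sizes[-1] != n:
        sizes.append(n)
    vals = df[trait].to_numpy(dtype=float)
    deg = df["degree"].to_numpy(dtype=float)

    if estimator == "sample_proportion":
        ok = ~np.isnan(vals)
        cum_A = np.cumsum(np.where(ok, vals == 1, 0))
        cum_n = np.cumsum(ok)
        series = []
        for k in sizes:
            if cum_n[k - 1] > 0:
                series.append((k, float(cum_A[k - 1] / cum_n[k - 1])))
        return series

    if estimator == "rds_i":
        # transitions attributed to the recruit's position in the ordering
        pos = {rid: i for i, rid in enumerate(df["id"])}
        rec_of = df["recruiter_id"]
        is_A = vals == 1
        is_B = vals == 0
        t = np.zeros((n, 4))  # AA, AB, BA, BB indicator per position
        for i, (rid, recruiter) in enumerate(zip(df["id"], rec_of)):
            if pd.isna(recruiter):
                continue
            j = pos[recruiter]
            rv, cv = vals[j], vals[i]
            if np.isnan(rv) or np.isnan(cv):
                continue
            t[i, 2 * (1 - int(rv)) + (1 - int(cv))] = 1
        ct = np.cumsum(t, axis=0)
        inv = 1.0 / deg
        cum_invA = np.cumsum(np.where(is_A, inv, 0.0))
        cum_invB = np.cumsum(np.where(is_B, inv, 0.0))
        cum_nA = np.cumsum(is_A)
        cum_nB = np.cumsum(is_B)
        series = []
        for k in sizes:
            i = k - 1
            nA, nB = cum_nA[i], cum_nB[i]
            if nB == 0:
                series.append((k, 1.0))
                continue
            if nA == 0:
                series.append((k, 0.0))
                continue
            rowA = ct[i, 0] + ct[i, 1]
            rowB = ct[i, 2] + ct[i, 3]
            if rowA == 0 or rowB == 0:
                continue
            S_AB = ct[i, 1] / rowA
            S_BA = ct[i, 2] / rowB
            D_A = nA / cum_invA[i]
            D_B = nB / cum_invB[i]
            denom = S_AB * D_A + S_BA * D_B
            if denom == 0:
                continue
            series.append((k, float(S_BA * D_B / denom)))
        return series

    # generic path: recompute per prefix
    if callable(estimator):
        fn = estimator
    elif estimator == "giles_ss":
        from .rds import giles_ss_proportion

        def fn(s: RdsSample, tr: str) -> float:
            return giles_ss_proportion(s, tr, compute_ci=False, **est_kwargs).p_hat
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    series = []
    for k in sizes:
        try:
            series.append((k, float(fn(sample.prefix(k), trait))))
        except EstimationError:
            continue
    return series


def convergence_check(
    sample: RdsSample,
    trait: str,
    estimator: str | Callable[[RdsSample, str], float] = "rds_i",
    tol: float = 0.02,
    window_frac: float = 0.25,
    mode: Literal["absolute", "relative"] = "absolute",
    min_n: int = 25,
    step: int = 1,
    **est_kwargs,
) -> tuple[bool, list[tuple[int, float]]]:
    """Stability of the cumulative estimate as the sample grows.

    The estimate is recomputed cumulatively in recruitment order; the sample
    has converged if every estimate in the final ``window_frac`` of the
    series lies within ``tol`` of the final estimate (absolute by default;
    ``mode="relative"`` scales the band by the final estimate).
    """
    series = _cumulative_series(sample, trait, estimator, min_n=min_n, step=step, **est_kwargs)
    if not series:
        raise EstimationError("estimator undefined on every prefix; no convergence series")
    ests = np.array([e for _, e in series])
    final = ests[-1]
    w = max(1, int(np.ceil(window_frac * len(ests))))
    band = tol if mode == "absolute" else tol * abs(final)
    converged = bool(np.all(np.abs(ests[-w:] - final) <= band))
    return converged, series


def bottleneck_series(
    sample: RdsSample,
    trait: str,
    estimator: str | Callable[[RdsSample, str], float] = "sample_proportion",
    min_n: int = 2,
) -> tuple[dict, float | None]:
    """Per-seed cumulative estimate series and the max final gap.

    For each seed with at least 2 respondents, the cumulative estimate is
    recomputed within that seed's recruitment subtree.  The gap is the
    largest pairwise absolute difference between final per-seed estimates
    (None with fewer than two qualifying seeds).  Diverging per-seed series
    indicate the chains are trapped in different communities
    ("bottlenecking").

    The default per-seed estimator is the crude proportion: subtree
    transition matrices are frequently degenerate, which would leave RDS-I
    undefined on many seeds.
    """
    seeds = sample.seeds["id"].tolist()
    series: dict = {}
    finals = []
    for s in seeds:
        sub = sample.subtree(s)
        if sub.n < min_n:
            continue
        ser = _cumulative_series(sub, trait, estimator, min_n=1)
        if not ser:
            continue
        series[s] = ser
        finals.append(ser[-1][1])
    gap = None
    if len(finals) >= 2:
        arr = np.array(finals)
        gap = float(arr.max() - arr.min())
    return series, gap


def sensitivity_check(p_hat: float, low: float = 0.2, high: float = 0.8) -> bool:
    """True (estimator *not* sensitive) iff low <= p_hat <= high, inclusive.

    Proportions near 0 or 1 make the multiplier's division unstable, so
    estimates outside the band are treated as sensitive/unreliable.
    """
    if not (0 <= p_hat <= 1):
        raise ValueError("p_hat must be a proportion")
    return low <= p_hat <= high


def select_estimator(reports: Iterable[DiagnosticsReport]) -> SelectionResult:
    """Pick RDS-I or Gile's SS from the per-province diagnostic battery.

    RDS-I is chosen iff strictly more provinces show recruitment homophily
    below 1 (the SS bootstrap's underestimation condition) than fail the
    convergence check (RDS-I's underestimation condition); ties go to
    Gile's SS.
    """
    reports = list(reports)
    if not reports:
        raise ValueError("at least one diagnostics report required")
    n_hom = sum(1 for r in reports if r.homophily_value < 1)
    n_nc = sum(1 for r in reports if not r.converged)
    if n_hom > n_nc:
        est = "rds_i"
        why = (
            f"{n_hom} province(s) with homophily < 1 (SS-bootstrap bias condition) vs "
            f"{n_nc} not converged (RDS-I bias condition): RDS-I less prone to underestimate"
        )
    else:
        est = "giles_ss"
        why = (
            f"{n_hom} province(s) with homophily < 1 vs {n_nc} not converged: "
            "Gile's SS selected"
        )
        if n_hom == n_nc:
            why += " (tie broken in favour of Gile's SS)"
    return SelectionResult(est, n_hom, n_nc, why)


@dataclass
class GroupComparison:
    test: Literal["t", "chi2"]
    statistic: float
    df: int
    p_value: float


def compare_groups(sample: RdsSample, grouping: str, outcome: str) -> GroupComparison:
    """Compare an outcome between the two groups of a binary trait.

    Binary outcomes get a Pearson chi-square (no continuity correction) on
    the 2x2 table; continuous outcomes get an equal-variance two-sample
    t test with pooled df ``n1 + n2 - 2``.
    """
    df = sample.data[[grouping, outcome]].dropna()
    g = df[grouping]
    y = df[outcome]
    a, b = y[g == 1], y[g == 0]
    if len(a) < 2 or len(b) < 2:
        raise EstimationError("need at least 2 observations per group")
    values = set(pd.unique(y))
    if values.issubset({0, 1}):
        table = pd.crosstab(g, y).to_numpy()
        if table.shape != (2, 2) or (table.sum(axis=0) == 0).any():
            raise EstimationError("2x2 table degenerate; chi-square undefined")
        chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
        return GroupComparison("chi2", float(chi2), int(dof), float(p))
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise EstimationError("zero variance in both groups; t test undefined")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return GroupComparison("t", float(t), len(a) + len(b) - 2, float(p))


def diagnose(
    sample: RdsSample,
    trait: str,
    estimator: str = "rds_i",
    p_hat: float | None = None,
    tol: float = 0.02,
    window_frac: float = 0.25,
    sensitivity_bounds: tuple[float, float] = (0.2, 0.8),
    province: str | None = None,
    bottleneck_flag_gap: float = 0.10,
    **est_kwargs,
) -> DiagnosticsReport:
    """Run the full battery on one sample/trait and bundle the report."""
    notes = [
        "homophily convention: 1 = random mixing, >1 = assortative recruitment "
        "(the selection rule reads the numeric threshold '< 1' directly)"
    ]
    h = homophily(sample, trait)
    converged, series = convergence_check(
        sample, trait, estimator, tol=tol, window_frac=window_frac, **est_kwargs
    )
    bseries, gap = bottleneck_series(sample, trait)
    if gap is not None and gap > bottleneck_flag_gap:
        notes.append(f"bottleneck gap {gap:.3f} exceeds {bottleneck_flag_gap}")
    sensitive = None
    if p_hat is None and series:
        p_hat = series[-1][1]
    if p_hat is not None:
        sensitive = not sensitivity_check(p_hat, *sensitivity_bounds)
    return DiagnosticsReport(
        homophily_value=h,
        converged=converged,
        convergence_series=series,
        bottleneck_series=bseries,
        bottleneck_gap=gap,
        sensitive=sensitive,
        province=province,
        notes="; ".join(notes),
    )
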