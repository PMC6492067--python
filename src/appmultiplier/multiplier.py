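"""Multiplier population estimates and age-weighted national extrapolation.

The multiplier method estimates a hidden population's size as

    N_hat = (count of members in a defining source) / (proportion of a
             representative sample belonging to that source)

Here the source is a social app: the numerator is a provincial count of
active app users (``counting``) and the denominator an RDS-estimated
proportion of app users among the population (``rds``).  CI bounds divide
the fixed count by the proportion's CI bounds.

Provincial estimates are then extrapolated to unobserved provinces within
geographic/socioeconomic regions via the age-weighted percentage of the
population among adult males, and summed — together with any pilot-study
estimates — into a national total with bound-wise CI propagation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._utils import round_half_up
from .counting import CountResult
from .errors import EstimationError
from .rds import ProportionEstimate

__all__ = [
    "AGE_BANDS",
    "MultiplierEstimate",
    "ProvinceRecord",
    "PilotEstimate",
    "ExtrapolationConfig",
    "NationalEstimate",
    "multiplier_estimate",
    "weighted_msm_percentage",
    "extrapolate_national",
    "summary_table",
    "add_total_row",
]

AGE_BANDS = ("15-19", "20-24", "25-29", "30-34", "35-39", "40-44", "45-49")


@dataclass
class MultiplierEstimate:
    """A provincial population-size estimate from count / proportion."""

    province: str
    count: CountResult
    proportion: ProportionEstimate
    n_hat: int
    ci: tuple[float, float]
    reliable: bool = True
    notes: str = ""


def multiplier_estimate(
    count: CountResult, proportion: ProportionEstimate, province: str = ""
) -> MultiplierEstimate:
    """Divide the app-user count by the estimated proportion of app users.

    Reported figures are rounded half-up at this final step only; the CI
    divides the count by the proportion's CI bounds (larger proportion bound
    -> smaller population bound).  A zero lower proportion bound yields an
    infinite upper population bound, flagged unreliable.
    """
    p = proportion.p_hat
    if not (0 < p <= 1):
        raise EstimationError(f"proportion must be in (0, 1], got {p}")
    n_hat = round_half_up(count.count / p)
    notes = []
    reliable = proportion.reliable
    if proportion.ci is None:
        ci = (float(n_hat), float(n_hat))
        notes.append("proportion carried no CI; population CI collapsed to the point")
    else:
        lo_p, hi_p = proportion.ci
        hi = math.inf if lo_p == 0 else round_half_up(count.count / lo_p)
        lo = round_half_up(count.count / hi_p) if hi_p > 0 else math.inf
        if math.isinf(hi):
            reliable = False
            notes.append("proportion CI touches 0: upper population bound unbounded")
        ci = (float(lo), float(hi))
    if not proportion.reliable:
        notes.append("proportion was flagged unreliable")
    return MultiplierEstimate(
        province=province, count=count, proportion=proportion,
        n_hat=n_hat, ci=ci, reliable=reliable, notes="; ".join(notes),
    )


@dataclass
class ProvinceRecord:
    name: str
    region: str
    male_pop_by_age: dict[str, float]
    observed: bool = False

    @property
    def male_pop_15_49(self) -> float:
        return float(sum(self.male_pop_by_age[b] for b in AGE_BANDS))


@dataclass
class PilotEstimate:
    province: str
    n_hat: float
    ci: tuple[float, float] | None = None


@dataclass
class ExtrapolationConfig:
    """Region mapping, male population by age band, and the app users' age mix."""

    provinces: list[ProvinceRecord]
    app_age_distribution: dict[str, float]
    pilot_estimates: list[PilotEstimate] = field(default_factory=list)

    def __post_init__(self) -> None:
        total = sum(self.app_age_distribution.get(b, 0.0) for b in AGE_BANDS)
        missing = [b for b in AGE_BANDS if b not in self.app_age_distribution]
        if missing:
            raise ValueError(f"app_age_distribution missing bands: {missing}")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"app_age_distribution must sum to 1, got {total}")
        for p in self.provinces:
            missing = [b for b in AGE_BANDS if b not in p.male_pop_by_age]
            if missing:
                raise ValueError(f"province {p.name}: missing age bands {missing}")
            if any(p.male_pop_by_age[b] <= 0 for b in AGE_BANDS):
                raise ValueError(f"province {p.name}: populations must be positive")

    @classmethod
    def from_dict(cls, d: Mapping) -> "ExtrapolationConfig":
        provinces = [
            ProvinceRecord(
                name=p["name"], region=p["region"],
                male_pop_by_age={k: float(v) for k, v in p["male_pop_by_age"].items()},
                observed=bool(p.get("observed", False)),
            )
            for p in d["provinces"]
        ]
        pilots = [
            PilotEstimate(
                province=q["province"], n_hat=float(q["n_hat"]),
                ci=tuple(q["ci"]) if q.get("ci") else None,
            )
            for q in d.get("pilot_estimates", [])
        ]
        return cls(provinces, dict(d["app_age_distribution"]), pilots)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExtrapolationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class NationalEstimate:
    total: float
    ci: tuple[float, float]
    pct_adult_males: float
    pct_ci: tuple[float, float]
    provenance: dict[str, str]
    per_province: dict[str, float] = field(default_factory=dict)
    notes: str = ""


def weighted_msm_percentage(
    estimate: "MultiplierEstimate | float",
    male_pop_by_age: Mapping[str, float],
    app_age_distribution: Mapping[str, float],
    extend_15_17: bool = True,
) -> float:
    """Age-weighted percentage of the population among adult males 15-49.

    The 18-49 population estimate is allocated to the seven 5-year age bands
    in proportion to the app users' age distribution.  The survey observes
    nobody under 18, so with ``extend_15_17`` (default) the 15-19 band's
    allocation — which covers ages 18-19 only — is rescaled by 5/2 under a
    uniform-within-band assumption to also cover ages 15-17.
    """
    n_hat = estimate.n_hat if isinstance(estimate, MultiplierEstimate) else float(estimate)
    missing = [b for b in AGE_BANDS if b not in male_pop_by_age]
    if missing:
        raise ValueError(f"male_pop_by_age missing bands: {missing}")
    missing = [b for b in AGE_BANDS if b not in app_age_distribution]
    if missing:
        raise ValueError(f"app_age_distribution missing bands: {missing}")
    total_dist = sum(app_age_distribution[b] for b in AGE_BANDS)
    if abs(total_dist - 1.0) > 1e-9:
        raise ValueError("app_age_distribution must sum to 1")
    alloc = {b: n_hat * app_age_distribution[b] for b in AGE_BANDS}
    if extend_15_17:
        alloc["15-19"] *= 5.0 / 2.0
    pop_total = sum(male_pop_by_age[b] for b in AGE_BANDS)
    if pop_total <= 0:
        raise ValueError("male population must be positive")
    return 100.0 * sum(alloc.values()) / pop_total


def _regional_pct(
    observed: Sequence[tuple[ProvinceRecord, float]],
    method: Literal["population_weighted", "unweighted", "median"],
) -> float:
    pcts = np.array([pct for _, pct in observed])
    if method == "population_weighted":
        w = np.array([rec.male_pop_15_49 for rec, _ in observed])
        return float(np.average(pcts, weights=w))
    if method == "unweighted":
        return float(pcts.mean())
    if method == "median":
        return float(np.median(pcts))
    raise ValueError(f"unknown averaging method {method!r}")


def extrapolate_national(
    provincial: Sequence[MultiplierEstimate],
    config: ExtrapolationConfig,
    method: Literal["population_weighted", "unweighted", "median"] = "population_weighted",
    extend_15_17: bool = True,
) -> NationalEstimate:
    """Extrapolate observed provinces to the rest of the country and sum.

    Each unobserved province receives the regional average (default:
    population-weighted mean) of the observed provinces' age-weighted
    percentages, applied to its own male population 15-49.  The national
    total is the sum of observed, extrapolated and pilot estimates; the CI
    applies the identical procedure to the provincial CI bounds (bound-wise,
    assuming no cancellation between provinces).
    """
    by_name = {rec.name: rec for rec in config.provinces}
    est_by_name = {e.province: e for e in provincial}
    unknown = [p for p in est_by_name if p not in by_name]
    if unknown:
        raise ValueError(f"estimates for provinces absent from config: {unknown}")

    def pct_of(e: MultiplierEstimate, value: float) -> float:
        rec = by_name[e.province]
        return weighted_msm_percentage(
            value, rec.male_pop_by_age, config.app_age_distribution,
            extend_15_17=extend_15_17,
        )

    # observed percentages per region, for point and both bounds
    regions: dict[str, list] = {}
    for e in est_by_name.values():
        rec = by_name[e.province]
        regions.setdefault(rec.region, []).append(
            (rec, pct_of(e, e.n_hat), pct_of(e, e.ci[0]), pct_of(e, e.ci[1]))
        )

    provenance: dict[str, str] = {}
    per_province: dict[str, float] = {}
    tot = lo = hi = 0.0
    for e in est_by_name.values():
        provenance[e.province] = "observed"
        per_province[e.province] = float(e.n_hat)
        tot += e.n_hat
        lo += e.ci[0]
        hi += e.ci[1]

    for rec in config.provinces:
        if rec.name in est_by_name:
            continue
        if rec.region not in regions:
            raise EstimationError(
                f"region {rec.region!r} has no observed province to extrapolate from"
            )
        obs = regions[rec.region]
        pct = _regional_pct([(r, p) for r, p, _, _ in obs], method)
        pct_lo = _regional_pct([(r, p) for r, _, p, _ in obs], method)
        pct_hi = _regional_pct([(r, p) for r, _, _, p in obs], method)
        n_ext = pct / 100.0 * rec.male_pop_15_49
        provenance[rec.name] = "extrapolated"
        per_province[rec.name] = n_ext
        tot += n_ext
        lo += pct_lo / 100.0 * rec.male_pop_15_49
        hi += pct_hi / 100.0 * rec.male_pop_15_49

    for q in config.pilot_estimates:
        provenance[q.province] = "pilot"
        per_province[q.province] = q.n_hat
        tot += q.n_hat
        qlo, qhi = q.ci if q.ci else (q.n_hat, q.n_hat)
        lo += qlo
        hi += qhi

    national_pop = sum(rec.male_pop_15_49 for rec in config.provinces)
    pct = 100.0 * tot / national_pop
    pct_ci = (100.0 * lo / national_pop, 100.0 * hi / national_pop)
    return NationalEstimate(
        total=tot, ci=(lo, hi), pct_adult_males=pct, pct_ci=pct_ci,
        provenance=provenance, per_province=per_province,
        notes="national male population from the config's provinces only; "
        "pilot provinces contribute their estimates but not population "
        "unless listed in config.provinces",
    )


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

SUMMARY_COLUMNS = [
    "province", "count_30d", "proportion", "prop_ci_low", "prop_ci_high",
    "pop_estimate", "pop_ci_low", "pop_ci_high",
]


def summary_table(estimates: Sequence[MultiplierEstimate]) -> pd.DataFrame:
    """Provincial summary rows (count, proportion + CI, population + CI)."""
    rows = []
    for e in estimates:
        lo_p, hi_p = e.proportion.ci if e.proportion.ci else (np.nan, np.nan)
        rows.append(
            {
                "province": e.province,
                "count_30d": e.count.count,
                "proportion": e.proportion.p_hat,
                "prop_ci_low": lo_p,
                "prop_ci_high": hi_p,
                "pop_estimate": e.n_hat,
                "pop_ci_low": e.ci[0],
                "pop_ci_high": e.ci[1],
            }
        )
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def add_total_row(table: pd.DataFrame) -> pd.DataFrame:
    """Append a Total row: counts, population estimates and CI bounds sum
    across provinces; the total proportion is the self-consistent multiplier
    ratio total_count / total_population."""
    t = table.copy()
    count_sum = t["count_30d"].sum()
    pop_sum = t["pop_estimate"].sum()
    total = {
        "province": "Total",
        "count_30d": count_sum,
        "proportion": count_sum / pop_sum if pop_sum else np.nan,
        "prop_ci_low": np.nan,
        "prop_ci_high": np.nan,
        "pop_estimate": pop_sum,
        "pop_ci_low": t["pop_ci_low"].sum(),
        "pop_ci_high": t["pop_ci_high"].sum(),
    }
    return pd.concat([t, pd.DataFrame([total])], ignore_index=True)


def ss_multiplier_fixed_point(
    sample,
    trait: str,
    count: CountResult,
    sim_reps: int = 200,
    max_iter: int = 20,
    rel_tol: float = 0.01,
    rng_seed: int = 0,
    n0: int | None = None,
) -> tuple[ProportionEstimate, MultiplierEstimate]:
    """Resolve the circularity of Gile's SS needing the population size.

    The SS estimator requires a prior N, but N is exactly what the
    multiplier produces.  This iterates SS(N_k) -> multiplier -> N_{k+1}
    from a crude starting value until the implied N changes by less than
    ``rel_tol`` (relative).
    """
    from .rds import giles_ss_proportion, sample_proportion

    if n0 is None:
        p0 = max(sample_proportion(sample, trait), 1e-3)
        n0 = max(int(count.count / p0), sample.n + 1)
    N = n0
    est = None
    for _ in range(max_iter):
        est = giles_ss_proportion(
            sample, trait, population_size=max(N, sample.n + 1),
            sim_reps=sim_reps, rng_seed=rng_seed, compute_ci=False,
        )
        N_new = max(round_half_up(count.count / est.p_hat), sample.n + 1)
        if abs(N_new - N) <= rel_tol * N:
            N = N_new
            break
        N = N_new
    est = giles_ss_proportion(
        sample, trait, population_size=max(N, sample.n + 1),
        sim_reps=sim_reps, rng_seed=rng_seed,
    )
    return est, multiplier_estimate(count, est)
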