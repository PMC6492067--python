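"""Synthetic populations with known ground truth.

Everything downstream of the field work — counting app users, RDS proportion
estimation, diagnostics, the multiplier — is testable by parameter recovery
if the data come from a generator whose truth is known.  This module builds:

* a two-group social network (group A = app users, group B = non-users) with
  negative-binomial degrees and a tunable within-group tie preference
  (``homophily_w``; 1 = random mixing), via a degree-corrected stochastic
  block model;
* coupon-limited RDS recruitment chains over that network;
* a multi-day app activity log (daily logins by group-A members plus
  transient single-day "visitor" profiles).

All randomness flows from ``PopulationSpec.rng_seed`` through per-stage
substreams, so a fixed seed reproduces the network, the sample and the log
byte-for-byte.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from ._utils import rng_for, to_json
from .counting import ActivityLog
from .errors import InfeasibleSpecError, PartialSampleWarning
from .rds import RdsSample

__all__ = [
    "PopulationSpec",
    "SimTruth",
    "generate_network",
    "simulate_rds",
    "simulate_activity_log",
    "ground_truth",
    "simulate_study",
]


@dataclass
class PopulationSpec:
    """Parameters of the simulated population and survey design.

    Defaults mirror the study conditions the pipeline is exercised under:
    a province-scale hidden population of 10,000 with app-use prevalence
    0.35, mean personal network size ~10, random mixing, and an RDS design
    of 6 seeds, 3 coupons and a 400-respondent target.
    """

    N: int = 10_000
    prevalence: float = 0.35
    degree_mean: float = 10.0
    degree_dispersion: float = 3.0
    homophily_w: float = 1.0
    seed_count: int = 6
    coupon_limit: int = 3
    sample_target: int = 400
    seed_bias: float | None = None
    rng_seed: int = 0
    # trait-generation knobs (see methods note)
    p_ever_given_nonuser: float = 0.3
    p_sex12m_by_group: tuple[float, float] = (0.95, 0.75)  # (A, B)
    province: str = "SimProvince"

    def __post_init__(self) -> None:
        if not (0 < self.prevalence < 1):
            raise InfeasibleSpecError(f"prevalence must be in (0, 1), got {self.prevalence}")
        if self.N <= self.sample_target:
            raise InfeasibleSpecError("N must exceed sample_target")
        if self.coupon_limit < 0:
            raise InfeasibleSpecError("coupon_limit must be >= 0")
        if self.degree_mean < 1:
            raise InfeasibleSpecError("degree_mean must be >= 1")
        if self.degree_mean >= self.N:
            raise InfeasibleSpecError("degree_mean must be far below N")
        if self.degree_dispersion <= 0:
            raise InfeasibleSpecError("degree_dispersion must be positive")
        if self.homophily_w <= 0:
            raise InfeasibleSpecError("homophily_w must be positive")
        if self.seed_bias is not None and not (0 <= self.seed_bias <= 1):
            raise InfeasibleSpecError("seed_bias must be in [0, 1]")


@dataclass
class SimTruth:
    """Realised ground truth of one simulated population."""

    true_N: int
    true_prevalence_A: float
    true_mean_degree_by_group: tuple[float, float]
    network_edge_count: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(to_json(self))


def _draw_degrees(spec: PopulationSpec, rng: np.random.Generator) -> np.ndarray:
    """Negative-binomial degrees (mean degree_mean, size degree_dispersion), min 1."""
    k = spec.degree_dispersion
    p = k / (k + spec.degree_mean)
    d = rng.negative_binomial(k, p, size=spec.N)
    return np.maximum(d, 1)


def generate_network(spec: PopulationSpec, rng: np.random.Generator | None = None) -> nx.Graph:
    """Simulate the two-group social network.

    Degree-corrected block model: target degrees are drawn per node, and the
    expected number of edges in each group block is the random-mixing value
    multiplied by ``homophily_w`` for the two within-group blocks, rescaled so
    the total expected edge count is preserved.  Edge endpoints are chosen
    proportional to target degree within their block; self-loops and parallel
    edges are discarded, so the graph is simple and realised degrees
    approximate the drawn ones.

    Nodes are ``0..N-1`` with a ``group`` attribute (1 = app user / group A).
    """
    if rng is None:
        rng = rng_for(spec.rng_seed, stream=0)
    N = spec.N
    n_A = int(round(N * spec.prevalence))
    groups = np.zeros(N, dtype=np.int8)
    groups[rng.permutation(N)[:n_A]] = 1

    deg = _draw_degrees(spec, rng).astype(float)
    idx_A = np.flatnonzero(groups == 1)
    idx_B = np.flatnonzero(groups == 0)
    S_A, S_B = deg[idx_A].sum(), deg[idx_B].sum()
    S = S_A + S_B

    # expected edges per block under random mixing, then homophily tilt
    lam = {
        ("A", "A"): spec.homophily_w * S_A * S_A / (2 * S),
        ("B", "B"): spec.homophily_w * S_B * S_B / (2 * S),
        ("A", "B"): S_A * S_B / S,
    }
    scale = (S / 2) / sum(lam.values())
    edges: list[np.ndarray] = []
    for (r, c), ev in lam.items():
        m = rng.poisson(ev * scale)
        if m == 0:
            continue
        src_pool = idx_A if r == "A" else idx_B
        dst_pool = idx_A if c == "A" else idx_B
        p_src = deg[src_pool] / deg[src_pool].sum()
        p_dst = deg[dst_pool] / deg[dst_pool].sum()
        u = rng.choice(src_pool, size=m, p=p_src)
        v = rng.choice(dst_pool, size=m, p=p_dst)
        edges.append(np.column_stack([u, v]))
    ev = np.vstack(edges)
    ev = ev[ev[:, 0] != ev[:, 1]]
    ev = np.unique(np.sort(ev, axis=1), axis=0)

    G = nx.Graph()
    G.add_nodes_from(range(N))
    nx.set_node_attributes(G, {i: int(g) for i, g in enumerate(groups)}, "group")
    G.add_edges_from(map(tuple, ev))
    return G


def _sample_traits(
    spec: PopulationSpec, group: int, rng: np.random.Generator
) -> dict[str, int]:
    app_30d = group
    app_ever = 1 if group == 1 else int(rng.random() < spec.p_ever_given_nonuser)
    p_sex = spec.p_sex12m_by_group[0] if group == 1 else spec.p_sex12m_by_group[1]
    sex_12m = int(rng.random() < p_sex)
    # generated respondents are all eligible: non-MSM-active respondents
    # qualify through the preference question
    prefer_women_only = 0
    return {
        "app_30d": app_30d,
        "app_ever": app_ever,
        "sex_12m": sex_12m,
        "prefer_women_only": prefer_women_only,
    }


def _sample_age(rng: np.random.Generator) -> int:
    # right-skewed adult ages, median ~24, truncated to the survey's 18-49
    age = 18 + int(rng.gamma(2.0, 3.5))
    return min(age, 49)


def simulate_rds(
    network: nx.Graph,
    spec: PopulationSpec,
    rng: np.random.Generator | None = None,
    degree_noise_sd: float = 0.0,
) -> RdsSample:
    """Simulate coupon-limited RDS recruitment over the network.

    Seeds are drawn uniformly among nodes with at least one tie (optionally
    ``seed_bias`` forces a fraction of seeds into group A).  Respondents are
    processed in recruitment order; each recruits up to ``coupon_limit``
    not-yet-sampled neighbours chosen uniformly without replacement.
    Recruitment stops at ``sample_target`` or when every chain has died.

    Reported degree is the respondent's realised network degree, optionally
    perturbed by multiplicative log-normal noise (``degree_noise_sd`` on the
    log scale) to mimic misreported network sizes.
    """
    if rng is None:
        rng = rng_for(spec.rng_seed, stream=1)
    if spec.sample_target > network.number_of_nodes():
        raise InfeasibleSpecError("sample_target exceeds network size")
    groups = nx.get_node_attributes(network, "group")
    eligible = [v for v in network.nodes if network.degree(v) >= 1]

    if spec.seed_bias is None:
        seeds = list(rng.choice(eligible, size=spec.seed_count, replace=False))
    else:
        n_seed_A = int(round(spec.seed_bias * spec.seed_count))
        pool_A = [v for v in eligible if groups[v] == 1]
        pool_B = [v for v in eligible if groups[v] == 0]
        seeds = list(rng.choice(pool_A, size=n_seed_A, replace=False)) + list(
            rng.choice(pool_B, size=spec.seed_count - n_seed_A, replace=False)
        )

    sampled: set[int] = set(seeds)
    rows: list[dict] = []
    queue: list[int] = []
    seed_of: dict[int, int] = {}
    order = 0
    for s in seeds:
        seed_of[s] = s
        rows.append({"id": s, "recruiter_id": None, "seed_id": s, "order": order})
        order += 1
        queue.append(s)

    qi = 0
    while qi < len(queue) and len(sampled) < spec.sample_target:
        r = queue[qi]
        qi += 1
        avail = [v for v in network.neighbors(r) if v not in sampled]
        if not avail:
            continue
        k = min(spec.coupon_limit, len(avail), spec.sample_target - len(sampled))
        if k == 0:
            continue
        recruits = rng.choice(avail, size=k, replace=False)
        for v in recruits:
            v = int(v)
            sampled.add(v)
            seed_of[v] = seed_of[r]
            rows.append({"id": v, "recruiter_id": r, "seed_id": seed_of[r], "order": order})
            order += 1
            queue.append(v)

    if len(sampled) < 0.5 * spec.sample_target:
        warnings.warn(
            f"all chains died at n={len(sampled)} before reaching 50% of "
            f"sample_target={spec.sample_target}",
            PartialSampleWarning, stacklevel=2,
        )

    df = pd.DataFrame(rows)
    true_deg = np.array([network.degree(v) for v in df["id"]], dtype=float)
    if degree_noise_sd > 0:
        noise = rng.lognormal(mean=0.0, sigma=degree_noise_sd, size=true_deg.size)
        reported = np.maximum(1, np.round(true_deg * noise)).astype(int)
    else:
        reported = true_deg.astype(int)
    df["degree"] = reported
    trait_rows = [_sample_traits(spec, groups[v], rng) for v in df["id"]]
    for col in ("app_30d", "app_ever", "sex_12m", "prefer_women_only"):
        df[col] = [t[col] for t in trait_rows]
    df["age"] = [_sample_age(rng) for _ in range(len(df))]
    df["province"] = spec.province
    return RdsSample(df)


def simulate_activity_log(
    network: nx.Graph,
    spec: PopulationSpec,
    days: int = 30,
    daily_login_prob_by_group: tuple[float, float] = (0.3, 0.0),
    visitor_rate: float = 2.0,
    period_start: _dt.date = _dt.date(2018, 6, 1),
    rng: np.random.Generator | None = None,
) -> ActivityLog:
    """Simulate a multi-day app activity log.

    Each group member logs in independently each day with its group's daily
    probability (group B's default is 0: non-users never appear).  Transient
    "visitor" profiles — short-term travellers the deduplication rule is
    designed to exclude — arrive at ``visitor_rate`` per day and are each
    sighted on exactly one day.
    """
    if days < 2:
        raise InfeasibleSpecError("days must be >= 2")
    if visitor_rate < 0 or any(p < 0 for p in daily_login_prob_by_group):
        raise InfeasibleSpecError("rates and probabilities must be non-negative")
    if rng is None:
        rng = rng_for(spec.rng_seed, stream=2)
    groups = nx.get_node_attributes(network, "group")
    nodes = np.fromiter(groups.keys(), dtype=np.int64)
    garr = np.fromiter(groups.values(), dtype=np.int8)
    p_node = np.where(garr == 1, daily_login_prob_by_group[0], daily_login_prob_by_group[1])

    profile_ids: list[str] = []
    dates: list[_dt.date] = []
    active = p_node > 0
    act_nodes = nodes[active]
    act_p = p_node[active]
    if act_nodes.size:
        logins = rng.random((act_nodes.size, days)) < act_p[:, None]
        who, day = np.nonzero(logins)
        for w, dy in zip(who, day):
            profile_ids.append(f"user{act_nodes[w]}")
            dates.append(period_start + _dt.timedelta(days=int(dy)))

    n_vis = rng.poisson(visitor_rate * days)
    vis_days = rng.integers(0, days, size=n_vis)
    for i, dy in enumerate(vis_days):
        profile_ids.append(f"visitor{i}")
        dates.append(period_start + _dt.timedelta(days=int(dy)))

    df = pd.DataFrame({"profile_id": profile_ids, "date": dates})
    df = df.sort_values(["date", "profile_id"], kind="stable").reset_index(drop=True)
    return ActivityLog(
        df, period_start=period_start, period_end=period_start + _dt.timedelta(days=days - 1)
    )


def ground_truth(network: nx.Graph) -> SimTruth:
    """Realised ground truth of a generated network."""
    groups = np.array([d["group"] for _, d in network.nodes(data=True)])
    deg = np.array([network.degree(v) for v in network.nodes])
    mean_A = float(deg[groups == 1].mean()) if (groups == 1).any() else 0.0
    mean_B = float(deg[groups == 0].mean()) if (groups == 0).any() else 0.0
    return SimTruth(
        true_N=network.number_of_nodes(),
        true_prevalence_A=float(groups.mean()),
        true_mean_degree_by_group=(mean_A, mean_B),
        network_edge_count=network.number_of_edges(),
    )


def simulate_study(
    spec: PopulationSpec,
    days: int = 30,
    daily_login_prob_by_group: tuple[float, float] = (0.3, 0.0),
    visitor_rate: float = 2.0,
) -> tuple[nx.Graph, RdsSample, ActivityLog, SimTruth]:
    """One full simulated province: network, RDS sample, activity log, truth."""
    G = generate_network(spec)
    sample = simulate_rds(G, spec)
    log = simulate_activity_log(
        G, spec, days=days,
        daily_login_prob_by_group=daily_login_prob_by_group,
        visitor_rate=visitor_rate,
    )
    return G, sample, log, ground_truth(G)
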