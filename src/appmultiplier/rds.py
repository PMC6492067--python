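"""Respondent-driven sampling: sample container and proportion estimators.

RDS recruits a hidden population along a coupon-limited referral forest and
reweights by self-reported network size (degree) to undo the bias of
degree-proportional sampling.  Two estimators for the proportion of a binary
trait are provided:

* RDS-I (Salganik–Heckathorn): combines the recruitment transition matrix
  between trait groups with harmonic-mean degrees via the tie-reciprocity
  balance ``P_A = S_BA * D_B / (S_AB * D_A + S_BA * D_B)``.
* Gile's SS (successive sampling): models RDS as without-replacement draws
  proportional to degree from a finite population of assumed size ``N``;
  inclusion probabilities are estimated by simulation and units weighted by
  their reciprocals.

Confidence intervals come from a chain-structured bootstrap that regrows
pseudo-chains from the observed transition matrix and the per-group
(degree, trait) pools.

Throughout the two-group convention is: group A = trait value 1, group B =
trait value 0.  Transition matrices are indexed rows = recruiter group,
columns = recruit group, in order (A, B).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from ._utils import largest_remainder_allocation, rng_for
from .errors import EstimationError, UnreliableEstimateWarning

__all__ = [
    "RdsSample",
    "TransitionMatrix",
    "ProportionEstimate",
    "transition_matrix",
    "harmonic_mean_degree",
    "rds_i_proportion",
    "giles_ss_proportion",
    "bootstrap_ci",
]

REQUIRED_COLUMNS = ("id", "recruiter_id", "seed_id", "order", "degree")


class RdsSample:
    """An RDS sample: respondents with recruiter links, degrees and traits.

    Wraps a :class:`pandas.DataFrame` with columns ``id``, ``recruiter_id``
    (missing for seeds), ``seed_id``, ``order`` (recruitment order, seeds
    first), ``degree`` (self-reported network size, >= 1) plus arbitrary
    trait/covariate columns (binary traits coded 0/1, missing allowed).
    """

    def __init__(self, data: pd.DataFrame, validate: bool = True):
        df = data.copy()
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"RdsSample missing required columns: {missing}")
        df = df.sort_values("order", kind="stable").reset_index(drop=True)
        self.data = df
        if validate:
            self._validate()

    # -- construction / io ------------------------------------------------

    @classmethod
    def from_csv(cls, path: str | Path, validate: bool = True) -> "RdsSample":
        df = pd.read_csv(path)
        return cls(df, validate=validate)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    def _validate(self) -> None:
        df = self.data
        if df["id"].duplicated().any():
            dupes = df.loc[df["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate respondent ids: {dupes[:5]}")
        if (df["degree"] < 1).any():
            raise ValueError("all degrees must be >= 1")
        order_of = dict(zip(df["id"], df["order"]))
        nonseed = df[df["recruiter_id"].notna()]
        for rid, recruiter in zip(nonseed["id"], nonseed["recruiter_id"]):
            if recruiter not in order_of:
                raise ValueError(f"respondent {rid!r}: recruiter {recruiter!r} not in sample")
            if order_of[recruiter] >= order_of[rid]:
                raise ValueError(
                    f"respondent {rid!r}: recruiter {recruiter!r} does not precede it in recruitment order"
                )

    # -- basic accessors ---------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def seeds(self) -> pd.DataFrame:
        return self.data[self.data["recruiter_id"].isna()]

    def degrees(self) -> np.ndarray:
        return self.data["degree"].to_numpy(dtype=float)

    def trait_values(self, trait: str) -> pd.Series:
        if trait not in self.data.columns:
            raise KeyError(f"trait column {trait!r} not present")
        return self.data[trait]

    def groups(self, trait: str) -> tuple[np.ndarray, np.ndarray, int]:
        """(group array with -1 for missing, degree array, number missing)."""
        vals = self.trait_values(trait)
        miss = vals.isna()
        g = vals.fillna(-1).to_numpy(dtype=int)
        return g, self.degrees(), int(miss.sum())

    def recruitment_pairs(self, trait: str) -> pd.DataFrame:
        """Recruiter/recruit trait values for pairs observed on both ends."""
        df = self.data
        vals = df.set_index("id")[trait]
        nonseed = df[df["recruiter_id"].notna()]
        out = pd.DataFrame(
            {
                "recruiter_value": vals.reindex(nonseed["recruiter_id"]).to_numpy(),
                "recruit_value": nonseed[trait].to_numpy(),
            }
        )
        return out.dropna().astype(int).reset_index(drop=True)

    def prefix(self, k: int) -> "RdsSample":
        """First ``k`` respondents in recruitment order (chains truncated)."""
        sub = self.data.iloc[:k].copy()
        kept = set(sub["id"])
        sub.loc[~sub["recruiter_id"].isin(kept), "recruiter_id"] = np.nan
        return RdsSample(sub, validate=False)

    def subtree(self, seed_id) -> "RdsSample":
        sub = self.data[self.data["seed_id"] == seed_id].copy()
        return RdsSample(sub, validate=False)


@dataclass
class TransitionMatrix:
    """Recruitment transitions between trait groups A (=1) and B (=0).

    ``counts[i, j]`` is the number of recruitments by a group-``i`` recruiter
    yielding a group-``j`` recruit with rows/cols ordered (A, B).  ``S`` is the
    row-normalised matrix; rows whose group made no recruitment are NaN and
    flagged in ``undefined_rows``.
    """

    counts: np.ndarray
    S: np.ndarray
    undefined_rows: tuple[str, ...] = ()

    @property
    def S_AA(self) -> float:
        return float(self.S[0, 0])

    @property
    def S_AB(self) -> float:
        return float(self.S[0, 1])

    @property
    def S_BA(self) -> float:
        return float(self.S[1, 0])

    @property
    def S_BB(self) -> float:
        return float(self.S[1, 1])


@dataclass
class ProportionEstimate:
    """A trait-proportion estimate with its bootstrap CI and provenance."""

    estimator: Literal["rds_i", "giles_ss", "sample_proportion"]
    trait: str
    p_hat: float
    ci: tuple[float, float] | None
    n: int
    bootstrap_reps: int = 0
    harmonic_degrees: tuple[float, float] | None = None
    reliable: bool = True
    converged: bool = True
    n_missing: int = 0
    notes: str = ""


# ---------------------------------------------------------------------------
# transition matrix & degrees
# ---------------------------------------------------------------------------

def transition_matrix(
    sample: RdsSample,
    trait: str,
    smoothing: Literal["none", "reciprocity"] = "none",
) -> TransitionMatrix:
    """Estimate recruitment transition proportions for a binary trait.

    ``smoothing="reciprocity"`` replaces the off-diagonal counts by their
    mean ``(t_AB + t_BA) / 2`` before normalising (a data-smoothed variant
    sometimes used to enforce tie reciprocity).
    """
    pairs = sample.recruitment_pairs(trait)
    if pairs.empty:
        raise EstimationError("no recruitment pairs with the trait observed on both ends")
    counts = np.zeros((2, 2), dtype=float)
    # row/col index 0 = group A (trait 1), 1 = group B (trait 0)
    for (rv, cv), k in pairs.value_counts().items():
        counts[1 - int(rv), 1 - int(cv)] = k
    if smoothing == "reciprocity":
        off = 0.5 * (counts[0, 1] + counts[1, 0])
        counts = counts.copy()
        counts[0, 1] = counts[1, 0] = off
    row_sums = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        S = counts / row_sums[:, None]
    undefined = tuple(g for g, s in zip("AB", row_sums) if s == 0)
    return TransitionMatrix(counts=counts, S=S, undefined_rows=undefined)


def harmonic_mean_degree(sample: RdsSample, trait: str, group: int) -> float:
    """Harmonic mean degree ``D_X = n_X / sum(1/d_i)`` of one trait group."""
    vals = sample.trait_values(trait)
    d = sample.degrees()[(vals == group).to_numpy()]
    if d.size == 0:
        raise EstimationError(f"group {group} is empty for trait {trait!r}")
    return float(d.size / np.sum(1.0 / d))


# ---------------------------------------------------------------------------
# RDS-I
# ---------------------------------------------------------------------------

def _rds_i_point(counts: np.ndarray, deg_A: np.ndarray, deg_B: np.ndarray) -> float:
    """Reciprocity-balance point estimate from counts and group degrees.

    Returns NaN when a needed transition row is undefined or no cross-group
    recruitment was observed; 1.0 / 0.0 when a group is absent.
    """
    if deg_B.size == 0:
        return 1.0
    if deg_A.size == 0:
        return 0.0
    row_A, row_B = counts[0].sum(), counts[1].sum()
    if row_A == 0 or row_B == 0:
        return float("nan")
    S_AB = counts[0, 1] / row_A
    S_BA = counts[1, 0] / row_B
    D_A = deg_A.size / np.sum(1.0 / deg_A)
    D_B = deg_B.size / np.sum(1.0 / deg_B)
    denom = S_AB * D_A + S_BA * D_B
    if denom == 0:
        return float("nan")
    return float(S_BA * D_B / denom)


def rds_i_proportion(
    sample: RdsSample,
    trait: str,
    reps: int = 1000,
    level: float = 0.95,
    rng_seed: int = 0,
    smoothing: Literal["none", "reciprocity"] = "none",
    compute_ci: bool = True,
) -> ProportionEstimate:
    """Salganik–Heckathorn (RDS-I) proportion of trait group A (= value 1).

    Missing trait values are excluded listwise.  When a group is empty the
    degenerate proportion (0 or 1) is returned; when a transition row is
    undefined the estimate is flagged unreliable with ``p_hat = NaN``.
    """
    g, d, n_missing = sample.groups(trait)
    keep = g >= 0
    g, d = g[keep], d[keep]
    deg_A, deg_B = d[g == 1], d[g == 0]
    notes = []
    if n_missing:
        notes.append(f"{n_missing} respondents dropped for missing trait {trait!r}")

    if deg_A.size == 0 or deg_B.size == 0:
        p = 1.0 if deg_B.size == 0 else 0.0
        return ProportionEstimate(
            estimator="rds_i", trait=trait, p_hat=p, ci=(p, p), n=int(keep.sum()),
            n_missing=n_missing, notes="; ".join(notes + ["single-group sample"]),
        )

    tm = transition_matrix(sample, trait, smoothing=smoothing)
    p = _rds_i_point(tm.counts, deg_A, deg_B)
    D_A = deg_A.size / np.sum(1.0 / deg_A)
    D_B = deg_B.size / np.sum(1.0 / deg_B)
    reliable = np.isfinite(p)
    if not reliable:
        notes.append(
            "undefined transition structure (a group made no recruitment or no "
            "cross-group recruitment observed); estimate unreliable"
        )
        warnings.warn(notes[-1], UnreliableEstimateWarning, stacklevel=2)
    ci = None
    if compute_ci and reliable:
        ci = bootstrap_ci(sample, trait, estimator="rds_i", reps=reps, level=level,
                          rng_seed=rng_seed, smoothing=smoothing)
    return ProportionEstimate(
        estimator="rds_i", trait=trait, p_hat=float(p), ci=ci, n=int(keep.sum()),
        bootstrap_reps=reps if ci else 0, harmonic_degrees=(float(D_A), float(D_B)),
        reliable=bool(reliable), n_missing=n_missing, notes="; ".join(notes),
    )


# ---------------------------------------------------------------------------
# Gile's SS
# ---------------------------------------------------------------------------

def _ss_inclusion_probs(
    pop_degrees: np.ndarray,
    pop_counts: np.ndarray,
    n: int,
    sim_reps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate successive sampling to estimate inclusion probability per degree.

    The population has ``pop_counts[k]`` units of degree ``pop_degrees[k]``.
    Each replicate draws ``n`` units without replacement with probability
    proportional to degree (equivalently: keep the ``n`` smallest
    ``Exp(1)/degree`` keys).  Returns the estimated inclusion probability for
    each degree class, clipped away from 0.
    """
    unit_deg = np.repeat(pop_degrees.astype(float), pop_counts)
    N = unit_deg.size
    if n >= N:
        return np.ones_like(pop_degrees, dtype=float)
    hits = np.zeros(pop_degrees.size, dtype=float)
    # map each population unit to its degree-class index
    class_idx = np.repeat(np.arange(pop_degrees.size), pop_counts)
    for _ in range(sim_reps):
        keys = rng.exponential(size=N) / unit_deg
        sel = np.argpartition(keys, n)[:n]
        hits += np.bincount(class_idx[sel], minlength=pop_degrees.size)
    pi = hits / (sim_reps * pop_counts)
    return np.clip(pi, 0.5 / (sim_reps * pop_counts), 1.0)


def _ss_weights(
    degrees: np.ndarray,
    N: int,
    sim_reps: int,
    max_iter: int,
    tol: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, bool]:
    """Iterated successive-sampling weights ``1/pi(d_i)`` for sample degrees."""
    n = degrees.size
    uniq, inv = np.unique(degrees, return_inverse=True)
    sample_counts = np.bincount(inv, minlength=uniq.size)
    w = 1.0 / degrees
    prev_dist = None
    converged = False
    for _ in range(max_iter):
        class_w = np.bincount(inv, weights=w, minlength=uniq.size)
        pop_counts = largest_remainder_allocation(class_w, N, floor=sample_counts)
        dist = pop_counts / N
        if prev_dist is not None and np.max(np.abs(dist - prev_dist)) < tol:
            converged = True
            break
        prev_dist = dist
        pi = _ss_inclusion_probs(uniq, pop_counts, n, sim_reps, rng)
        w = 1.0 / pi[inv]
    return w, converged


def giles_ss_proportion(
    sample: RdsSample,
    trait: str,
    population_size: int,
    sim_reps: int = 200,
    max_iter: int = 8,
    tol: float = 5e-3,
    reps: int = 1000,
    level: float = 0.95,
    rng_seed: int = 0,
    compute_ci: bool = True,
) -> ProportionEstimate:
    """Gile's sequential-sampling (SS) proportion of trait group A.

    Models the RDS sample as a probability-proportional-to-degree draw of
    ``n`` units without replacement from a finite population of assumed size
    ``population_size``.  Inclusion probabilities per degree class are
    estimated by Monte Carlo (``sim_reps`` replicates) from a population
    degree distribution itself re-estimated from the current weights, and the
    two are iterated to a fixed point (max change in the estimated degree
    distribution below ``tol``).  The point estimate is the weighted (Hájek)
    proportion with weights ``1/pi(d_i)``.
    """
    g, d, n_missing = sample.groups(trait)
    keep = g >= 0
    g, d = g[keep], d[keep]
    n = int(keep.sum())
    if population_size <= n:
        raise EstimationError(f"population_size ({population_size}) must exceed the sample size ({n})")
    rng = rng_for(rng_seed, stream=7)
    w, converged = _ss_weights(d, population_size, sim_reps, max_iter, tol, rng)
    p = float(np.sum(w[g == 1]) / np.sum(w))
    notes = []
    if n_missing:
        notes.append(f"{n_missing} respondents dropped for missing trait {trait!r}")
    if not converged:
        notes.append("successive-sampling weight iteration hit max_iter without converging")
    ci = None
    if compute_ci:
        ci = bootstrap_ci(
            sample, trait, estimator="giles_ss", reps=reps, level=level,
            rng_seed=rng_seed, population_size=population_size,
            ss_sim_reps=max(25, sim_reps // 4),
        )
    return ProportionEstimate(
        estimator="giles_ss", trait=trait, p_hat=p, ci=ci, n=n,
        bootstrap_reps=reps if ci else 0, converged=converged,
        n_missing=n_missing, notes="; ".join(notes),
    )


# ---------------------------------------------------------------------------
# chain bootstrap
# ---------------------------------------------------------------------------

def _simulate_chains(
    S: np.ndarray, n: int, reps: int, rng: np.random.Generator
) -> np.ndarray:
    """Markov group chains (reps x n, values 1=A / 0=B) from transition probs."""
    g = np.empty((reps, n), dtype=np.int8)
    g[:, 0] = rng.integers(0, 2, size=reps)
    pA_given_A = S[0, 0] if np.isfinite(S[0, 0]) else 1.0
    pA_given_B = S[1, 0] if np.isfinite(S[1, 0]) else 0.0
    for t in range(1, n):
        u = rng.random(reps)
        prev = g[:, t - 1]
        thresh = np.where(prev == 1, pA_given_A, pA_given_B)
        g[:, t] = (u < thresh).astype(np.int8)
    return g


def _bootstrap_rds_i(
    groups: np.ndarray, degs: np.ndarray
) -> np.ndarray:
    """Vectorised RDS-I over bootstrap replicates (rows)."""
    prev, nxt = groups[:, :-1], groups[:, 1:]
    t_AA = ((prev == 1) & (nxt == 1)).sum(axis=1).astype(float)
    t_AB = ((prev == 1) & (nxt == 0)).sum(axis=1).astype(float)
    t_BA = ((prev == 0) & (nxt == 1)).sum(axis=1).astype(float)
    t_BB = ((prev == 0) & (nxt == 0)).sum(axis=1).astype(float)
    n_A = (groups == 1).sum(axis=1)
    n_B = (groups == 0).sum(axis=1)
    inv_d = 1.0 / degs
    invsum_A = np.where(groups == 1, inv_d, 0.0).sum(axis=1)
    invsum_B = np.where(groups == 0, inv_d, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        S_AB = t_AB / (t_AA + t_AB)
        S_BA = t_BA / (t_BA + t_BB)
        D_A = n_A / invsum_A
        D_B = n_B / invsum_B
        p = S_BA * D_B / (S_AB * D_A + S_BA * D_B)
    p = np.where(n_B == 0, 1.0, p)
    p = np.where(n_A == 0, 0.0, p)
    return p


def bootstrap_ci(
    sample: RdsSample,
    trait: str,
    estimator: Literal["rds_i", "giles_ss", "sample_proportion"] = "rds_i",
    reps: int = 1000,
    level: float = 0.95,
    rng_seed: int = 0,
    population_size: int | None = None,
    smoothing: Literal["none", "reciprocity"] = "none",
    ss_sim_reps: int = 50,
    max_failure_frac: float = 0.2,
) -> tuple[float, float]:
    """Chain-structured (Salganik) bootstrap percentile CI for a proportion.

    Each replicate regrows one pseudo-chain of length ``n``: the seed group is
    drawn uniformly from {A, B}, each subsequent group from the observed
    transition matrix, and each member's degree is resampled with replacement
    from the empirical pool of its group (seeds included in the pools).  The
    chosen estimator is applied to every replicate and the percentile interval
    at ``level`` returned.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100 for a stable percentile interval")
    g, d, _ = sample.groups(trait)
    keep = g >= 0
    g, d = g[keep], d[keep]
    n = g.size
    pool_A, pool_B = d[g == 1], d[g == 0]
    if pool_A.size == 0 or pool_B.size == 0:
        p = 1.0 if pool_B.size == 0 else 0.0
        return (p, p)
    tm = transition_matrix(sample, trait, smoothing=smoothing)
    rng = rng_for(rng_seed, stream=11)

    chains = _simulate_chains(tm.S, n, reps, rng)
    idx_A = rng.integers(0, pool_A.size, size=chains.shape)
    idx_B = rng.integers(0, pool_B.size, size=chains.shape)
    degs = np.where(chains == 1, pool_A[idx_A], pool_B[idx_B]).astype(float)

    if estimator == "rds_i":
        stats = _bootstrap_rds_i(chains, degs)
    elif estimator == "sample_proportion":
        stats = chains.mean(axis=1)
    elif estimator == "giles_ss":
        if population_size is None:
            raise ValueError("population_size required for the giles_ss bootstrap")
        stats = np.empty(reps)
        for r in range(reps):
            w, _ = _ss_weights(degs[r], population_size, ss_sim_reps, 4, 5e-3, rng)
            stats[r] = np.sum(w[chains[r] == 1]) / np.sum(w)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")

    valid = stats[np.isfinite(stats)]
    fail_frac = 1.0 - valid.size / reps
    if fail_frac > max_failure_frac:
        warnings.warn(
            f"estimator failed in {fail_frac:.0%} of bootstrap replicates; CI unreliable",
            UnreliableEstimateWarning, stacklevel=2,
        )
    if valid.size == 0:
        raise EstimationError("estimator failed in every bootstrap replicate")
    alpha = 1.0 - level
    lo, hi = np.quantile(valid, [alpha / 2, 1 - alpha / 2])
    return (float(lo), float(hi))


# ---------------------------------------------------------------------------
# auxiliary estimators (test oracles / diagnostics support)
# ---------------------------------------------------------------------------

def sample_proportion(sample: RdsSample, trait: str) -> float:
    """Crude (unweighted) proportion of trait group A, missing excluded."""
    vals = sample.trait_values(trait).dropna()
    if vals.empty:
        raise EstimationError("no observed trait values")
    return float((vals == 1).mean())


def hajek_proportion(sample: RdsSample, trait: str) -> float:
    """Degree-weighted (Volz–Heckathorn style) proportion: weights 1/d."""
    g, d, _ = sample.groups(trait)
    keep = g >= 0
    g, d = g[keep], d[keep]
    w = 1.0 / d
    return float(np.sum(w[g == 1]) / np.sum(w))
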