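"""Diagnostic battery: homophily, convergence, bottlenecks, selection, tests."""

import numpy as np
import pandas as pd
import pytest
import warnings
from hypothesis import given, settings
from hypothesis import strategies as st

from appmultiplier import (
    DiagnosticsReport,
    EstimationError,
    PopulationSpec,
    RdsSample,
    bottleneck_series,
    compare_groups,
    convergence_check,
    diagnose,
    generate_network,
    homophily,
    select_estimator,
    sensitivity_check,
    simulate_rds,
)


def pair_sample(pairs):
    """Build a sample realising the given (recruiter_group, recruit_group) pairs."""
    rows = []
    next_id = 0
    # enough seeds of each group to recruit without coupon concerns
    seeds = {1: [], 0: []}
    for g in (1, 0):
        for _ in range(max(1, sum(1 for rg, _ in pairs if rg == g))):
            rows.append((next_id, None, next_id, len(rows), 3, g))
            seeds[g].append(next_id)
            next_id += 1
    use_count = {1: 0, 0: 0}
    for rg, cg in pairs:
        recruiter = seeds[rg][use_count[rg] % len(seeds[rg])]
        use_count[rg] += 1
        rows.append((next_id, recruiter, recruiter, len(rows), 3, cg))
        next_id += 1
    df = pd.DataFrame(rows, columns=["id", "recruiter_id", "seed_id", "order", "degree", "app_30d"])
    return RdsSample(df)


class TestHomophily:
    def test_perfect_assortativity_above_one(self):
        s = pair_sample([(1, 1)] * 4 + [(0, 0)] * 4)
        assert homophily(s, "app_30d") > 1

    def test_random_mixing_near_one(self, baseline_study):
        _, sample = baseline_study
        assert abs(homophily(sample, "app_30d") - 1) < 0.1

    def test_hand_computed_fixture(self):
        # pairs: (A->A)x4, (A->B)x1, (B->B)x1, (B->A)x4
        s = pair_sample([(1, 1)] * 4 + [(1, 0)] + [(0, 0)] + [(0, 1)] * 4)
        # brute force: observed same = 5; recruit pool share of A = 8/10;
        # expected = 5*0.8 (A recruiters) + 5*0.2 (B recruiters) = 5
        assert homophily(s, "app_30d") == pytest.approx(5 / 5)

    def test_no_pairs_rejected(self):
        df = pd.DataFrame(
            [(1, None, 1, 0, 2, 1)],
            columns=["id", "recruiter_id", "seed_id", "order", "degree", "app_30d"],
        )
        with pytest.raises(EstimationError):
            homophily(RdsSample(df), "app_30d")

    def test_permutation_null_centred_at_one(self, baseline_study):
        """Shuffling recruits uniformly across recruiters gives mean ~ 1."""
        _, sample = baseline_study
        df = sample.data.reset_index(drop=True)
        rng = np.random.default_rng(0)
        ids = df["id"].to_numpy()
        vals = []
        for _ in range(200):
            shuffled = df.copy()
            # each non-seed gets a recruiter drawn uniformly among earlier respondents
            ks = np.arange(len(df))
            pick = rng.integers(0, np.maximum(ks, 1))
            new_rec = ids[pick].astype(float)
            is_seed = df["recruiter_id"].isna().to_numpy()
            shuffled["recruiter_id"] = np.where(is_seed, np.nan, new_rec)
            vals.append(homophily(RdsSample(shuffled, validate=False), "app_30d"))
        assert abs(np.mean(vals) - 1) < 0.05


class TestConvergence:
    def test_constant_series_converges(self):
        s = pair_sample([(1, 1)] * 30 + [(0, 0)] * 0)
        # all group A after the B seed: use crude proportion on a long constant tail
        conv, series = convergence_check(s, "app_30d", estimator="sample_proportion", min_n=5)
        assert conv

    def test_final_jump_fails(self):
        # mostly A, then a late run of B creating a > 0.02 shift in the window
        pairs = [(1, 1)] * 60 + [(0, 0)] * 20
        s = pair_sample(pairs)
        conv, _ = convergence_check(s, "app_30d", estimator="sample_proportion", min_n=5)
        assert not conv

    def test_tolerance_extremes(self, baseline_study):
        _, sample = baseline_study
        conv_loose, series = convergence_check(sample, "app_30d", tol=1.0)
        assert conv_loose
        ests = [e for _, e in series]
        conv_zero, _ = convergence_check(sample, "app_30d", tol=0.0)
        w = int(np.ceil(0.25 * len(ests)))
        assert conv_zero == (len(set(ests[-w:])) == 1)

    def test_homophily_reduces_convergence_rate(self):
        """Two seeds in opposite groups: strong homophily destabilises the
        cumulative estimate relative to random mixing (paired experiment)."""
        rates = {}
        for w in (1.0, 6.0):
            conv = 0
            for s in range(30):
                spec = PopulationSpec(
                    N=10_000, sample_target=400, seed_count=2,
                    homophily_w=w, seed_bias=0.5, rng_seed=5000 + s,
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    sample = simulate_rds(generate_network(spec), spec)
                c, _ = convergence_check(sample, "app_30d", estimator="sample_proportion")
                conv += c
            rates[w] = conv
        assert rates[6.0] < rates[1.0]


class TestBottleneck:
    def test_identical_subtrees_zero_gap(self):
        rows = [
            (1, None, 1, 0, 3, 1), (2, None, 2, 1, 3, 1),
            (3, 1, 1, 2, 3, 0), (4, 2, 2, 3, 3, 0),
            (5, 1, 1, 4, 3, 1), (6, 2, 2, 5, 3, 1),
        ]
        df = pd.DataFrame(rows, columns=["id", "recruiter_id", "seed_id", "order", "degree", "app_30d"])
        _, gap = bottleneck_series(RdsSample(df), "app_30d")
        assert gap == pytest.approx(0.0)

    def test_pure_opposite_subtrees_gap_one(self):
        rows = [
            (1, None, 1, 0, 3, 1), (2, None, 2, 1, 3, 0),
            (3, 1, 1, 2, 3, 1), (4, 1, 1, 3, 3, 1),
            (5, 2, 2, 4, 3, 0), (6, 2, 2, 5, 3, 0),
        ]
        df = pd.DataFrame(rows, columns=["id", "recruiter_id", "seed_id", "order", "degree", "app_30d"])
        _, gap = bottleneck_series(RdsSample(df), "app_30d")
        assert gap == pytest.approx(1.0)

    def test_single_seed_gap_undefined(self):
        rows = [(1, None, 1, 0, 3, 1), (2, 1, 1, 1, 3, 0), (3, 1, 1, 2, 3, 1)]
        df = pd.DataFrame(rows, columns=["id", "recruiter_id", "seed_id", "order", "degree", "app_30d"])
        series, gap = bottleneck_series(RdsSample(df), "app_30d")
        assert gap is None
        assert len(series) == 1

    def test_homophily_widens_gap(self):
        gaps = {}
        for w in (1.0, 8.0):
            spec = PopulationSpec(
                N=2000, sample_target=200, seed_count=2,
                homophily_w=w, seed_bias=0.5, rng_seed=42,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sample = simulate_rds(generate_network(spec), spec)
            _, gaps[w] = bottleneck_series(sample, "app_30d")
        assert gaps[8.0] > gaps[1.0]


class TestSensitivity:
    @pytest.mark.parametrize(
        "p,expected", [(0.35, True), (0.15, False), (0.2, True), (0.8, True), (0.81, False)]
    )
    def test_band(self, p, expected):
        assert sensitivity_check(p) is expected

    @given(
        p=st.floats(0, 1), low=st.floats(0, 0.5), widen=st.floats(0, 0.5)
    )
    @settings(max_examples=100, deadline=None)
    def test_widening_band_is_monotone(self, p, low, widen):
        high = 1 - low
        if low > high:
            return
        inner = sensitivity_check(p, low, high)
        outer = sensitivity_check(p, max(low - widen, 0), min(high + widen, 1))
        assert not (inner and not outer)


class TestSelectEstimator:
    @staticmethod
    def reports(n_hom_lt1, n_not_conv, n_total=12):
        out = []
        for i in range(n_total):
            out.append(
                DiagnosticsReport(
                    homophily_value=0.8 if i < n_hom_lt1 else 1.2,
                    converged=not (n_hom_lt1 <= i < n_hom_lt1 + n_not_conv),
                )
            )
        return out

    def test_more_homophilous_than_nonconverged_gives_rds_i(self):
        res = select_estimator(self.reports(4, 2))
        assert res.estimator == "rds_i"
        assert res.n_homophily_lt1 == 4 and res.n_not_converged == 2
        assert "4" in res.rationale and "2" in res.rationale

    def test_tie_goes_to_giles_ss(self):
        res = select_estimator(self.reports(0, 0))
        assert res.estimator == "giles_ss"
        assert "tie" in res.rationale

    def test_more_nonconverged_gives_giles_ss(self):
        assert select_estimator(self.reports(1, 3)).estimator == "giles_ss"


class TestCompareGroups:
    def test_identical_means_t_zero(self):
        rows = []
        for i, (g, age) in enumerate([(1, 20), (1, 30), (0, 20), (0, 30)]):
            rows.append((i, None, i, i, 3, g, age))
        df = pd.DataFrame(rows, columns=["id", "recruiter_id", "seed_id", "order", "degree", "app_30d", "age"])
        res = compare_groups(RdsSample(df), "app_30d", "age")
        assert res.test == "t"
        assert res.statistic == pytest.approx(0.0)
        assert res.df == 2

    def test_identical_proportions_chi2_zero(self):
        rows = []
        i = 0
        for g in (0, 1):
            for y in (0, 0, 1, 1):
                rows.append((i, None, i, i, 3, g, y))
                i += 1
        df = pd.DataFrame(rows, columns=["id", "recruiter_id", "seed_id", "order", "degree", "app_30d", "sex_12m"])
        res = compare_groups(RdsSample(df), "app_30d", "sex_12m")
        assert res.test == "chi2"
        assert res.statistic == pytest.approx(0.0)

    def test_chi2_matches_hand_computation(self):
        # 2x2 table: group1 -> (30 yes, 70 no); group0 -> (60 yes, 40 no)
        rows = []
        i = 0
        for g, yes, no in [(1, 30, 70), (0, 60, 40)]:
            for y, k in [(1, yes), (0, no)]:
                for _ in range(k):
                    rows.append((i, None, i, i, 3, g, y))
                    i += 1
        df = pd.DataFrame(rows, columns=["id", "recruiter_id", "seed_id", "order", "degree", "app_30d", "sex_12m"])
        res = compare_groups(RdsSample(df), "app_30d", "sex_12m")
        # hand: sum (O-E)^2/E with E from the margins
        obs = np.array([[30, 70], [60, 40]])
        row, col, n = obs.sum(1), obs.sum(0), obs.sum()
        exp = np.outer(row, col) / n
        chi2_hand = ((obs - exp) ** 2 / exp).sum()
        assert res.statistic == pytest.approx(chi2_hand)
        assert res.df == 1

    def test_zero_variance_rejected(self):
        rows = [(i, None, i, i, 3, g, 25) for i, g in enumerate([1, 1, 0, 0])]
        df = pd.DataFrame(rows, columns=["id", "recruiter_id", "seed_id", "order", "degree", "app_30d", "age"])
        with pytest.raises(EstimationError):
            compare_groups(RdsSample(df), "app_30d", "age")


def test_diagnose_bundles_battery(baseline_study):
    _, sample = baseline_study
    report = diagnose(sample, "app_30d", province="Sim")
    assert report.homophily_value > 0
    assert isinstance(report.converged, bool)
    assert report.bottleneck_gap is not None
    assert report.sensitive is not None
    assert report.convergence_series[-1][0] == sample.n
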