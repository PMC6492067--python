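"""RDS estimators: transition matrix, RDS-I, Gile's SS, chain bootstrap."""

import numpy as np
import pandas as pd
import pytest

from appmultiplier import (
    EstimationError,
    PopulationSpec,
    RdsSample,
    bootstrap_ci,
    generate_network,
    giles_ss_proportion,
    harmonic_mean_degree,
    rds_i_proportion,
    simulate_rds,
    transition_matrix,
)
from appmultiplier.rds import hajek_proportion, sample_proportion


def make_sample(rows, trait="app_30d"):
    df = pd.DataFrame(rows, columns=["id", "recruiter_id", "seed_id", "order", "degree", trait])
    return RdsSample(df)


class TestTransitionMatrix:
    def test_pure_homophily_rows(self):
        rows = [
            (1, None, 1, 0, 2, 1), (2, None, 2, 1, 2, 0),
            (3, 1, 1, 2, 2, 1), (4, 2, 2, 3, 2, 0),
        ]
        tm = transition_matrix(make_sample(rows), "app_30d")
        assert tm.S_AA == 1.0 and tm.S_BB == 1.0

    def test_counts_ratio(self, twelve_respondent_sample):
        tm = transition_matrix(twelve_respondent_sample, "app_30d")
        # transitions by construction: A->A 3, A->B 2, B->A 2, B->B 3
        assert tm.counts.tolist() == [[3, 2], [2, 3]]
        assert tm.S_AB == pytest.approx(0.4)
        assert tm.S_BA == pytest.approx(0.4)

    def test_cross_rate_matches_group_share_under_random_mixing(self, baseline_study):
        _, sample = baseline_study
        tm = transition_matrix(sample, "app_30d")
        # S_AB ~ prevalence of B (0.65) within sampling error
        assert abs(tm.S_AB - 0.65) < 0.08

    def test_undefined_row_flagged(self):
        rows = [(1, None, 1, 0, 2, 1), (2, 1, 1, 1, 2, 0)]  # B never recruits
        tm = transition_matrix(make_sample(rows), "app_30d")
        assert tm.undefined_rows == ("B",)
        assert np.isnan(tm.S_BA)


class TestHarmonicMeanDegree:
    def test_constant_degrees(self):
        rows = [(i, None, i, i, 2, 1) for i in range(3)]
        assert harmonic_mean_degree(make_sample(rows), "app_30d", 1) == pytest.approx(2.0)

    def test_direct_formula(self):
        rows = [(0, None, 0, 0, 1, 1), (1, None, 1, 1, 4, 1)]
        assert harmonic_mean_degree(make_sample(rows), "app_30d", 1) == pytest.approx(1.6)

    def test_at_most_arithmetic_mean(self, baseline_study):
        _, sample = baseline_study
        for grp in (0, 1):
            d = sample.data.loc[sample.data["app_30d"] == grp, "degree"]
            assert harmonic_mean_degree(sample, "app_30d", grp) <= d.mean() + 1e-12

    def test_empty_group_rejected(self):
        rows = [(0, None, 0, 0, 2, 1)]
        with pytest.raises(EstimationError):
            harmonic_mean_degree(make_sample(rows), "app_30d", 0)


class TestRdsI:
    def test_single_group_degenerate(self):
        rows = [(1, None, 1, 0, 2, 1), (2, 1, 1, 1, 3, 1), (3, 1, 1, 2, 4, 1)]
        est = rds_i_proportion(make_sample(rows), "app_30d", compute_ci=False)
        assert est.p_hat == 1.0

    def test_symmetry_gives_half(self):
        # S_AB = S_BA and equal degree distributions -> 0.5
        rows = [
            (1, None, 1, 0, 3, 1), (2, None, 2, 1, 3, 0),
            (3, 1, 1, 2, 3, 0), (4, 2, 2, 3, 3, 1),
            (5, 3, 1, 4, 3, 0), (6, 4, 2, 5, 3, 1),
        ]
        est = rds_i_proportion(make_sample(rows), "app_30d", compute_ci=False)
        assert est.p_hat == pytest.approx(0.5)

    def test_hand_evaluated_fixture(self, twelve_respondent_sample):
        """Point estimate equals an independent hand evaluation of the
        reciprocity formula from the fixture's counts and degrees."""
        # hand oracle, straight from the fixture table:
        t_AA, t_AB, t_BA, t_BB = 3, 2, 2, 3
        S_AB = t_AB / (t_AA + t_AB)
        S_BA = t_BA / (t_BA + t_BB)
        deg_A = [2, 3, 2, 3, 8, 6]
        deg_B = [4, 6, 5, 2, 5, 4]
        D_A = len(deg_A) / sum(1 / d for d in deg_A)
        D_B = len(deg_B) / sum(1 / d for d in deg_B)
        expected = S_BA * D_B / (S_AB * D_A + S_BA * D_B)
        est = rds_i_proportion(twelve_respondent_sample, "app_30d", compute_ci=False)
        assert est.p_hat == pytest.approx(expected)
        assert est.p_hat == pytest.approx(5 / 9)  # exact closed form of the fixture

    def test_degree_scale_invariance(self, twelve_respondent_sample):
        df = twelve_respondent_sample.data.copy()
        df["degree"] *= 7
        scaled = rds_i_proportion(RdsSample(df), "app_30d", compute_ci=False)
        base = rds_i_proportion(twelve_respondent_sample, "app_30d", compute_ci=False)
        assert scaled.p_hat == pytest.approx(base.p_hat)

    def test_complement_sums_to_one(self, twelve_respondent_sample):
        df = twelve_respondent_sample.data.copy()
        df["not_app"] = 1 - df["app_30d"]
        s = RdsSample(df)
        p_A = rds_i_proportion(s, "app_30d", compute_ci=False).p_hat
        p_B = rds_i_proportion(s, "not_app", compute_ci=False).p_hat
        assert p_A + p_B == pytest.approx(1.0)

    def test_unreliable_when_a_group_never_recruits(self):
        rows = [
            (1, None, 1, 0, 2, 1), (2, None, 2, 1, 2, 0),
            (3, 1, 1, 2, 2, 0), (4, 1, 1, 3, 2, 1),
        ]
        with pytest.warns(UserWarning):
            est = rds_i_proportion(make_sample(rows), "app_30d", compute_ci=False)
        assert not est.reliable
        assert np.isnan(est.p_hat)


class TestGilesSS:
    def test_equal_degrees_gives_sample_proportion(self, twelve_respondent_sample):
        df = twelve_respondent_sample.data.copy()
        df["degree"] = 5
        s = RdsSample(df)
        est = giles_ss_proportion(s, "app_30d", population_size=500, sim_reps=50, compute_ci=False)
        assert est.p_hat == pytest.approx(sample_proportion(s, "app_30d"))

    def test_large_population_limit_is_hajek(self):
        spec = PopulationSpec(rng_seed=5, sample_target=200)
        sample = simulate_rds(generate_network(spec), spec)
        est = giles_ss_proportion(
            sample, "app_30d", population_size=10**6, sim_reps=40,
            compute_ci=False, rng_seed=2,
        )
        assert abs(est.p_hat - hajek_proportion(sample, "app_30d")) < 0.02

    def test_population_smaller_than_sample_rejected(self, twelve_respondent_sample):
        with pytest.raises(EstimationError):
            giles_ss_proportion(twelve_respondent_sample, "app_30d", population_size=10)

    def test_complement_sums_to_one(self, baseline_study):
        _, sample = baseline_study
        df = sample.data.copy()
        df["not_app"] = 1 - df["app_30d"]
        s = RdsSample(df)
        kw = dict(population_size=10_000, sim_reps=80, compute_ci=False, rng_seed=4)
        p_A = giles_ss_proportion(s, "app_30d", **kw).p_hat
        p_B = giles_ss_proportion(s, "not_app", **kw).p_hat
        assert p_A + p_B == pytest.approx(1.0)


class TestBootstrap:
    def test_single_group_collapses(self):
        rows = [(1, None, 1, 0, 2, 1), (2, 1, 1, 1, 3, 1), (3, 2, 1, 2, 4, 1)]
        assert bootstrap_ci(make_sample(rows), "app_30d", reps=100) == (1.0, 1.0)

    def test_deterministic_under_fixed_seed(self, twelve_respondent_sample):
        a = bootstrap_ci(twelve_respondent_sample, "app_30d", reps=1000, rng_seed=3)
        b = bootstrap_ci(twelve_respondent_sample, "app_30d", reps=1000, rng_seed=3)
        assert a == b
        c = bootstrap_ci(twelve_respondent_sample, "app_30d", reps=1000, rng_seed=4)
        assert a != c

    def test_too_few_reps_rejected(self, twelve_respondent_sample):
        with pytest.raises(ValueError):
            bootstrap_ci(twelve_respondent_sample, "app_30d", reps=50)

    def test_interval_brackets_estimate_on_simulated_data(self, baseline_study):
        _, sample = baseline_study
        est = rds_i_proportion(sample, "app_30d", reps=500, rng_seed=0)
        lo, hi = est.ci
        assert lo <= est.p_hat <= hi
        assert 0 <= lo < hi <= 1

    def test_giles_ss_bootstrap_runs(self, baseline_study):
        _, sample = baseline_study
        lo, hi = bootstrap_ci(
            sample, "app_30d", estimator="giles_ss", reps=100,
            population_size=10_000, rng_seed=1, ss_sim_reps=25,
        )
        assert 0 < lo < hi < 1


def test_missing_traits_excluded_listwise(baseline_study):
    _, sample = baseline_study
    df = sample.data.copy()
    df.loc[df.index[:20], "app_30d"] = np.nan
    s = RdsSample(df)
    est = rds_i_proportion(s, "app_30d", compute_ci=False)
    assert est.n == sample.n - 20
    assert est.n_missing == 20
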