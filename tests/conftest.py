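import pandas as pd
import pytest

from appmultiplier import PopulationSpec, RdsSample, generate_network, simulate_rds


@pytest.fixture(scope="session")
def twelve_respondent_sample() -> RdsSample:
    """Hand-auditable 12-respondent sample: 2 seeds, fixed degrees/links.

    Groups (app_30d): A = {1, 3, 5, 7, 10, 12}, B = {2, 4, 6, 8, 9, 11}.
    Transitions: A->A x3, A->B x2, B->A x2, B->B x3.
    """
    rows = [
        # id, recruiter, seed, order, degree, app_30d
        (1, None, 1, 0, 2, 1),
        (2, None, 2, 1, 4, 0),
        (3, 1, 1, 2, 3, 1),
        (4, 1, 1, 3, 6, 0),
        (5, 1, 1, 4, 2, 1),
        (6, 2, 2, 5, 5, 0),
        (7, 2, 2, 6, 3, 1),
        (8, 3, 1, 7, 4, 0),
        (9, 4, 1, 8, 2, 0),
        (10, 4, 1, 9, 8, 1),
        (11, 6, 2, 10, 5, 0),
        (12, 7, 2, 11, 6, 1),
    ]
    df = pd.DataFrame(
        rows, columns=["id", "recruiter_id", "seed_id", "order", "degree", "app_30d"]
    )
    return RdsSample(df)


@pytest.fixture(scope="session")
def baseline_spec() -> PopulationSpec:
    """The default study conditions used across recovery experiments."""
    return PopulationSpec(rng_seed=0)


@pytest.fixture(scope="session")
def baseline_study(baseline_spec):
    """One simulated network + RDS sample under the default conditions."""
    G = generate_network(baseline_spec)
    sample = simulate_rds(G, baseline_spec)
    return G, sample
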