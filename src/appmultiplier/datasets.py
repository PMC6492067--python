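"""Published provincial tables from a 12-province social-app multiplier
study of MSM population size in Vietnam.

These are the printed per-province inputs and results of that study (RDS survey composition; app-user counts,
RDS-I proportions and population estimates for the 11 provinces with
reliable estimates).  They serve as fixed inputs for consistency checks and
worked examples — the study's raw data were never deposited.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "load_survey_summary",
    "load_provincial_estimates",
    "SURVEY_SUMMARY_PUBLISHED_TOTALS",
    "PROVINCIAL_PUBLISHED_TOTALS",
    "NATIONAL_PUBLISHED",
]

# Per-province RDS survey composition (12 provinces).
# columns: province, participants, eligible, mean_age, mean_network_size,
#          eligible_by_preference_only, jackd_account, jackd_30d
_SURVEY_ROWS = [
    ("An Giang",  173, 167, 22,  8, 39,  33,  18),
    ("Bac Giang", 132, 125, 28, 46, 28,  77,  52),
    ("Binh Dinh", 134, 126, 27,  5, 26, 101,  43),
    ("Can Tho",   195, 167, 23,  6, 28,  37,  19),
    ("Da Nang",   193, 167, 24,  5, 17, 114,  80),
    ("Dak Lak",   123, 121, 24,  8, 52,  41,  21),
    ("Dong Nai",  238, 227, 25,  7, 15,  69,  17),
    ("Dong Thap", 217, 212, 24,  9, 61,  47,  33),
    ("Hanoi",     296, 264, 23, 13, 22, 209, 130),
    ("Hai Phong", 345, 279, 25, 10, 70, 155,  96),
    ("Nam Dinh",  132, 122, 25, 10, 21,  84,  65),
    ("Thanh Hoa", 244, 200, 25,  9, 34, 107,  67),
]

SURVEY_SUMMARY_PUBLISHED_TOTALS = {
    "participants": 2422,
    "eligible": 2177,
    "eligible_by_preference_only": 413,
    "jackd_account": 1074,
    "jackd_30d": 641,
    "mean_age": 24.3,
    "mean_network_size": 10.6,
}

# Provincial app-user counts, RDS-I proportions (30-day app use unless
# noted) and population estimates for the 11 provinces with reliable
# estimates.  count_source: manual dedup / provider figure / capture-
# recapture; trait: which app-use question fed the proportion.
_ESTIMATE_ROWS = [
    # province, count_30d, prop, p_lo, p_hi, pop, pop_lo, pop_hi, weighted_pct, count_source, trait
    ("Bac Giang",   360, 0.42, 0.28, 0.55,   864,   653,  1274, 0.23, "manual",            "30d"),
    ("Binh Dinh",   260, 0.35, 0.23, 0.47,   743,   559,  1108, 0.21, "manual",            "30d"),
    ("Can Tho",     713, 0.11, 0.03, 0.19,  6276,  3677, 21418, 1.22, "manual",            "30d"),
    ("Da Nang",    1713, 0.43, 0.28, 0.58,  3990,  2974,  6059, 1.70, "manual",            "30d"),
    ("Dak Lak",     279, 0.15, 0.07, 0.23,  1895,  1226,  4180, 0.46, "manual",            "30d"),
    ("Dong Nai",   1191, 0.15, 0.02, 0.28,  7759,  4216, 68370, 1.10, "capture_recapture", "ever"),
    ("Dong Thap",   303, 0.14, 0.06, 0.21,  2181,  1420,  4711, 0.48, "manual",            "30d"),
    ("Hanoi",     12848, 0.42, 0.32, 0.52, 30417, 24656, 39691, 1.81, "provider",          "30d"),
    ("Hai Phong",  1141, 0.34, 0.25, 0.43,  3336,  2645,  4515, 0.73, "manual",            "30d"),
    ("Nam Dinh",    446, 0.39, 0.26, 0.52,  1131,   850,  1687, 0.29, "manual",            "30d"),
    ("Thanh Hoa",   670, 0.22, 0.11, 0.33,  3017,  2032,  5846, 0.40, "provider",          "30d"),
]

PROVINCIAL_PUBLISHED_TOTALS = {
    "count_30d": 19_924,
    "pop_estimate": 61_609,
    "pop_ci_low": 44_909,
    "pop_ci_high": 158_860,
    "proportion": 0.37,
    "weighted_pct": 0.96,
}

NATIONAL_PUBLISHED = {
    "total": 178_000,
    "ci": (122_000, 512_000),
    "pct_adult_males": 0.68,
    "pct_ci": (0.46, 1.95),
}


def load_survey_summary() -> pd.DataFrame:
    """Per-province RDS survey participation and app-use summary (12 rows)."""
    return pd.DataFrame(
        _SURVEY_ROWS,
        columns=[
            "province", "participants", "eligible", "mean_age",
            "mean_network_size", "eligible_by_preference_only",
            "jackd_account", "jackd_30d",
        ],
    )


def load_provincial_estimates() -> pd.DataFrame:
    """Provincial counts, proportions and population estimates (11 rows)."""
    return pd.DataFrame(
        _ESTIMATE_ROWS,
        columns=[
            "province", "count_30d", "proportion", "prop_ci_low",
            "prop_ci_high", "pop_estimate", "pop_ci_low", "pop_ci_high",
            "weighted_pct", "count_source", "trait",
        ],
    )
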