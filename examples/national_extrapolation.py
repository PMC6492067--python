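"""Extrapolate observed provincial estimates to a synthetic national total.

Uses a small synthetic country (two regions, a mix of observed and
unobserved provinces, one pilot estimate) to show the age-weighted
percentage computation and region-wise extrapolation.  The age-band
populations here are synthetic stand-ins, not census figures.
"""

from appmultiplier import (
    AGE_BANDS,
    CountResult,
    ExtrapolationConfig,
    PilotEstimate,
    ProportionEstimate,
    ProvinceRecord,
    extrapolate_national,
    multiplier_estimate,
)

# app users skew young: most mass in the 20-34 bands
age_mix = dict(zip(AGE_BANDS, (0.10, 0.30, 0.25, 0.18, 0.10, 0.05, 0.02)))

def pops(scale):
    shares = (0.16, 0.16, 0.15, 0.15, 0.14, 0.13, 0.11)
    return {b: scale * s for b, s in zip(AGE_BANDS, shares)}

config = ExtrapolationConfig(
    provinces=[
        ProvinceRecord("Delta City", "Delta", pops(900_000), observed=True),
        ProvinceRecord("Delta Rural", "Delta", pops(400_000)),
        ProvinceRecord("Highlands A", "Highlands", pops(300_000), observed=True),
        ProvinceRecord("Highlands B", "Highlands", pops(250_000)),
    ],
    app_age_distribution=age_mix,
    pilot_estimates=[PilotEstimate("Pilot Metro", 12_000, ci=(8_000, 20_000))],
)

observed = [
    multiplier_estimate(
        CountResult(4200, "provider"),
        ProportionEstimate("rds_i", "app_30d", 0.40, (0.30, 0.50), 300),
        province="Delta City",
    ),
    multiplier_estimate(
        CountResult(600, "dedup"),
        ProportionEstimate("rds_i", "app_30d", 0.25, (0.15, 0.35), 200),
        province="Highlands A",
    ),
]

national = extrapolate_national(observed, config)
for name, value in national.per_province.items():
    print(f"{name:12s} {national.provenance[name]:13s} {value:10.0f}")
print()
print(f"national total: {national.total:,.0f}  "
      f"(95% CI {national.ci[0]:,.0f}-{national.ci[1]:,.0f})")
print(f"as % of adult males 15-49: {national.pct_adult_males:.2f}% "
      f"(CI {national.pct_ci[0]:.2f}-{national.pct_ci[1]:.2f}%)")
print()
print("Unobserved provinces get their region's population-weighted mean")
print("percentage; CI bounds are propagated province-wise and summed.")
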