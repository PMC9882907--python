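"""Fit a waiting-time distribution to categorical survey responses.

Care surveys report waiting times in ordered bins ("less than 1
month", "1-3 months", ..., "2 years or longer").  This example
generates a synthetic survey of 646 respondents whose true waiting
times follow a gamma with mean 180 d (shape 2), bins the responses
into the seven standard categories, and recovers the continuous
distribution by the expand-then-fit procedure.
"""

from mndpath import (
    StepSpec,
    SyntheticSurveySpec,
    fit_survey_table,
    generate_survey,
)

true = StepSpec("true", mean=180.0, sd=127.3)  # gamma shape 2, scale 90
spec = SyntheticSurveySpec(true_step=true, n_respondents=646, nonresponse_rate=0.08)
table = generate_survey(spec, seed=3)

print(f"usable responses: {table.total_count}  (excluded: {table.excluded_count})")
for cat in table.categories:
    upper = "open" if cat.upper is None else f"{cat.upper:6.1f}"
    print(f"  [{cat.lower:6.1f}, {upper:>6s}) days : {cat.count:3d}")

fitted = fit_survey_table(table, rng=0)
print(f"\ntrue   mean {true.mean:.0f} d, shape {true.shape:.2f}")
print(f"fitted mean {fitted.mean:.0f} d, shape {fitted.shape:.2f}")
print("\nThe fit resamples within each bin from the current gamma iterate,")
print("so the recovered moments are close to the interval-censored MLE")
print("rather than inheriting the upward bias of midpoint/uniform filling.")
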