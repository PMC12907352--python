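"""Latent-class-stratified intervention response analysis.

Generates a large synthetic ASD cohort with class-graded responder
probabilities (0.68 / 0.42 / 0.19), applies the >=20% ADOS-2 reduction rule,
reports per-class response rates, and fits the age-adjusted logistic model
for the odds of response by class (low-interaction class as reference).
"""

import numpy as np

import playseq as ps
from playseq.cohort import generate_outcomes

rng = np.random.default_rng(4)
classes = np.repeat([0, 1, 2], [105, 120, 75])  # high / medium / low, n=300
out = generate_outcomes(classes, [0.68, 0.42, 0.19], rng)
out["child_id"] = [f"c{i}" for i in range(len(out))]

flags = ps.response_flags(out, threshold=0.20)
names = np.array(["high", "medium", "low"])[classes]
rates = ps.response_rates(names, flags)
print("response rates by latent class (responders/total -> %):")
for cls in ("high", "medium", "low"):
    r, t = rates.counts[cls]
    print(f"  {cls:7s} {r}/{t} -> {rates.rates[cls]}%")

age = rng.uniform(36, 96, len(out))
fit = ps.logistic_fit(flags, names, age, reference="low")
print("\nage-adjusted odds ratios vs the low-interaction class:")
for key in ("class[high]", "class[medium]"):
    lo, hi = fit.or_conf_int.loc[key]
    print(f"  {key}: OR = {fit.odds_ratios[key]:.2f} (95% CI {lo:.2f}-{hi:.2f})")
print("OR > 1 means better odds of a >=20% ADOS-2 reduction than the reference class.")
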