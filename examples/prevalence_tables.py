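"""Wald prevalence estimates: from printed counts and from a simulated survey.

A (count, denominator) pair fully determines the percent estimate and its
95% Wald interval, so published table rows can be recomputed exactly; on a
simulated survey the same operation respects missingness and subgroups.
"""

from violence_survey import (
    default_config,
    estimate_prevalence,
    generate_dataset,
    prevalence_table,
)

print("from printed counts (percent, 95% Wald CI):")
for label, count, denom in [
    ("verbal conflict", 967, 3818),
    ("physical conflict", 118, 3818),
    ("child corporal punishment", 97, 1474),
]:
    print(f"  {label:<26s} {estimate_prevalence(count, denom).format()}")

df = generate_dataset(default_config(seed=3))
print("\ndirect elicitation on a simulated survey (reported, i.e. after suppression):")
for est in prevalence_table(df, ["direct_verbal_conflict", "direct_physical_conflict",
                                 "direct_corporal_punishment"]):
    name = est.name.removeprefix("direct_")
    print(f"  {name:<26s} {est.count:>4d}/{est.denominator}  {est.format()}")
print("the corporal-punishment denominator is the child subsample, not all 3818")
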