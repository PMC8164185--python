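"""Double list experiment: estimate a stigmatized prevalence without asking it.

Simulates a survey whose latent non-consensual-sex prevalence is 3.57%, runs
the double-list difference-in-means estimator, and compares the double and
single designs' precision by Monte Carlo.
"""

from violence_survey import (
    default_config,
    double_list_estimate,
    generate_dataset,
    power_simulation,
)

df = generate_dataset(default_config(seed=11))
est = double_list_estimate(df, "sexual_violence")
print(f"sexual violence, double list estimate: {est.format()}")
print(f"  per-list single estimates: {est.per_list_estimates[0]:.2f}, "
      f"{est.per_list_estimates[1]:.2f} (their average is the double estimate)")
print(f"  arms A/B: {est.n_arm_a}/{est.n_arm_b}; SE {est.se:.2f} points")
print("  a negative lower bound is expected: item-count estimates are noisy\n")

res = power_simulation(0.0357, n=3818, reps=300, seed=4)
print("design comparison at n=3818, truth 3.57% (300 Monte-Carlo surveys):")
for design in ("double", "single"):
    d = res[design]
    print(f"  {design:<7s} empirical SE {d['empirical_se']:.2f} points, "
          f"mean CI width {d['mean_ci_width']:.2f}")
print("answering both lists lets respondent-level noise difference out,")
print("so the double design is tighter at the same sample size")
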