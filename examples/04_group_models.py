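"""End-to-end group analysis on a small synthetic cohort.

Simulates a 30-subject cohort with the default SI-group shift on the
level-2 evolution rate, MAP-fits every subject per condition, extracts
trial-level trajectories, fits the eleven Bayesian mixed-effects
models, and prints the trajectory-model coefficients for the
contingency belief (mu2) together with convergence diagnostics.
"""

from escalearn import (
    CohortConfig,
    FitConfig,
    PriorSpec,
    SamplerConfig,
    TaskConfig,
    extract_trajectories,
    fit_cohort,
    fits_to_frame,
    run_all_models,
    simulate_cohort,
)

priors = PriorSpec()
data = simulate_cohort(TaskConfig(seed=3), CohortConfig(n_si=15, n_ctrl=15, seed=3))
fits = fit_cohort(data, priors, FitConfig(n_restarts=1, seed=3))
long_table = extract_trajectories(fits, data, priors)
params = fits_to_frame(fits)

summary = run_all_models(
    long_table, params, SamplerConfig(chains=4, warmup=500, keep=1000, seed=3)
)
mu2 = summary[summary["model"] == "mu2"]
print(mu2[["term", "mean", "l95", "u95", "rhat", "ess", "significant"]]
      .to_string(index=False, float_format=lambda v: f"{v:+.5f}"))
print(
    "\nReference levels: no SI history, avoidance trials. A positive Trial\n"
    "coefficient says contingency beliefs strengthen over the task; the\n"
    "Trial:SI interaction asks whether the SI group strengthens faster.\n"
    "Terms whose 95% credible interval excludes zero are flagged. Rhat near\n"
    "1 and large ESS indicate the chains mixed well."
)
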