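"""Validate the MAP inversion by self-consistent parameter recovery.

Simulates agents from the same generative model the fit assumes across
a grid of level-2 evolution rates, refits each agent, and reports
bias, RMSE and the rank correlation between generative and fitted
values.  omega2 recovers well at 120 trials; omega3 is weakly
identified at this task length (estimates sit at the prior mean), a
property of the design worth knowing before interpreting fits.
"""

from escalearn import FitConfig, recovery_experiment

report = recovery_experiment(
    {"omega2": [-4.0, -3.0, -2.0], "omega3": [-7.0, -6.0, -5.0]},
    n_per_cell=10,
    seed=7,
    fit_config=FitConfig(n_restarts=1, seed=7),
)

summary = report.drop_duplicates("parameter")[["parameter", "bias", "rmse", "rank_corr"]]
print(summary.to_string(index=False, float_format=lambda v: f"{v:+.3f}"))
print(
    "\nrank_corr is the Spearman correlation between generative and fitted\n"
    "values. Expect a clearly positive value for omega2 and a near-zero one\n"
    "for omega3: 120 binary trials carry almost no information about the\n"
    "level-3 evolution rate, so its MAP estimate is pinned to the prior."
)
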