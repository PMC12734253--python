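# escalearn

Hierarchical Gaussian Filter (HGF) modelling of escape/avoidance
go/no-go learning, built for computational-psychiatry analyses that
compare belief-updating dynamics between groups — here, undergraduates
with versus without a lifetime history of suicidal ideation (SI)
learning to terminate (escape) or prevent (avoidance) an aversive
sound.

The package covers the complete analysis path as a reusable,
seed-reproducible library:

1. **Synthetic task + cohort generator** — the 120-trial, four-cue
   negative-reinforcement design (active/passive escape,
   active/passive avoidance) with HGF learner agents and configurable
   group differences, so the pipeline runs without any data download.
2. **3-level binary HGF** — coupled Gaussian random walks inverted
   trial by trial into closed-form belief updates driven by
   precision-weighted prediction errors, plus the unit-square-sigmoid
   response model with inverse temperature β.
3. **MAP inversion** — per subject and condition, L-BFGS-B with
   jittered restarts under toolbox-default Gaussian priors.
4. **Trajectory extraction** — eight per-trial series (μ₂, μ₃, σ₂,
   σ₃, ε₂, ε₃, ψ₂, ψ₃) in an analysis-ready long table.
5. **Group inference** — eleven Bayesian Gaussian mixed-effects models
   (subject random intercepts) fitted by a collapsed conjugate Gibbs
   sampler, with split-Rhat/bulk-ESS diagnostics and
   credible-interval significance flags.

## The model in brief

    x₁⁽ᵗ⁾ ~ Bernoulli(s(x₂⁽ᵗ⁾))            s = logistic
    x₂⁽ᵗ⁾ ~ N(x₂⁽ᵗ⁻¹⁾, exp(κ·x₃⁽ᵗ⁾ + ω₂))
    x₃⁽ᵗ⁾ ~ N(x₃⁽ᵗ⁻¹⁾, exp(ω₃))

Level 2 is the log-odds *contingency belief* that "go" is the correct
action (uncertainty σ₂); level 3 is the *volatility belief* (how
changeable contingencies are; uncertainty σ₃). Filtering yields, per
trial, dynamic learning rates ψᵢ (ratios of precisions) and
precision-weighted prediction errors εᵢ = ψᵢ·δᵢ₋₁ — the learning
signals. Choices follow P(go) = μ̂₁^β / (μ̂₁^β + (1−μ̂₁)^β); κ is
fixed at 1. See `docs/methods.md` for the full treatment, numerical
conventions and known limitations.

## Worked example

```python
from escalearn import CohortConfig, TaskConfig, accuracy_by_type, simulate_cohort

data = simulate_cohort(TaskConfig(seed=1), CohortConfig(seed=1))
print(accuracy_by_type(data))
```

prints (group mean ± sd of per-subject percent-correct):

```
group trial_type  mean_pct  sd_pct  n
 NoSI     escape      77.5     9.7 62
 NoSI  avoidance      76.1     9.1 62
 ...
   SI     escape      80.0     8.6 58
   SI  avoidance      80.1     9.3 58
```

Escape accuracy in the high 70s matches the level observed in the
laboratory task the generator emulates. Fitting the cohort and running
the group models (`examples/04_group_models.py`, a 30-subject cohort)
prints the contingency-belief coefficient table:

```
        term     mean      l95      u95     rhat         ess  significant
   Intercept +0.00437 -0.02190 +0.03024 +1.00059 +3947.71436        False
       Trial -0.00013 -0.00037 +0.00011 +0.99964 +4000.00000        False
          SI -0.02566 -0.06074 +0.01085 +1.00068 +3789.63889        False
      Escape +0.00690 -0.01433 +0.02789 +1.00025 +3737.03890        False
    Trial:SI +0.00047 +0.00019 +0.00074 +1.00002 +4000.00000         True
Trial:Escape +0.00005 -0.00021 +0.00032 +1.00042 +3594.98232        False
   SI:Escape -0.02395 -0.04303 -0.00511 +0.99947 +4000.00000         True
```

The positive `Trial:SI` interaction — the SI group's contingency
beliefs strengthening faster across the task — is the qualitative
signature the default generator builds in via a +0.5 shift on the SI
group's ω₂. Each example script in `examples/` is a short narrative
of one capability:

| script | what it shows |
|---|---|
| `01_simulate_cohort.py` | task design, agent simulation, accuracy table |
| `02_filter_beliefs.py`  | belief/uncertainty/PE trajectories on a toy input |
| `03_parameter_recovery.py` | self-consistent MAP recovery; ω₃ weak identifiability |
| `04_group_models.py` | end-to-end cohort analysis with diagnostics |

A thin CLI wraps the same pipeline for shell use:

```bash
escalearn all --seed 1 --out results/       # simulate -> fit -> analyze
escalearn analyze --seed 1 --out results/ --strict   # nonzero exit on Rhat/ESS violation
```

Outputs (`trials.csv`, `params.csv`, `long_trajectories.csv`,
`summary.csv`, `report.md`) carry `#`-prefixed provenance headers
(config hash, master seed, version); reruns from the same master seed
are byte-identical.

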