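"""Synthetic escape/avoidance go/no-go task and HGF agent cohorts.

Emulates a negative-reinforcement learning task with two conditions:
escape trials start with an aversive sound that a correct response
terminates; avoidance trials start in silence that a correct response
maintains.  Four fractal cues each deterministically signal one
(condition, correct action) cell — active escape, passive escape,
active avoidance, passive avoidance — and contingencies never reverse
within a run (a reversal option exists but is off by default).

Agents are simulated HGF learners: per cue they track the belief that
"go" is the correct action and respond through the unit-square sigmoid
with inverse temperature beta.  Cohorts draw per-subject generative
parameters from a population, optionally shifting the means for the
SI-history group to build in group differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hgf import HGFParams, predict_step, unit_square_sigmoid, update_step

__all__ = [
    "TaskConfig",
    "CohortConfig",
    "DesignTrial",
    "TASK_TIMING",
    "TRIALS_COLUMNS",
    "make_task_schedule",
    "simulate_agent",
    "simulate_cohort",
    "accuracy_by_type",
]

#: stimulus timing carried as dataset metadata only (no reaction-time model)
TASK_TIMING = {
    "cue_s": 1.0,
    "response_window_s": 2.0,
    "aversive_feedback_s": 2.0,
    "silence_feedback_s": 0.75,
    "iti_s": 1.0,
}

TRIALS_COLUMNS = [
    "subject_id",
    "group",
    "trial",
    "condition",
    "cue_id",
    "correct_action",
    "choice",
    "correct",
    "u",
]

# cue -> (condition, correct_action): the four task cells
_CUE_MAP = {
    0: ("escape", "go"),
    1: ("escape", "nogo"),
    2: ("avoidance", "go"),
    3: ("avoidance", "nogo"),
}
_MAX_RUN = 4  # no more than 4 consecutive trials of the same cue


class ConfigError(ValueError):
    """Invalid task or cohort configuration."""


@dataclass(frozen=True)
class TaskConfig:
    n_trials: int = 120
    n_cues: int = 4
    balanced: bool = True
    reversal_trial: int | None = None  # off by default; contingencies stay fixed
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials <= 0:
            raise ConfigError(f"n_trials must be > 0, got {self.n_trials}")
        if self.n_cues != 4:
            raise ConfigError("the task design uses exactly 4 cues (one per cell)")
        if self.balanced and self.n_trials % self.n_cues:
            raise ConfigError(
                f"balanced design needs n_trials divisible by {self.n_cues}, got {self.n_trials}"
            )


@dataclass(frozen=True)
class DesignTrial:
    trial: int
    condition: str
    cue_id: int
    correct_action: str


@dataclass(frozen=True)
class CohortConfig:
    """Population the cohort's generative parameters are drawn from.

    Defaults give two groups (58 with SI history, 62 without), subject-level
    omega2 ~ Normal(-3, sd 0.5), omega3 fixed at -6, log beta ~ Normal(log
    0.65, sd 0.5), and an additive +0.5 shift on the SI group's omega2 mean so
    the trial-by-SI contingency-belief interaction emerges qualitatively.  The
    beta scale is calibrated so simulated escape-trial accuracy sits in the
    high-70s percent range observed in the task.
    """

    n_si: int = 58
    n_ctrl: int = 62
    parameter_population: dict = field(
        default_factory=lambda: {
            "omega2": (-3.0, 0.5),
            "omega3": (-6.0, 0.0),
            "log_beta": (float(np.log(0.65)), 0.5),
        }
    )
    group_effects: dict = field(default_factory=lambda: {"omega2": 0.5})
    input_coding: str = "go_correct"  # or "chosen_correct"
    cue_specific_beliefs: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_si < 0 or self.n_ctrl < 0:
            raise ConfigError("group sizes must be non-negative")
        for name, (_, sd) in self.parameter_population.items():
            if sd < 0:
                raise ConfigError(f"spread for {name} must be >= 0, got {sd}")
        unknown = set(self.group_effects) - set(self.parameter_population)
        if unknown:
            raise ConfigError(f"group_effects for unknown parameters: {sorted(unknown)}")
        if self.input_coding not in ("go_correct", "chosen_correct"):
            raise ConfigError(f"unknown input_coding {self.input_coding!r}")


def make_task_schedule(config: TaskConfig) -> list[DesignTrial]:
    """Constrained pseudo-random trial order, reproducible from the seed.

    Balanced designs assign n_trials/4 trials per cue; the shuffle never
    allows more than 4 consecutive trials of the same cue (sequential
    draw with restart on dead ends).
    """
    rng = np.random.default_rng(config.seed)
    counts = np.full(config.n_cues, config.n_trials // config.n_cues)
    counts[: config.n_trials % config.n_cues] += 1

    for _attempt in range(1000):
        left = counts.copy()
        order: list[int] = []
        run_cue, run_len = -1, 0
        dead = False
        for _ in range(config.n_trials):
            avail = np.flatnonzero(left > 0)
            if run_len >= _MAX_RUN:
                avail = avail[avail != run_cue]
            if len(avail) == 0:
                dead = True
                break
            cue = int(rng.choice(avail, p=left[avail] / left[avail].sum()))
            order.append(cue)
            left[cue] -= 1
            run_len = run_len + 1 if cue == run_cue else 1
            run_cue = cue
        if not dead:
            break
    else:  # pragma: no cover - vanishingly unlikely
        raise ConfigError("could not build a schedule satisfying the run constraint")

    schedule = []
    for t, cue in enumerate(order, start=1):
        cond, act = _CUE_MAP[cue]
        if config.reversal_trial is not None and t >= config.reversal_trial:
            act = "nogo" if act == "go" else "go"
        schedule.append(DesignTrial(trial=t, condition=cond, cue_id=cue, correct_action=act))
    return schedule


def simulate_agent(
    schedule: list[DesignTrial],
    params: HGFParams,
    seed: int,
    *,
    subject_id: str = "s000",
    group: str = "NoSI",
    input_coding: str = "go_correct",
    cue_specific_beliefs: bool = True,
) -> pd.DataFrame:
    """Simulate one HGF agent playing the scheduled task.

    On each trial the agent forms the level-1 prediction muhat1 for the
    current cue (independent belief state per cue by default — each cue
    consistently signals one action, so this is what lets accuracy rise
    above chance), chooses "go" with probability
    unit_square_sigmoid(muhat1, beta), observes the fully revealed
    correct action, and updates.  The recorded input column ``u`` is
    always 1 iff "go" is the correct action for the trial's cue; the
    agent's own update uses that coding or, with
    ``input_coding="chosen_correct"``, the trial's correctness.
    """
    if not schedule:
        raise ValueError("schedule must be non-empty")
    rng = np.random.default_rng(seed)
    states: dict[int, object] = {}
    shared_key = -1
    records = []
    for dt in schedule:
        key = dt.cue_id if cue_specific_beliefs else shared_key
        state = states.get(key, params.initial_state())
        pred = predict_step(state, params)
        p_go = unit_square_sigmoid(pred.muhat1, params.beta)
        choice = "go" if rng.random() < p_go else "nogo"
        correct = int(choice == dt.correct_action)
        u = int(dt.correct_action == "go")
        u_agent = u if input_coding == "go_correct" else correct
        try:
            states[key], _ = update_step(pred, u_agent, params, trial=dt.trial)
        except Exception as err:
            raise type(err)(f"subject {subject_id}, trial {dt.trial}: {err}") from None
        records.append(
            {
                "subject_id": subject_id,
                "group": group,
                "trial": dt.trial,
                "condition": dt.condition,
                "cue_id": dt.cue_id,
                "correct_action": dt.correct_action,
                "choice": choice,
                "correct": correct,
                "u": u,
            }
        )
    return pd.DataFrame.from_records(records, columns=TRIALS_COLUMNS)


def _draw_subject_params(rng: np.random.Generator, cohort: CohortConfig, si: bool) -> HGFParams:
    vals = {}
    for name, (mean, sd) in cohort.parameter_population.items():
        m = mean + (cohort.group_effects.get(name, 0.0) if si else 0.0)
        vals[name] = rng.normal(m, sd) if sd > 0 else m
    return HGFParams(
        omega2=vals["omega2"],
        omega3=vals["omega3"],
        beta=float(np.exp(vals["log_beta"])),
    )


def simulate_cohort(
    task: TaskConfig, cohort: CohortConfig, *, return_params: bool = False
):
    """Simulate a full cohort (SI + control groups) on the task.

    Every subject gets its own schedule permutation and choice stream,
    all derived deterministically from the two config seeds.  Returns the
    stacked trial table, plus the per-subject generative parameters when
    ``return_params`` is set.
    """
    root = np.random.SeedSequence(entropy=[int(cohort.seed), int(task.seed)])
    n_total = cohort.n_si + cohort.n_ctrl
    seeds = root.spawn(n_total)
    frames, truths = [], []
    for i in range(n_total):
        si = i < cohort.n_si
        group = "SI" if si else "NoSI"
        sid = f"s{i:03d}"
        child = seeds[i].spawn(3)
        param_rng = np.random.default_rng(child[0])
        p = _draw_subject_params(param_rng, cohort, si)
        sched = make_task_schedule(
            TaskConfig(
                n_trials=task.n_trials,
                n_cues=task.n_cues,
                balanced=task.balanced,
                reversal_trial=task.reversal_trial,
                seed=int(child[1].generate_state(1)[0] % (2**31 - 1)),
            )
        )
        frames.append(
            simulate_agent(
                sched,
                p,
                int(child[2].generate_state(1)[0] % (2**31 - 1)),
                subject_id=sid,
                group=group,
                input_coding=cohort.input_coding,
                cue_specific_beliefs=cohort.cue_specific_beliefs,
            )
        )
        truths.append(
            {"subject_id": sid, "group": group, "omega2": p.omega2, "omega3": p.omega3, "beta": p.beta}
        )
    data = pd.concat(frames, ignore_index=True)
    if return_params:
        return data, pd.DataFrame(truths)
    return data


def accuracy_by_type(dataset: pd.DataFrame) -> pd.DataFrame:
    """Group-level accuracy (%) per trial category, subject means first.

    Categories: escape / avoidance condition and go / no-go correct
    action.  Per-subject percent-correct is computed within category,
    then averaged within group; empty cells are reported as missing.
    """
    d = dataset.copy()
    out = []
    cats = {
        "escape": d["condition"] == "escape",
        "avoidance": d["condition"] == "avoidance",
        "go": d["correct_action"] == "go",
        "nogo": d["correct_action"] == "nogo",
    }
    for group, gd in d.groupby("group"):
        for cat, mask in cats.items():
            sub = gd[mask.loc[gd.index]]
            if sub.empty:
                out.append({"group": group, "trial_type": cat, "mean_pct": np.nan, "sd_pct": np.nan, "n": 0})
                continue
            per_subj = sub.groupby("subject_id")["correct"].mean() * 100.0
            out.append(
                {
                    "group": group,
                    "trial_type": cat,
                    "mean_pct": float(per_subj.mean()),
                    "sd_pct": float(per_subj.std(ddof=1)) if len(per_subj) > 1 else np.nan,
                    "n": int(len(per_subj)),
                }
            )
    return pd.DataFrame(out)
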