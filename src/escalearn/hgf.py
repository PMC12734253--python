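"""Three-level binary Hierarchical Gaussian Filter (HGF).

The generative model is a hierarchy of coupled Gaussian random walks
observed through a Bernoulli emission:

    x1(t) ~ Bernoulli(logistic(x2(t)))
    x2(t) ~ Normal(x2(t-1), exp(kappa * x3(t) + omega2))
    x3(t) ~ Normal(x3(t-1), exp(omega3))

Level 2 carries the log-odds belief that "go" is the correct action
(the contingency belief); level 3 carries the belief about how quickly
that contingency changes (volatility).  Inverting the model trial by
trial yields closed-form prediction/update equations in which each
belief is revised by a precision-weighted prediction error, with a
dynamic (trial-varying) learning rate given by a ratio of precisions.

Choices are linked to beliefs by the unit-square sigmoid with inverse
temperature ``beta``: higher beta means more deterministic,
belief-consistent responding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "HGFParams",
    "BeliefState",
    "Prediction",
    "TrajectoryRow",
    "Trajectory",
    "HGFNumericalError",
    "predict_step",
    "update_step",
    "filter_sequence",
    "unit_square_sigmoid",
    "choice_loglik",
    "TRAJECTORY_OUTCOMES",
]

#: outcome series extracted downstream for group-level modelling
TRAJECTORY_OUTCOMES = ("mu2", "mu3", "sigma2", "sigma3", "eps2", "eps3", "psi2", "psi3")

# exp() overflow guard: beyond this the belief variances are astronomically
# large and the parameter set is useless anyway
_EXP_MAX = 700.0
_P_CLAMP = 1e-12  # likelihood-only probability clamp


class HGFNumericalError(ArithmeticError):
    """Raised when a parameter set drives the filter into an invalid regime.

    The canonical case is a non-positive level-3 posterior precision
    (pi3 <= 0), which standard practice treats as rejection of the
    parameter set rather than something to clip.
    """


@dataclass(frozen=True)
class HGFParams:
    """Perceptual + response parameters and initial belief state.

    kappa    -- coupling of level-3 volatility into level-2 drift (fixed 1)
    omega2   -- tonic evolution rate at level 2, log-variance units
    omega3   -- tonic evolution rate at level 3, log-variance units
    beta     -- inverse temperature of the unit-square-sigmoid response model
    rho2/rho3 -- deterministic drift terms, disabled (0) by default
    mu2_0, sigma2_0, mu3_0, sigma3_0 -- initial posterior means/variances
    """

    kappa: float = 1.0
    omega2: float = -3.0
    omega3: float = -6.0
    beta: float = 1.0
    rho2: float = 0.0
    rho3: float = 0.0
    mu2_0: float = 0.0
    sigma2_0: float = 0.1
    mu3_0: float = 1.0
    sigma3_0: float = 1.0
    # "binary": psi2 = 1/pi2 = sigma2 (binary-observation convention, default);
    # "literal": psi2 = pihat1/pi2 (generic precision-ratio form, for
    # sensitivity analysis).  Affects only the reported psi2/eps2 series,
    # never the belief updates themselves.
    level2_rate: str = "binary"

    def __post_init__(self) -> None:
        if self.level2_rate not in ("binary", "literal"):
            raise ValueError(f"unknown level2_rate convention {self.level2_rate!r}")
        if not self.beta >= 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if not self.sigma2_0 > 0:
            raise ValueError(f"sigma2_0 must be > 0, got {self.sigma2_0}")
        if not self.sigma3_0 > 0:
            raise ValueError(f"sigma3_0 must be > 0, got {self.sigma3_0}")

    def initial_state(self) -> "BeliefState":
        return BeliefState(self.mu2_0, self.sigma2_0, self.mu3_0, self.sigma3_0)

    def with_(self, **kw) -> "HGFParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class BeliefState:
    """Posterior means/variances at levels 2 and 3 after a trial."""

    mu2: float
    sigma2: float
    mu3: float
    sigma3: float

    def __post_init__(self) -> None:
        if not self.sigma2 > 0:
            raise ValueError(f"sigma2 must be > 0, got {self.sigma2}")
        if not self.sigma3 > 0:
            raise ValueError(f"sigma3 must be > 0, got {self.sigma3}")


@dataclass(frozen=True)
class Prediction:
    """Pre-input predictions derived from the previous posterior."""

    muhat1: float
    pihat1: float
    muhat2: float
    pihat2: float
    muhat3: float
    pihat3: float
    v2: float  # predicted level-2 random-walk variance exp(kappa*muhat3 + omega2)


@dataclass(frozen=True)
class TrajectoryRow:
    """All per-trial HGF quantities for one input."""

    trial: int
    u: int
    muhat1: float
    pihat1: float
    muhat2: float
    pihat2: float
    muhat3: float
    pihat3: float
    delta1: float
    delta2: float
    pi2: float
    pi3: float
    mu2: float
    sigma2: float
    mu3: float
    sigma3: float
    psi2: float
    psi3: float
    eps2: float
    eps3: float


@dataclass
class Trajectory:
    """Ordered per-trial rows plus convenience array accessors."""

    rows: list[TrajectoryRow] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def __getitem__(self, i):
        return self.rows[i]

    def series(self, name: str) -> np.ndarray:
        return np.array([getattr(r, name) for r in self.rows], dtype=float)

    @property
    def muhat1(self) -> np.ndarray:
        return self.series("muhat1")

    def to_frame(self):
        import pandas as pd

        cols = [f.name for f in TrajectoryRow.__dataclass_fields__.values()]  # type: ignore[attr-defined]
        return pd.DataFrame({c: self.series(c) for c in cols}).astype({"trial": int, "u": int})


def _logistic(x: float) -> float:
    # numerically symmetric logistic
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def _checked_exp(x: float, what: str) -> float:
    if x > _EXP_MAX:
        raise HGFNumericalError(f"exp overflow in {what} (argument {x:.3g})")
    return math.exp(x)


def predict_step(state: BeliefState, params: HGFParams) -> Prediction:
    """Form trial predictions from the previous posterior.

    The prior means carry over (plus optional drift); the level-2 prior
    precision shrinks by the volatility-modulated random-walk variance
    v2 = exp(kappa*mu3 + omega2), and the level-3 prior precision by
    exp(omega3).  The level-1 prediction is the logistic of the level-2
    prior mean, with Bernoulli precision 1/(muhat1*(1-muhat1)).
    """
    muhat2 = state.mu2 + params.rho2
    muhat3 = state.mu3 + params.rho3
    muhat1 = _logistic(muhat2)
    if muhat1 <= 0.0 or muhat1 >= 1.0:
        # level-2 mean so extreme the logistic saturates in floats; treat as
        # parameter-set rejection rather than clipping inside the state update
        raise HGFNumericalError(
            f"level-1 prediction saturated (muhat2 = {muhat2:.3g})"
        )
    pihat1 = 1.0 / (muhat1 * (1.0 - muhat1))
    v2 = _checked_exp(params.kappa * muhat3 + params.omega2, "v2 (kappa*mu3 + omega2)")
    pihat2 = 1.0 / (state.sigma2 + v2)
    pihat3 = 1.0 / (state.sigma3 + _checked_exp(params.omega3, "exp(omega3)"))
    return Prediction(muhat1, pihat1, muhat2, pihat2, muhat3, pihat3, v2)


def update_step(
    pred: Prediction, u: int, params: HGFParams, trial: int = 0
) -> tuple[BeliefState, TrajectoryRow]:
    """Revise beliefs after observing binary input ``u``.

    Level 2 is updated by the raw level-1 prediction error delta1
    scaled by 1/pi2 (its dynamic learning rate psi2 = sigma2); level 3
    by the volatility prediction error delta2 scaled by
    psi3 = pihat2/pi3.  A non-positive level-3 posterior precision
    raises :class:`HGFNumericalError` (parameter-set rejection).
    """
    if u not in (0, 1):
        raise ValueError(f"input u must be binary, got {u!r}")

    delta1 = u - pred.muhat1
    pi2 = pred.pihat2 + pred.muhat1 * (1.0 - pred.muhat1)
    mu2 = pred.muhat2 + delta1 / pi2
    sigma2 = 1.0 / pi2

    # volatility prediction error at level 2
    delta2 = (sigma2 + (mu2 - pred.muhat2) ** 2) * pred.pihat2 - 1.0
    w2 = pred.v2 * pred.pihat2
    pi3 = pred.pihat3 + (params.kappa**2 / 2.0) * w2 * (w2 + (2.0 * w2 - 1.0) * delta2)
    if pi3 <= 0.0:
        raise HGFNumericalError(
            f"non-positive level-3 posterior precision pi3={pi3:.3g} at trial {trial}"
        )
    mu3 = pred.muhat3 + (params.kappa / 2.0) * (w2 / pi3) * delta2
    sigma3 = 1.0 / pi3

    psi2 = sigma2 if params.level2_rate == "binary" else pred.pihat1 / pi2
    psi3 = pred.pihat2 / pi3
    eps2 = psi2 * delta1
    eps3 = psi3 * delta2

    state = BeliefState(mu2, sigma2, mu3, sigma3)
    row = TrajectoryRow(
        trial=trial,
        u=int(u),
        muhat1=pred.muhat1,
        pihat1=pred.pihat1,
        muhat2=pred.muhat2,
        pihat2=pred.pihat2,
        muhat3=pred.muhat3,
        pihat3=pred.pihat3,
        delta1=delta1,
        delta2=delta2,
        pi2=pi2,
        pi3=pi3,
        mu2=mu2,
        sigma2=sigma2,
        mu3=mu3,
        sigma3=sigma3,
        psi2=psi2,
        psi3=psi3,
        eps2=eps2,
        eps3=eps3,
    )
    return state, row


def filter_sequence(u: "np.ndarray | list[int]", params: HGFParams) -> Trajectory:
    """Run the trial-wise filter over a binary input sequence.

    Row t is computed from the posterior after trial t-1 (trial 0 uses
    the initial state from ``params``); deterministic.
    """
    seq = np.asarray(u)
    if seq.ndim != 1 or len(seq) < 1:
        raise ValueError("input sequence must be 1-D and non-empty")
    state = params.initial_state()
    traj = Trajectory()
    for t, ut in enumerate(seq, start=1):
        pred = predict_step(state, params)
        try:
            state, row = update_step(pred, int(ut), params, trial=t)
        except HGFNumericalError as err:
            raise HGFNumericalError(f"{err} (filter aborted at trial {t})") from None
        traj.rows.append(row)
    return traj


def unit_square_sigmoid(muhat1: float, beta: float) -> float:
    """P(choose go) = muhat1^beta / (muhat1^beta + (1-muhat1)^beta).

    Strictly increasing in muhat1 for beta > 0; beta = 0 gives 0.5
    (pure guessing).  muhat1 must lie strictly inside the unit interval.
    """
    if not 0.0 < muhat1 < 1.0:
        raise ValueError(f"muhat1 must be in (0, 1), got {muhat1}")
    if beta < 0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    # compute in log space: 1 / (1 + exp(-beta * logit(muhat1)))
    logit = math.log(muhat1) - math.log1p(-muhat1)
    return _logistic(beta * logit)


def choice_loglik(
    trajectory: Trajectory, choices: "np.ndarray | list[int]", beta: float
) -> float:
    """Sum of log P(choice_t | muhat1_t, beta) under the unit-square sigmoid.

    Choice probabilities are clamped to [1e-12, 1 - 1e-12] before the
    log, so the value is finite (and always <= 0).
    """
    ch = np.asarray(choices)
    if len(ch) != len(trajectory):
        raise ValueError(
            f"length mismatch: {len(trajectory)} trajectory rows vs {len(ch)} choices"
        )
    total = 0.0
    for row, c in zip(trajectory.rows, ch):
        if c not in (0, 1):
            raise ValueError(f"choices must be binary, got {c!r}")
        p_go = unit_square_sigmoid(row.muhat1, beta)
        p = p_go if c == 1 else 1.0 - p_go
        p = min(max(p, _P_CLAMP), 1.0 - _P_CLAMP)
        total += math.log(p)
    return total
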