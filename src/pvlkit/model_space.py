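"""The factorial space of reinforcement-learning choice models for the IGT/SGT.

Each model is a triple of components applied trial by trial:

* a **utility function** mapping a card's gain/loss to a scalar subjective
  value u(t) — weighted expected utility (EU), prospect utility on the net
  payoff (PU), or prospect utility evaluating gains and losses separately
  before aggregating (PU2);
* an **updating rule** maintaining a per-deck expectancy E_j(t) — the delta
  (Rescorla-Wagner) rule, the decay-reinforcement rule (DRL), or a mixed rule
  combining memory decay with a delta step;
* a **choice rule** turning expectancies into deck probabilities via a
  ratio-of-strength (softmax) transform with sensitivity θ, where θ either
  grows with the trial index (TDC, θ(t) = (t/10)^c) or stays constant
  (TIC, θ = 3^c − 1).

The 3 × 3 × 2 cross gives 18 models. Three named presets are the models the
literature singles out: EVL = EU+DELTA+TDC, PVL = PU+DRL+TIC, and
PVL2 = PU2+DRL+TIC.

Parameter vectors are ordered canonically: utility parameters first, then
updating parameters, then the choice consistency c.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product
from typing import Callable, Sequence

import numpy as np

from .task_engine import DECKS, TrialOutcome

EU, PU, PU2 = "EU", "PU", "PU2"
DELTA, DRL, MIXED = "DELTA", "DRL", "MIXED"
TDC, TIC = "TDC", "TIC"

UTILITIES = (EU, PU, PU2)
UPDATING_RULES = (DELTA, DRL, MIXED)
CHOICE_RULES = (TDC, TIC)

#: Named presets from the literature.
PRESETS = {
    "EVL": (EU, DELTA, TDC),
    "PVL": (PU, DRL, TIC),
    "PVL2": (PU2, DRL, TIC),
}

N_DECKS = len(DECKS)
DECK_INDEX = {d: i for i, d in enumerate(DECKS)}


# ---------------------------------------------------------------------------
# Parameter containers (thin, validated views onto the canonical vector)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EUParams:
    """Weighted-utility parameters: W is the attention weight on losses."""

    W: float

    def __post_init__(self):
        if not 0.0 <= self.W <= 1.0:
            raise ValueError("W must lie in [0, 1]")


@dataclass(frozen=True)
class PUParams:
    """Net-payoff prospect utility: curvature alpha, loss aversion lam."""

    alpha: float
    lam: float

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.lam < 0:
            raise ValueError("lam must be nonnegative")


@dataclass(frozen=True)
class PU2Params:
    """Separate-gains/losses prospect utility: curvature alpha, loss aversion gamma."""

    alpha: float
    gamma: float

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.gamma < 0:
            raise ValueError("gamma must be nonnegative")


@dataclass(frozen=True)
class DeltaParams:
    """Delta-rule updating rate A in [0, 1]."""

    A: float

    def __post_init__(self):
        if not 0.0 <= self.A <= 1.0:
            raise ValueError("A must lie in [0, 1]")


@dataclass(frozen=True)
class DRLParams:
    """Decay-reinforcement recency multiplier A in [0, 1]."""

    A: float

    def __post_init__(self):
        if not 0.0 <= self.A <= 1.0:
            raise ValueError("A must lie in [0, 1]")


@dataclass(frozen=True)
class MixedParams:
    """Mixed-rule decay D and updating rate A, both in [0, 1]."""

    D: float
    A: float

    def __post_init__(self):
        if not 0.0 <= self.D <= 1.0:
            raise ValueError("D must lie in [0, 1]")
        if not 0.0 <= self.A <= 1.0:
            raise ValueError("A must lie in [0, 1]")


@dataclass(frozen=True)
class ChoiceParams:
    """Consistency parameter c for the TDC or TIC sensitivity function."""

    c: float
    rule: str = TIC

    def __post_init__(self):
        if self.rule not in CHOICE_RULES:
            raise ValueError(f"unknown choice rule {self.rule!r}")
        if self.rule == TIC and self.c < 0:
            raise ValueError("TIC consistency c must be nonnegative")


Expectancies = np.ndarray  # 4-vector of per-deck expected utilities


# ---------------------------------------------------------------------------
# Utility functions
# ---------------------------------------------------------------------------

def utility_eu(outcome: TrialOutcome, p: EUParams) -> float:
    """Weighted expected utility: u = (1−W)·win − W·loss.

    W = 0.5 weighs gains and losses equally (equal-magnitude outcomes cancel);
    W = 0 ignores losses entirely, W = 1 ignores gains.
    """
    return (1.0 - p.W) * outcome.win - p.W * outcome.loss


def utility_pu(outcome: TrialOutcome, p: PUParams) -> float:
    """Prospect utility of the net payoff x = win − loss.

    Returns x^α for x ≥ 0 and −λ·|x|^α for x < 0. At α = 0 the function is a
    step: any net gain (including a zero net) is worth 1 and any net loss −λ.
    """
    x = outcome.win - outcome.loss
    if x >= 0:
        return x ** p.alpha
    return -p.lam * (-x) ** p.alpha


def utility_pu2(outcome: TrialOutcome, p: PU2Params) -> float:
    """Prospect utility with gains and losses evaluated separately.

    Returns win^α − γ·loss^α. Unlike :func:`utility_pu`, an outcome with equal
    gain and loss is generally not neutral (it is (1−γ)·win^α).
    """
    return outcome.win ** p.alpha - p.gamma * outcome.loss ** p.alpha


# ---------------------------------------------------------------------------
# Updating rules
# ---------------------------------------------------------------------------

def update_delta(E: Expectancies, chosen: str, u: float, p: DeltaParams) -> Expectancies:
    """Delta rule: the chosen deck moves a fraction A toward u; others keep."""
    E = np.asarray(E, dtype=float).copy()
    j = DECK_INDEX[chosen]
    E[j] += p.A * (u - E[j])
    return E


def update_drl(E: Expectancies, chosen: str, u: float, p: DRLParams) -> Expectancies:
    """Decay-reinforcement rule: all expectancies decay by A, chosen adds u.

    The update is not bounded by the previous expectancy and the current
    utility: e.g. A = 0.9, E = 10, u = 5 gives 0.9·10 + 5 = 14.
    """
    E = np.asarray(E, dtype=float) * p.A
    E[DECK_INDEX[chosen]] += u
    return E


def update_mixed(E: Expectancies, chosen: str, u: float, p: MixedParams) -> Expectancies:
    """Mixed rule: decay all by (1−D), then a delta step of size A on chosen.

    Reduces exactly to the delta rule at D = 0; at A = 1 the chosen deck's
    expectancy becomes u regardless of D.
    """
    E = np.asarray(E, dtype=float) * (1.0 - p.D)
    j = DECK_INDEX[chosen]
    E[j] += p.A * (u - E[j])
    return E


# ---------------------------------------------------------------------------
# Choice rules
# ---------------------------------------------------------------------------

def sensitivity_tdc(t: int, c: float) -> float:
    """Trial-dependent sensitivity θ(t) = (t/10)^c for trial index t ≥ 1.

    c > 0 makes choices increasingly expectancy-driven over the session,
    c < 0 increasingly random; θ(10) = 1 for every c.
    """
    if t < 1:
        raise ValueError("trial index must be >= 1")
    return (t / 10.0) ** c


def sensitivity_tic(c: float) -> float:
    """Trial-independent sensitivity θ = 3^c − 1 for c ≥ 0.

    c = 0 gives θ = 0 (uniformly random choice regardless of expectancies).
    """
    if c < 0:
        raise ValueError("TIC consistency c must be nonnegative")
    return 3.0 ** c - 1.0


def choice_probabilities(E: Sequence[float], theta: float) -> np.ndarray:
    """Ratio-of-strength (softmax) deck probabilities: P_j ∝ exp(θ·E_j).

    Computed with max-subtraction, so the result is finite, positive, and sums
    to one for any finite θ·E (after shifting, every exponent is ≤ 0 and the
    largest is exactly 0).
    """
    s = theta * np.asarray(E, dtype=float)
    s -= s.max()
    w = np.exp(s)
    return w / w.sum()


# ---------------------------------------------------------------------------
# Model specifications
# ---------------------------------------------------------------------------

_UTILITY_PARAMS = {EU: ("W",), PU: ("alpha", "lam"), PU2: ("alpha", "gamma")}
_UPDATING_PARAMS = {DELTA: ("A",), DRL: ("A",), MIXED: ("D", "A")}

_BOUNDS = {
    "W": (0.0, 1.0),
    "alpha": (0.0, 1.0),
    "lam": (0.0, 10.0),
    "gamma": (0.0, 10.0),
    "A": (0.0, 1.0),
    "D": (0.0, 1.0),
}
_C_BOUNDS = {TDC: (-5.0, 5.0), TIC: (0.0, 5.0)}


@dataclass(frozen=True)
class ModelSpec:
    """One point in the 18-model factorial space."""

    utility: str
    updating: str
    choice: str

    def __post_init__(self):
        if self.utility not in UTILITIES:
            raise ValueError(f"unknown utility function {self.utility!r}")
        if self.updating not in UPDATING_RULES:
            raise ValueError(f"unknown updating rule {self.updating!r}")
        if self.choice not in CHOICE_RULES:
            raise ValueError(f"unknown choice rule {self.choice!r}")

    def __str__(self) -> str:
        return f"{self.utility}-{self.updating}-{self.choice}"

    @classmethod
    def from_string(cls, s: str) -> "ModelSpec":
        """Parse "PU2-DRL-TIC"-style strings; preset names also accepted."""
        if s in PRESETS:
            return cls(*PRESETS[s])
        parts = s.split("-")
        if len(parts) != 3:
            raise ValueError(f"cannot parse model string {s!r}")
        return cls(*parts)

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return _UTILITY_PARAMS[self.utility] + _UPDATING_PARAMS[self.updating] + ("c",)

    @property
    def n_parameters(self) -> int:
        return len(self.parameter_names)

    @property
    def preset_name(self) -> str | None:
        triple = (self.utility, self.updating, self.choice)
        for name, preset in PRESETS.items():
            if preset == triple:
                return name
        return None


def get_model(name_or_spec: str | ModelSpec) -> ModelSpec:
    if isinstance(name_or_spec, ModelSpec):
        return name_or_spec
    return ModelSpec.from_string(name_or_spec)


def enumerate_model_space() -> list[ModelSpec]:
    """All 18 models, in utility-major, updating-middle, choice-minor order."""
    return [
        ModelSpec(u, r, c)
        for u, r, c in product(UTILITIES, UPDATING_RULES, CHOICE_RULES)
    ]


def parameter_bounds(spec: ModelSpec) -> list[tuple[str, float, float]]:
    """Ordered (name, lower, upper) bounds of a model's free parameters.

    W, A, D and α live on [0, 1]; the loss-aversion multipliers λ and γ on
    [0, 10]; the consistency c on [0, 5] for TIC and [−5, 5] for TDC (negative
    c lets sensitivity decay over trials).
    """
    out = []
    for name in spec.parameter_names:
        if name == "c":
            lo, hi = _C_BOUNDS[spec.choice]
        else:
            lo, hi = _BOUNDS[name]
        out.append((name, lo, hi))
    return out


def validate_params(spec: ModelSpec, params: Sequence[float]) -> None:
    """Raise ValueError if ``params`` is mis-sized or outside the bounds."""
    bounds = parameter_bounds(spec)
    if len(params) != len(bounds):
        raise ValueError(
            f"{spec} expects {len(bounds)} parameters "
            f"({', '.join(n for n, _, _ in bounds)}), got {len(params)}"
        )
    for value, (name, lo, hi) in zip(params, bounds):
        if not (lo <= value <= hi) or not math.isfinite(value):
            raise ValueError(f"{spec}: {name}={value} outside [{lo}, {hi}]")


# ---------------------------------------------------------------------------
# Compiled scalar kernels — shared by the likelihood and the simulator
# ---------------------------------------------------------------------------
# The forward recursion is evaluated hundreds of thousands of times during a
# multi-start fit, so the kernels below work on plain floats and 4-lists
# rather than numpy arrays (vector overhead dominates at this size).

def compile_utility(spec: ModelSpec, params: Sequence[float]) -> Callable[[float, float], float]:
    """A (win, loss) -> u closure for the spec's utility at fixed parameters."""
    if spec.utility == EU:
        (W,) = params[:1]
        return lambda win, loss: (1.0 - W) * win - W * loss
    if spec.utility == PU:
        alpha, lam = params[:2]

        def u_pu(win: float, loss: float) -> float:
            x = win - loss
            return x ** alpha if x >= 0 else -lam * (-x) ** alpha

        return u_pu
    alpha, gamma = params[:2]
    return lambda win, loss: win ** alpha - gamma * loss ** alpha


def compile_update(spec: ModelSpec, params: Sequence[float]) -> Callable[[list, int, float], None]:
    """An in-place (E, chosen_index, u) updater for the spec's learning rule."""
    n_u = len(_UTILITY_PARAMS[spec.utility])
    if spec.updating == DELTA:
        A = params[n_u]

        def step_delta(E: list, j: int, u: float) -> None:
            E[j] += A * (u - E[j])

        return step_delta
    if spec.updating == DRL:
        A = params[n_u]

        def step_drl(E: list, j: int, u: float) -> None:
            for k in range(N_DECKS):
                E[k] *= A
            E[j] += u

        return step_drl
    D, A = params[n_u], params[n_u + 1]
    keep = 1.0 - D

    def step_mixed(E: list, j: int, u: float) -> None:
        for k in range(N_DECKS):
            E[k] *= keep
        E[j] += A * (u - E[j])

    return step_mixed


def compile_sensitivity(spec: ModelSpec, params: Sequence[float]) -> Callable[[int], float]:
    """A trial-index -> θ closure (constant for TIC)."""
    c = params[-1]
    if spec.choice == TIC:
        theta = 3.0 ** c - 1.0
        return lambda t: theta
    return lambda t: (t / 10.0) ** c
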