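"""One-step-ahead maximum-likelihood fitting and BIC model comparison.

A model is scored by how well it predicts each choice *before* seeing it: the
recursion is run forward over a participant's observed choices and outcomes,
and the log-likelihood sums the log predicted probability of the deck actually
chosen on every trial after the first (the first choice is made with no
information and contributes no term). Each model's maximized log-likelihood is
compared against a statistical baseline that assumes independent choices with
constant deck probabilities (three free parameters), via a BIC difference

    BIC = 2·(LL_model − LL_baseline) − k·ln(n),

where k is the model's extra-parameter count relative to the baseline and n
the number of fitted data points. Positive scores favour the cognitive model.

Optimization is a multi-start scheme: likelihoods are evaluated on a seeded
Latin-hypercube design of start points spread over the bounded parameter box
(50 by default), and Nelder-Mead simplex refinement is run from the best few.
Bounds are enforced by optimizing through a logit map to the real line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from math import exp, isfinite, log
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import qmc

from .model_space import (
    DECK_INDEX,
    ModelSpec,
    compile_sensitivity,
    compile_update,
    compile_utility,
    parameter_bounds,
    validate_params,
)
from .task_engine import IGT, SGT

logger = logging.getLogger(__name__)


class NumericalFailureError(RuntimeError):
    """A non-finite intermediate value in the likelihood recursion."""

    def __init__(self, trial: int, message: str = ""):
        self.trial = trial
        super().__init__(message or f"non-finite likelihood term at trial {trial}")


class FitFailureError(RuntimeError):
    """No start point produced a finite likelihood."""


@dataclass
class ChoiceSequence:
    """One participant's (or agent's) full trial-by-trial record for one task.

    ``trials`` is an ordered sequence of (deck label, gain, loss-magnitude)
    triples; the study sessions had 120 trials.
    """

    task_id: str
    trials: list[tuple[str, float, float]]
    participant_id: str | None = None

    def __post_init__(self):
        if self.task_id not in (IGT, SGT):
            raise ValueError(f"unknown task {self.task_id!r}")
        for i, (deck, win, loss) in enumerate(self.trials):
            if deck not in DECK_INDEX:
                raise ValueError(f"trial {i + 1}: unknown deck label {deck!r}")
            if not (isfinite(win) and isfinite(loss)) or win < 0 or loss < 0:
                raise ValueError(f"trial {i + 1}: amounts must be finite and nonnegative")
            if self.task_id == SGT and win > 0 and loss > 0:
                raise ValueError(
                    f"trial {i + 1}: SGT outcomes are pure gains or pure losses"
                )
        # flat arrays for the hot likelihood loop
        self._idx = [DECK_INDEX[d] for d, _, _ in self.trials]
        self._wins = [float(w) for _, w, _ in self.trials]
        self._losses = [float(l) for _, _, l in self.trials]

    def __len__(self) -> int:
        return len(self.trials)


def one_step_ahead_loglik(
    spec: ModelSpec,
    params: Sequence[float],
    seq: ChoiceSequence,
    tdc_index: str = "predicted",
    validate: bool = True,
) -> float:
    """Log-likelihood of a choice sequence under one-step-ahead prediction.

    Starting from zero expectancies, for each trial t = 1..T−1 the utility of
    the observed outcome updates the chosen deck's expectancy, and the log of
    the softmax probability assigned to the choice actually made on trial t+1
    is accumulated. A T-trial sequence therefore contributes T−1 terms, and a
    sequence predicted uniformly at random scores (T−1)·ln(1/4).

    ``tdc_index`` selects the trial index fed to the trial-dependent
    sensitivity θ(t) = (t/10)^c: ``"predicted"`` (default) uses the index of
    the trial being predicted (t+1), ``"current"`` the index of the last
    observed trial (t). TIC models ignore it.
    """
    if tdc_index not in ("predicted", "current"):
        raise ValueError("tdc_index must be 'predicted' or 'current'")
    if validate:
        validate_params(spec, params)

    utility = compile_utility(spec, params)
    step = compile_update(spec, params)
    sens = compile_sensitivity(spec, params)
    offset = 1 if tdc_index == "predicted" else 0

    idx, wins, losses = seq._idx, seq._wins, seq._losses
    T = len(idx)
    E = [0.0, 0.0, 0.0, 0.0]
    ll = 0.0
    for t in range(1, T):
        step(E, idx[t - 1], utility(wins[t - 1], losses[t - 1]))
        theta = sens(t + offset)
        s = (theta * E[0], theta * E[1], theta * E[2], theta * E[3])
        m = max(s)
        z = exp(s[0] - m) + exp(s[1] - m) + exp(s[2] - m) + exp(s[3] - m)
        term = s[idx[t]] - m - log(z)
        if not isfinite(term):
            raise NumericalFailureError(t + 1)
        ll += term
    return ll


@dataclass(frozen=True)
class BaselineFit:
    """Constant-probability baseline: the MLE is the empirical choice mix."""

    probs: tuple[float, float, float, float]
    loglik: float
    n_predicted: int


def fit_baseline(seq: ChoiceSequence) -> BaselineFit:
    """Closed-form MLE of the independent constant-probability model.

    Fitted on the same T−1 predicted trials as the cognitive models (the first
    choice conditions both likelihoods), so the two log-likelihoods are
    comparable. Decks never chosen contribute nothing to the log-likelihood.
    """
    if len(seq) < 2:
        raise ValueError("need at least 2 trials to fit the baseline")
    predicted = seq._idx[1:]
    n = len(predicted)
    counts = [0, 0, 0, 0]
    for j in predicted:
        counts[j] += 1
    probs = tuple(c / n for c in counts)
    loglik = sum(c * log(c / n) for c in counts if c > 0)
    return BaselineFit(probs=probs, loglik=loglik, n_predicted=n)


def bic_difference(loglik_model: float, loglik_baseline: float, k: int, n: int) -> float:
    """BIC difference score: 2·(LL_model − LL_baseline) − k·ln(n).

    ``k`` is the model's parameter count minus the baseline's three; positive
    scores mean the cognitive model outperforms the baseline.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return 2.0 * (loglik_model - loglik_baseline) - k * log(n)


@dataclass(frozen=True)
class FitConfig:
    """Settings for the multi-start maximum-likelihood search.

    ``n_starts`` Latin-hypercube points are scored and the best ``n_refine``
    are polished with Nelder-Mead (function/parameter tolerances ``f_tol`` /
    ``x_tol``, at most ``max_iter_per_dim``·dim iterations per start).
    ``bic_n_mode`` selects the BIC sample size: ``"predicted"`` uses the T−1
    predicted choices, ``"all"`` the full T trials.
    """

    n_starts: int = 50
    n_refine: int = 5
    f_tol: float = 1e-8
    x_tol: float = 1e-8
    max_iter_per_dim: int = 500
    rng_seed: int = 0
    bic_n_mode: str = "predicted"
    tdc_index: str = "predicted"

    def __post_init__(self):
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.bic_n_mode not in ("predicted", "all"):
            raise ValueError("bic_n_mode must be 'predicted' or 'all'")

    def with_seed(self, rng_seed: int) -> "FitConfig":
        return replace(self, rng_seed=rng_seed)


@dataclass
class FitResult:
    """Maximum-likelihood fit of one model to one choice sequence."""

    spec: ModelSpec
    params: tuple[float, ...]
    loglik: float
    bic_diff: float
    baseline_loglik: float
    n_predicted: int
    converged: bool
    n_starts_used: int
    participant_id: str | None = None
    task_id: str | None = None

    @property
    def param_dict(self) -> dict[str, float]:
        return dict(zip(self.spec.parameter_names, self.params))


def _logit_box(bounds: np.ndarray):
    """Maps between the open parameter box and the unconstrained real line."""
    lo, hi = bounds[:, 0], bounds[:, 1]
    width = hi - lo

    def to_z(x: np.ndarray) -> np.ndarray:
        u = np.clip((np.asarray(x, dtype=float) - lo) / width, 1e-12, 1 - 1e-12)
        return np.log(u / (1.0 - u))

    def to_x(z: np.ndarray) -> np.ndarray:
        return lo + width * expit(np.asarray(z, dtype=float))

    return to_z, to_x


def fit_model(
    spec: ModelSpec,
    seq: ChoiceSequence,
    cfg: FitConfig = FitConfig(),
) -> FitResult:
    """Maximize the one-step-ahead log-likelihood of ``spec`` on ``seq``.

    Deterministic given ``cfg.rng_seed``. The returned log-likelihood is the
    best over all start points and all simplex refinements, so it can never be
    worse than the best raw grid start.
    """
    if len(seq) < 2:
        raise ValueError("need at least 2 trials to fit a model")
    bounds = np.array([(lo, hi) for _, lo, hi in parameter_bounds(spec)])
    dim = len(bounds)
    to_z, to_x = _logit_box(bounds)

    def neg_ll(x: np.ndarray) -> float:
        try:
            return -one_step_ahead_loglik(
                spec, x, seq, tdc_index=cfg.tdc_index, validate=False
            )
        except NumericalFailureError:
            return np.inf

    sampler = qmc.LatinHypercube(d=dim, seed=cfg.rng_seed)
    starts = qmc.scale(sampler.random(cfg.n_starts), bounds[:, 0], bounds[:, 1])
    start_vals = np.array([neg_ll(x) for x in starts])
    if not np.isfinite(start_vals).any():
        raise FitFailureError(f"{spec}: all {cfg.n_starts} start points non-finite")

    order = np.argsort(start_vals)
    best_x = starts[order[0]]
    best_val = start_vals[order[0]]
    converged = False
    max_iter = cfg.max_iter_per_dim * dim
    for i in order[: cfg.n_refine]:
        if not np.isfinite(start_vals[i]):
            continue
        res = minimize(
            lambda z: neg_ll(to_x(z)),
            to_z(starts[i]),
            method="Nelder-Mead",
            options={
                "fatol": cfg.f_tol,
                "xatol": cfg.x_tol,
                "maxiter": max_iter,
                "maxfev": 2 * max_iter,
            },
        )
        if res.fun < best_val:
            best_val = res.fun
            best_x = to_x(res.x)
        converged = converged or bool(res.success)

    baseline = fit_baseline(seq)
    k = spec.n_parameters - 3
    n = baseline.n_predicted if cfg.bic_n_mode == "predicted" else len(seq)
    loglik = -float(best_val)
    return FitResult(
        spec=spec,
        params=tuple(float(v) for v in best_x),
        loglik=loglik,
        bic_diff=bic_difference(loglik, baseline.loglik, k, n),
        baseline_loglik=baseline.loglik,
        n_predicted=baseline.n_predicted,
        converged=converged,
        n_starts_used=cfg.n_starts,
        participant_id=seq.participant_id,
        task_id=seq.task_id,
    )


def fit_models(
    specs: Sequence[ModelSpec],
    sequences: Sequence[ChoiceSequence],
    cfg: FitConfig = FitConfig(),
) -> list[FitResult]:
    """Fit every model in ``specs`` to every sequence; convenience wrapper."""
    results = []
    for seq in sequences:
        for spec in specs:
            results.append(fit_model(spec, seq, cfg))
            logger.debug(
                "fit %s on %s/%s: loglik=%.3f bic_diff=%.3f",
                spec, seq.participant_id, seq.task_id,
                results[-1].loglik, results[-1].bic_diff,
            )
    return results
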