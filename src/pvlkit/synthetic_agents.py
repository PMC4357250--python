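"""Synthetic agents: generative play of the 18 models on the real schedules.

Agents realize a model generatively: starting from zero expectancies the first
deck is drawn uniformly, outcomes come from a seeded dealer over the exact
IGT/SGT payoff blocks, and every later choice is sampled from the model's
softmax probabilities. The generative step and the likelihood recursion share
the same compiled kernels, so an agent's data is exactly the process its
generating model assigns likelihood to.

A cohort gives each agent one parameter vector and one session per task
generated under *the same* parameters — the cross-task consistency assumption
that model parameters measure stable characteristics of an individual. The
default parameter sampler is independent uniform over each parameter's bounds,
except the consistency c, drawn on [0.5, 3] so that agents are neither purely
random (c ≈ 0) nor rigidly deterministic (c near its upper bound) — both
extremes make the recovery problem degenerate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import exp
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .comparison import spearman_consistency
from .fitting import ChoiceSequence, FitConfig, FitFailureError, FitResult, fit_model
from .model_space import (
    DECKS,
    ModelSpec,
    compile_sensitivity,
    compile_update,
    compile_utility,
    parameter_bounds,
    validate_params,
)
from .task_engine import DeckDealer, IGT, PayoffSchedule, SGT, get_schedule

logger = logging.getLogger(__name__)

#: Default sampling range for the consistency parameter c.
DEFAULT_C_RANGE = (0.5, 3.0)

_TASK_STREAM = {IGT: 0, SGT: 1}


@dataclass(frozen=True)
class AgentConfig:
    """One synthetic agent: a model, its parameters, and a session seed."""

    spec: ModelSpec
    params: tuple[float, ...]
    n_trials: int = 120
    seed: int = 0

    def __post_init__(self):
        validate_params(self.spec, self.params)
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


def simulate_agent(cfg: AgentConfig, schedule: PayoffSchedule) -> ChoiceSequence:
    """Play one session of ``schedule`` under the agent's model.

    Fully reproducible from ``cfg.seed``; the dealer stream and the choice
    stream are independent, and the two tasks use disjoint streams derived
    from the same seed, so an agent's IGT and SGT sessions differ even though
    the parameters are shared.
    """
    root = np.random.SeedSequence([int(cfg.seed), _TASK_STREAM[schedule.task_id]])
    dealer_ss, choice_ss = root.spawn(2)
    dealer = DeckDealer(schedule, dealer_ss)
    rng = np.random.default_rng(choice_ss)

    utility = compile_utility(cfg.spec, cfg.params)
    step = compile_update(cfg.spec, cfg.params)
    sens = compile_sensitivity(cfg.spec, cfg.params)

    E = [0.0, 0.0, 0.0, 0.0]
    trials: list[tuple[str, float, float]] = []
    uniforms = rng.random(cfg.n_trials)
    for t in range(1, cfg.n_trials + 1):
        theta = sens(t)
        s = (theta * E[0], theta * E[1], theta * E[2], theta * E[3])
        m = max(s)
        w = (exp(s[0] - m), exp(s[1] - m), exp(s[2] - m), exp(s[3] - m))
        target = uniforms[t - 1] * (w[0] + w[1] + w[2] + w[3])
        acc, j = 0.0, 3
        for k in range(4):
            acc += w[k]
            if target < acc:
                j = k
                break
        outcome = dealer.draw(DECKS[j])
        trials.append((DECKS[j], outcome.win, outcome.loss))
        step(E, j, utility(outcome.win, outcome.loss))
    return ChoiceSequence(schedule.task_id, trials)


def uniform_parameter_sampler(
    spec: ModelSpec, c_range: tuple[float, float] = DEFAULT_C_RANGE
) -> Callable[[np.random.Generator], tuple[float, ...]]:
    """Independent-uniform sampler over the model's parameter box.

    The consistency c is restricted to ``c_range`` (default [0.5, 3]); all
    other parameters use their full bounds.
    """
    ranges = []
    for name, lo, hi in parameter_bounds(spec):
        if name == "c":
            lo, hi = max(lo, c_range[0]), min(hi, c_range[1])
        ranges.append((lo, hi))

    def sample(rng: np.random.Generator) -> tuple[float, ...]:
        return tuple(float(rng.uniform(lo, hi)) for lo, hi in ranges)

    return sample


@dataclass
class Cohort:
    """A set of agents, each with one session per task under shared parameters."""

    spec: ModelSpec
    agents: list[AgentConfig]
    sequences: dict[str, list[ChoiceSequence]]  # task -> per-agent sessions

    @property
    def n_agents(self) -> int:
        return len(self.agents)

    @property
    def tasks(self) -> tuple[str, ...]:
        return tuple(self.sequences)

    def parameter_table(self) -> pd.DataFrame:
        """Generating parameters, one row per agent."""
        names = self.spec.parameter_names
        rows = [
            {"participant_id": a_seq.participant_id, **dict(zip(names, agent.params))}
            for agent, a_seq in zip(self.agents, self.sequences[self.tasks[0]])
        ]
        return pd.DataFrame(rows)


def generate_cohort(
    n_agents: int,
    spec: ModelSpec,
    param_sampler: Callable[[np.random.Generator], tuple[float, ...]] | None = None,
    n_trials: int = 120,
    master_seed: int = 0,
    tasks: Sequence[str] = (IGT, SGT),
) -> Cohort:
    """Sample ``n_agents`` parameter vectors and simulate each task per agent.

    Per-agent seeds are split deterministically from ``master_seed``, so equal
    master seeds give byte-identical cohorts.
    """
    if n_agents < 1:
        raise ValueError("n_agents must be >= 1")
    sampler = param_sampler or uniform_parameter_sampler(spec)
    root = np.random.SeedSequence(master_seed)
    param_rng = np.random.default_rng(root.spawn(1)[0])
    # independent integer session seeds per agent, below 2**31
    agent_seeds = np.random.default_rng(root.spawn(2)[1]).integers(
        0, 2**31 - 1, size=n_agents
    )

    agents, sequences = [], {task: [] for task in tasks}
    for i in range(n_agents):
        cfg = AgentConfig(
            spec=spec,
            params=sampler(param_rng),
            n_trials=n_trials,
            seed=int(agent_seeds[i]),
        )
        agents.append(cfg)
        pid = f"agent{i + 1:03d}"
        for task in tasks:
            seq = simulate_agent(cfg, get_schedule(task))
            seq.participant_id = pid
            sequences[task].append(seq)
    return Cohort(spec=spec, agents=agents, sequences=sequences)


@dataclass
class RecoveryReport:
    """Parameter-recovery and cross-task consistency summary for a cohort."""

    fit_spec: ModelSpec
    fits: dict[str, list[FitResult | None]]  # task -> per-agent fit (None = failed)
    recovery: pd.DataFrame  # columns: task, parameter, rho, p_one_tailed
    cross_task: pd.DataFrame  # columns: parameter, rho, p_one_tailed
    insufficient_n: bool
    n_fit_failures: int = 0

    def recovered_table(self, task: str) -> pd.DataFrame:
        names = self.fit_spec.parameter_names
        rows = []
        for fit in self.fits[task]:
            if fit is None:
                rows.append({n: np.nan for n in names})
            else:
                rows.append(dict(zip(names, fit.params)))
        return pd.DataFrame(rows)


def recovery_experiment(
    cohort: Cohort,
    fit_spec: ModelSpec | None = None,
    cfg: FitConfig = FitConfig(),
) -> RecoveryReport:
    """Fit every sequence in a cohort and measure parameter recovery.

    Returns Spearman rank correlations between generating and recovered values
    per parameter and task, and — when both tasks are present — the cross-task
    rank correlation of the *recovered* values per parameter, mirroring the
    consistency analysis run on real participants. Individual fit failures are
    recorded and skipped rather than aborting the cohort.
    """
    fit_spec = fit_spec or cohort.spec
    names = fit_spec.parameter_names
    insufficient = cohort.n_agents < 3

    fits: dict[str, list[FitResult | None]] = {}
    n_failures = 0
    for task in cohort.tasks:
        fits[task] = []
        for seq in cohort.sequences[task]:
            try:
                fits[task].append(fit_model(fit_spec, seq, cfg))
            except FitFailureError:
                logger.warning("fit failure: %s on %s/%s", fit_spec, seq.participant_id, task)
                fits[task].append(None)
                n_failures += 1

    report = RecoveryReport(
        fit_spec=fit_spec,
        fits=fits,
        recovery=pd.DataFrame(columns=["task", "parameter", "rho", "p_one_tailed"]),
        cross_task=pd.DataFrame(columns=["parameter", "rho", "p_one_tailed"]),
        insufficient_n=insufficient,
        n_fit_failures=n_failures,
    )
    if insufficient:
        return report

    self_recovery = fit_spec == cohort.spec
    gen = cohort.parameter_table() if self_recovery else None
    rec_rows = []
    for task in cohort.tasks:
        recovered = report.recovered_table(task)
        if gen is None:
            continue
        for name in names:
            ok = recovered[name].notna()
            res = spearman_consistency(
                gen.loc[ok.values, name].to_numpy(), recovered.loc[ok, name].to_numpy(),
                parameter=name,
            )
            rec_rows.append(
                {"task": task, "parameter": name, "rho": res.rho,
                 "p_one_tailed": res.p_one_tailed}
            )
    if rec_rows:
        report.recovery = pd.DataFrame(rec_rows)

    if len(cohort.tasks) >= 2:
        t1, t2 = cohort.tasks[0], cohort.tasks[1]
        r1, r2 = report.recovered_table(t1), report.recovered_table(t2)
        cross_rows = []
        for name in names:
            ok = (r1[name].notna() & r2[name].notna()).to_numpy()
            res = spearman_consistency(
                r1.loc[ok, name].to_numpy(), r2.loc[ok, name].to_numpy(), parameter=name
            )
            cross_rows.append(
                {"parameter": name, "rho": res.rho, "p_one_tailed": res.p_one_tailed}
            )
        report.cross_task = pd.DataFrame(cross_rows)
    return report
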