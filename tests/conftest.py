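"""Shared fixtures and independent reference implementations.

The reference likelihood below is deliberately naive: it keeps expectancies in
a dict keyed by deck label, evaluates each published equation with explicit
branching, and uses scipy's softmax — structurally unrelated to the package's
compiled-kernel recursion, so agreement is a genuine cross-check.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.special import log_softmax

from pvlkit import ChoiceSequence, ModelSpec, build_igt_schedule, build_sgt_schedule
from pvlkit.model_space import parameter_bounds
from pvlkit.synthetic_agents import AgentConfig, simulate_agent


@pytest.fixture(scope="session")
def igt():
    return build_igt_schedule()


@pytest.fixture(scope="session")
def sgt():
    return build_sgt_schedule()


def reference_loglik(spec: ModelSpec, params, seq: ChoiceSequence) -> float:
    """Naive per-trial evaluation of the one-step-ahead log-likelihood."""
    p = dict(zip(spec.parameter_names, params))
    decks = ["A", "B", "C", "D"]
    E = {d: 0.0 for d in decks}
    total = 0.0
    n = len(seq.trials)
    for t in range(1, n):  # t = 1-based index of the observed trial
        deck, win, loss = seq.trials[t - 1]

        if spec.utility == "EU":
            u = (1 - p["W"]) * win - p["W"] * loss
        elif spec.utility == "PU":
            x = win - loss
            u = x ** p["alpha"] if x >= 0 else -p["lam"] * abs(x) ** p["alpha"]
        else:
            u = win ** p["alpha"] - p["gamma"] * loss ** p["alpha"]

        if spec.updating == "DELTA":
            E[deck] = E[deck] + p["A"] * (u - E[deck])
        elif spec.updating == "DRL":
            for d in decks:
                E[d] = p["A"] * E[d] + (u if d == deck else 0.0)
        else:
            for d in decks:
                decayed = (1 - p["D"]) * E[d]
                E[d] = decayed + (p["A"] * (u - decayed) if d == deck else 0.0)

        if spec.choice == "TIC":
            theta = 3 ** p["c"] - 1
        else:
            theta = ((t + 1) / 10) ** p["c"]  # index of the predicted trial

        log_probs = log_softmax([theta * E[d] for d in decks])
        chosen_next = seq.trials[t][0]
        total += log_probs[decks.index(chosen_next)]
    return total


def random_params(spec: ModelSpec, rng: np.random.Generator) -> tuple[float, ...]:
    """A uniform draw from the model's parameter box (c kept moderate so the
    likelihood stays away from hard-deterministic corners)."""
    out = []
    for name, lo, hi in parameter_bounds(spec):
        if name == "c":
            lo, hi = max(lo, 0.0), min(hi, 3.0)
        out.append(float(rng.uniform(lo, hi)))
    return tuple(out)


def make_sequence(
    task_schedule, spec=None, params=None, n_trials=60, seed=0
) -> ChoiceSequence:
    """A reproducible synthetic session (default: a mid-range PVL2 agent)."""
    spec = spec or ModelSpec("PU2", "DRL", "TIC")
    params = params or (0.5, 1.5, 0.7, 1.0)
    cfg = AgentConfig(spec=spec, params=params, n_trials=n_trials, seed=seed)
    return simulate_agent(cfg, task_schedule)


@pytest.fixture()
def pvl2_igt_sequence(igt) -> ChoiceSequence:
    return make_sequence(igt, n_trials=60, seed=11)


@pytest.fixture()
def pvl2_sgt_sequence(sgt) -> ChoiceSequence:
    return make_sequence(sgt, n_trials=60, seed=12)
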