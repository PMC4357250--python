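"""Payoff schedules and card dealing for the Iowa and Soochow Gambling Tasks.

Both tasks present four decks (A–D). Each deck's payoffs follow a fixed,
published block structure: the Iowa Gambling Task (IGT) repeats a 10-trial
block per deck, the Soochow Gambling Task (SGT) a 5-trial block. The order of
outcomes within each block is randomized, but every completed block contains
exactly the printed multiset of outcomes, so per-block net payoffs are exact
(no sampling error). Decks are inexhaustible: blocks repeat indefinitely.

Monetary amounts are in dollars. Losses are stored as nonnegative magnitudes;
the published tables print them with a negative sign, which is notation only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

DECKS = ("A", "B", "C", "D")

IGT = "IGT"
SGT = "SGT"


class TrialOutcome(NamedTuple):
    """A single card's payoff: gain amount and loss magnitude, both >= 0."""

    win: float
    loss: float

    @property
    def net(self) -> float:
        return self.win - self.loss


@dataclass(frozen=True)
class DeckSpec:
    """One deck's repeating payoff block.

    ``gains[i]`` and ``losses[i]`` together form the i-th card of the block;
    both are nonnegative magnitudes of equal length ``block_length``.
    """

    deck_id: str
    block_length: int
    gains: tuple[float, ...]
    losses: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.deck_id not in DECKS:
            raise ValueError(f"unknown deck label {self.deck_id!r}")
        if self.block_length <= 0:
            raise ValueError("block_length must be positive")
        if len(self.gains) != self.block_length or len(self.losses) != self.block_length:
            raise ValueError("gains and losses must each have block_length entries")
        if any(g < 0 for g in self.gains) or any(l < 0 for l in self.losses):
            raise ValueError("gains and losses are stored as nonnegative magnitudes")

    @property
    def block_net(self) -> float:
        return float(sum(self.gains) - sum(self.losses))

    def outcomes(self) -> list[TrialOutcome]:
        return [TrialOutcome(g, l) for g, l in zip(self.gains, self.losses)]


@dataclass(frozen=True)
class PayoffSchedule:
    """The four-deck payoff structure of one task (IGT or SGT)."""

    task_id: str
    decks: dict[str, DeckSpec]

    def __post_init__(self) -> None:
        if self.task_id not in (IGT, SGT):
            raise ValueError(f"unknown task {self.task_id!r}")
        if set(self.decks) != set(DECKS):
            raise ValueError("schedule must define decks A, B, C and D")

    def deck(self, deck_id: str) -> DeckSpec:
        try:
            return self.decks[deck_id]
        except KeyError:
            raise KeyError(f"unknown deck label {deck_id!r}") from None


def build_igt_schedule() -> PayoffSchedule:
    """The IGT payoff distribution.

    Decks A and B pay a $1.00 gain on every card, C and D $0.50. Per 10-card
    block, A carries five additional losses {1.50, 2.00, 2.50, 3.00, 3.50},
    B one loss of 12.50, C five losses {0.25, 0.50, 0.50, 0.50, 0.75}, and
    D one loss of 2.50, so A/B net −$2.50 and C/D net +$2.50 per block.
    """

    def deck(deck_id: str, gain: float, loss_amounts: list[float]) -> DeckSpec:
        losses = tuple(loss_amounts) + (0.0,) * (10 - len(loss_amounts))
        return DeckSpec(deck_id, 10, (gain,) * 10, losses)

    return PayoffSchedule(
        IGT,
        {
            "A": deck("A", 1.00, [1.50, 2.00, 2.50, 3.00, 3.50]),
            "B": deck("B", 1.00, [12.50]),
            "C": deck("C", 0.50, [0.25, 0.50, 0.50, 0.50, 0.75]),
            "D": deck("D", 0.50, [2.50]),
        },
    )


def build_sgt_schedule() -> PayoffSchedule:
    """The SGT payoff distribution.

    Every card is a pure gain or a pure loss, in 5-card blocks:
    A = four gains of $1.00 and one loss of $5.25, B = four gains of $0.50 and
    one loss of $3.25, C = four losses of $1.00 and one gain of $5.25, D = four
    losses of $0.50 and one gain of $3.25. Expected values per 10 trials match
    the IGT (A/B −$2.50, C/D +$2.50) while gain-loss frequency is reversed.
    """

    def deck(deck_id: str, payoffs: list[float]) -> DeckSpec:
        gains = tuple(p if p > 0 else 0.0 for p in payoffs)
        losses = tuple(-p if p < 0 else 0.0 for p in payoffs)
        return DeckSpec(deck_id, 5, gains, losses)

    return PayoffSchedule(
        SGT,
        {
            "A": deck("A", [1.00, 1.00, 1.00, 1.00, -5.25]),
            "B": deck("B", [0.50, 0.50, 0.50, 0.50, -3.25]),
            "C": deck("C", [-1.00, -1.00, -1.00, -1.00, 5.25]),
            "D": deck("D", [-0.50, -0.50, -0.50, -0.50, 3.25]),
        },
    )


def get_schedule(task_id: str) -> PayoffSchedule:
    """Schedule lookup by task label ("IGT" or "SGT")."""
    if task_id == IGT:
        return build_igt_schedule()
    if task_id == SGT:
        return build_sgt_schedule()
    raise ValueError(f"unknown task {task_id!r}")


def block_expected_value(schedule: PayoffSchedule, deck: str, per_trials: int = 10) -> float:
    """Net expected payoff of ``deck`` over ``per_trials`` trials.

    ``per_trials`` must be a positive multiple of the deck's block length;
    the value is exact because blocks are dealt as complete permutations.
    """
    spec = schedule.deck(deck)
    if per_trials <= 0 or per_trials % spec.block_length != 0:
        raise ValueError(
            f"per_trials={per_trials} is not a positive multiple of "
            f"block_length={spec.block_length}"
        )
    return spec.block_net * (per_trials // spec.block_length)


@dataclass
class ValidationReport:
    passed: bool
    violations: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.passed


def validate_schedule(schedule: PayoffSchedule) -> ValidationReport:
    """Check a schedule against the published block structure.

    Verifies block lengths (10 for IGT, 5 for SGT), loss-frequency counts
    (IGT: 5/1/5/1 loss cards per block for A/B/C/D), the SGT pure-outcome
    property (every card is a gain or a loss, never both), and the ±$2.50
    expected value per 10 trials of every deck.
    """
    violations: list[str] = []
    expected_block = {IGT: 10, SGT: 5}[schedule.task_id]
    expected_ev = {"A": -2.50, "B": -2.50, "C": 2.50, "D": 2.50}

    for deck_id in DECKS:
        spec = schedule.deck(deck_id)
        if spec.block_length != expected_block:
            violations.append(
                f"deck {deck_id}: block_length {spec.block_length} != {expected_block}"
            )
            continue
        ev10 = spec.block_net * (10 / spec.block_length)
        if abs(ev10 - expected_ev[deck_id]) > 1e-9:
            violations.append(
                f"deck {deck_id}: expected value per 10 trials {ev10:+.2f} "
                f"!= {expected_ev[deck_id]:+.2f}"
            )
        if schedule.task_id == IGT:
            n_losses = sum(1 for l in spec.losses if l > 0)
            expected_losses = {"A": 5, "B": 1, "C": 5, "D": 1}[deck_id]
            if n_losses != expected_losses:
                violations.append(
                    f"deck {deck_id}: {n_losses} loss cards per block, expected {expected_losses}"
                )
        else:
            for i, (g, l) in enumerate(zip(spec.gains, spec.losses)):
                if g > 0 and l > 0:
                    violations.append(
                        f"deck {deck_id} card {i + 1}: both gain and loss nonzero "
                        "(SGT cards are pure gains or pure losses)"
                    )
                if g == 0 and l == 0:
                    violations.append(
                        f"deck {deck_id} card {i + 1}: null card (SGT cards always pay out)"
                    )
    return ValidationReport(passed=not violations, violations=violations)


class DeckDealer:
    """Stateful dealer over a schedule with within-block randomization.

    Each deck is dealt as an endless stream of blocks; within each block the
    printed outcomes appear in a fresh uniformly random order. The stream is
    bit-reproducible given ``rng_seed``: each deck gets its own child RNG, so
    draws from one deck never perturb another deck's stream.
    """

    def __init__(self, schedule: PayoffSchedule, rng_seed):
        self.schedule = schedule
        self.rng_seed = rng_seed
        if not isinstance(rng_seed, np.random.SeedSequence):
            rng_seed = np.random.SeedSequence(rng_seed)
        seqs = rng_seed.spawn(len(DECKS))
        self._rngs = {d: np.random.default_rng(s) for d, s in zip(DECKS, seqs)}
        self._queues: dict[str, list[TrialOutcome]] = {d: [] for d in DECKS}
        self.draw_counts: dict[str, int] = {d: 0 for d in DECKS}

    def draw(self, deck: str) -> TrialOutcome:
        """Deal the next card from ``deck``."""
        if deck not in DECKS:
            raise KeyError(f"unknown deck label {deck!r}")
        queue = self._queues[deck]
        if not queue:
            outcomes = self.schedule.deck(deck).outcomes()
            order = self._rngs[deck].permutation(len(outcomes))
            queue.extend(outcomes[i] for i in order)
        self.draw_counts[deck] += 1
        return queue.pop(0)


def draw_outcome(dealer: DeckDealer, deck: str) -> TrialOutcome:
    """Functional alias for :meth:`DeckDealer.draw`."""
    return dealer.draw(deck)


def schedule_to_table(schedule: PayoffSchedule):
    """Export a schedule as a tidy table (task, deck, trial_in_block, gain, loss)."""
    import pandas as pd

    rows = [
        (schedule.task_id, deck_id, i + 1, g, l)
        for deck_id in DECKS
        for i, (g, l) in enumerate(
            zip(schedule.deck(deck_id).gains, schedule.deck(deck_id).losses)
        )
    ]
    return pd.DataFrame(rows, columns=["task", "deck", "trial_in_block", "gain", "loss"])


def schedule_from_table(table) -> PayoffSchedule:
    """Rebuild a :class:`PayoffSchedule` from :func:`schedule_to_table` output."""
    tasks = table["task"].unique()
    if len(tasks) != 1:
        raise ValueError("table must describe exactly one task")
    decks = {}
    for deck_id, grp in table.groupby("deck"):
        grp = grp.sort_values("trial_in_block")
        decks[deck_id] = DeckSpec(
            deck_id,
            len(grp),
            tuple(float(g) for g in grp["gain"]),
            tuple(float(l) for l in grp["loss"]),
        )
    return PayoffSchedule(str(tasks[0]), decks)
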