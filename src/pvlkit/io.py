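"""Delimited-file formats for trial data and fit results.

Trial files are UTF-8 CSV with a header and one row per trial:
``participant_id, task, trial, deck, gain, loss``. Trial indices are 1-based
and must be consecutive within each (participant, task) pair. Losses may be
written with either sign (published payoff tables print them negative); they
are normalized to magnitudes on read.

Fit tables have one row per (participant, task, model) with a fixed column
order; parameter columns are the union over models, blank where a model does
not use a parameter.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .comparison import ModelSummary, summaries_to_frame
from .fitting import ChoiceSequence, FitResult
from .model_space import ModelSpec
from .task_engine import DECKS, IGT, SGT

logger = logging.getLogger(__name__)

TRIAL_COLUMNS = ["participant_id", "task", "trial", "deck", "gain", "loss"]
PARAM_COLUMNS = ["W", "alpha", "lam", "gamma", "A", "D", "c"]
FIT_COLUMNS = (
    ["participant_id", "task", "model"]
    + PARAM_COLUMNS
    + ["loglik", "baseline_loglik", "bic_diff", "n_predicted", "converged", "n_starts_used"]
)


class TrialFileError(ValueError):
    """Structured parse error naming the offending row(s)."""


def read_trials(path) -> list[ChoiceSequence]:
    """Read and validate a trial CSV into per-(participant, task) sequences.

    Negative loss values are accepted and normalized to magnitudes; a file
    mixing signs in the loss column triggers a warning (it usually indicates
    inconsistent export conventions).
    """
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialFileError(f"{path}: missing columns {missing}")

    bad_task = df.index[~df["task"].isin([IGT, SGT])]
    if len(bad_task):
        raise TrialFileError(
            f"{path}: unknown task {df.loc[bad_task[0], 'task']!r} at row {bad_task[0] + 2}"
        )
    bad_deck = df.index[~df["deck"].isin(DECKS)]
    if len(bad_deck):
        raise TrialFileError(
            f"{path}: unknown deck {df.loc[bad_deck[0], 'deck']!r} at row {bad_deck[0] + 2}"
        )
    if (df["loss"] < 0).any() and (df["loss"] > 0).any():
        logger.warning("%s: loss column mixes signs; normalizing to magnitudes", path)
    df = df.assign(loss=df["loss"].abs())
    if (df["gain"] < 0).any():
        row = int(df.index[df["gain"] < 0][0])
        raise TrialFileError(f"{path}: negative gain at row {row + 2}")

    sequences = []
    for (pid, task), grp in df.groupby(["participant_id", "task"], sort=True):
        grp = grp.sort_values("trial")
        trials_idx = grp["trial"].to_numpy()
        expected = np.arange(1, len(grp) + 1)
        if len(np.unique(trials_idx)) != len(trials_idx):
            raise TrialFileError(f"{path}: duplicate trial index for ({pid}, {task})")
        if not np.array_equal(trials_idx, expected):
            raise TrialFileError(
                f"{path}: trials for ({pid}, {task}) are not consecutive from 1"
            )
        trials = list(
            zip(grp["deck"], grp["gain"].astype(float), grp["loss"].astype(float))
        )
        sequences.append(ChoiceSequence(str(task), trials, participant_id=str(pid)))
    return sequences


def write_trials(sequences: Sequence[ChoiceSequence], path) -> Path:
    """Write sequences to the trial CSV format (losses as magnitudes)."""
    rows = [
        (seq.participant_id, seq.task_id, t + 1, deck, win, loss)
        for seq in sequences
        for t, (deck, win, loss) in enumerate(seq.trials)
    ]
    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def fits_to_frame(fits: Iterable[FitResult]) -> pd.DataFrame:
    """Fit results as a table with deterministic column order."""
    rows = []
    for fit in fits:
        row = {c: np.nan for c in PARAM_COLUMNS}
        row.update(fit.param_dict)
        rows.append(
            {
                "participant_id": fit.participant_id,
                "task": fit.task_id,
                "model": str(fit.spec),
                **row,
                "loglik": fit.loglik,
                "baseline_loglik": fit.baseline_loglik,
                "bic_diff": fit.bic_diff,
                "n_predicted": fit.n_predicted,
                "converged": fit.converged,
                "n_starts_used": fit.n_starts_used,
            }
        )
    return pd.DataFrame(rows, columns=FIT_COLUMNS)


def frame_to_fits(df: pd.DataFrame) -> list[FitResult]:
    """Rebuild :class:`FitResult` objects from a fit table (round-trip inverse)."""
    fits = []
    for _, row in df.iterrows():
        spec = ModelSpec.from_string(row["model"])
        params = tuple(float(row[name]) for name in spec.parameter_names)
        fits.append(
            FitResult(
                spec=spec,
                params=params,
                loglik=float(row["loglik"]),
                bic_diff=float(row["bic_diff"]),
                baseline_loglik=float(row["baseline_loglik"]),
                n_predicted=int(row["n_predicted"]),
                converged=bool(row["converged"]),
                n_starts_used=int(row["n_starts_used"]),
                participant_id=None if pd.isna(row["participant_id"]) else str(row["participant_id"]),
                task_id=None if pd.isna(row["task"]) else str(row["task"]),
            )
        )
    return fits


def write_fits(fits: Sequence[FitResult], path) -> Path:
    path = Path(path)
    fits_to_frame(fits).to_csv(path, index=False)
    return path


def read_fits(path) -> list[FitResult]:
    return frame_to_fits(pd.read_csv(path))


def write_results(
    fits: Sequence[FitResult],
    summaries: Sequence[ModelSummary],
    outdir,
) -> dict[str, Path]:
    """Write a fit table and a summary table under ``outdir``.

    Empty summary lists still produce a header-only file (with a warning), so
    downstream tooling can rely on both files existing.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"fits": write_fits(fits, outdir / "fits.csv")}
    if not summaries:
        logger.warning("no summaries to write; emitting header-only file")
    summaries_to_frame(list(summaries)).reindex(
        columns=["model", "task", "n", "M", "Mdn", "SD", "pct_BIC_positive"]
    ).to_csv(outdir / "summaries.csv", index=False)
    paths["summaries"] = outdir / "summaries.csv"
    return paths
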