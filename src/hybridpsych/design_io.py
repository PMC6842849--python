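"""Session designs, response coding and tabular I/O.

The two classification experiments share one design family: eight conditions,
each presenting every log visible-energy ratio from an 11-level set a fixed
number of times (8 copies -> 704 trials; 10 copies -> 880 trials), with all
conditions randomly interleaved within a session.

In the first experiment each condition fixes either the cardinal or the
intercardinal component's category (animal, flower, house or vehicle) and
draws the other component's category at random from the remaining three.  In
the second, four category pairs (big/small animal x big/small man-made) are
each presented with both filter assignments, so both categories are fixed.

Trials are plain records; sessions round-trip through UTF-8 comma-separated
files with a header row, one trial per row.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LOG_RATIO_LEVELS",
    "RANDOM_FROM_SET",
    "EXP1_CATEGORIES",
    "EXP2_CATEGORIES",
    "DataError",
    "Condition",
    "TrialRecord",
    "experiment1_conditions",
    "experiment2_conditions",
    "generate_session",
    "generate_experiment_session",
    "code_response",
    "records_to_frame",
    "frame_to_records",
    "write_session",
    "read_session",
]

#: The 11 log visible-energy ratio levels (natural log, cardinal/intercardinal).
LOG_RATIO_LEVELS: tuple[float, ...] = (
    -3.66, -2.20, -1.39, -0.41, -0.20, 0.0, 0.20, 0.41, 1.39, 2.20, 3.66,
)

#: Sentinel: draw this component's category at random from the remaining set.
RANDOM_FROM_SET = "random-from-set"

EXP1_CATEGORIES: tuple[str, ...] = ("animal", "flower", "house", "vehicle")
EXP2_CATEGORIES: tuple[str, ...] = ("BA", "BM", "SA", "SM")


class DataError(ValueError):
    """A trial table violates the design contract."""


@dataclass(frozen=True)
class Condition:
    """One hybrid condition: which categories fill the two filter bands."""

    name: str
    cardinal_category: str
    intercardinal_category: str


@dataclass
class TrialRecord:
    """One classification trial."""

    session_id: str
    trial_index: int
    condition: str
    log_ratio: float
    cardinal_category: str
    intercardinal_category: str
    response_category: str | None = None
    response_is_cardinal: str | None = None  # "cardinal" / "intercardinal" / "neither"


def experiment1_conditions() -> list[Condition]:
    """CA/CF/CH/CV fix the cardinal category; IA/IF/IH/IV the intercardinal."""
    conds = []
    for cat in EXP1_CATEGORIES:
        conds.append(Condition(f"C{cat[0].upper()}", cat, RANDOM_FROM_SET))
    for cat in EXP1_CATEGORIES:
        conds.append(Condition(f"I{cat[0].upper()}", RANDOM_FROM_SET, cat))
    return conds


def experiment2_conditions() -> list[Condition]:
    """Four category pairs, each under both filter assignments."""
    pairs = (("BA", "BM"), ("BA", "SM"), ("SA", "BM"), ("SA", "SM"))
    conds = []
    for first, second in pairs:
        conds.append(Condition(f"{first}-{second}-cardinal", first, second))
    for first, second in pairs:
        conds.append(Condition(f"{first}-{second}-intercardinal", second, first))
    return conds


def generate_session(
    conditions: Sequence[Condition],
    levels: Sequence[float] = LOG_RATIO_LEVELS,
    copies: int = 8,
    seed: int | None = None,
    categories: Sequence[str] | None = None,
    session_id: str = "session",
) -> list[TrialRecord]:
    """Build a randomized, interleaved trial list.

    Each condition contributes ``copies`` trials at every level; a
    random-from-set component category is drawn uniformly from ``categories``
    minus the condition's fixed category, independently per trial.  The pooled
    list is globally shuffled.  Fully reproducible from ``seed``.
    """
    if copies < 1:
        raise ValueError("copies must be >= 1")
    if not levels:
        raise ValueError("levels must be nonempty")
    rng = np.random.default_rng(seed)
    categories = tuple(categories) if categories else EXP1_CATEGORIES

    trials: list[TrialRecord] = []
    for cond in conditions:
        for level in levels:
            for _ in range(copies):
                card, inter = cond.cardinal_category, cond.intercardinal_category
                if card == RANDOM_FROM_SET:
                    card = rng.choice([c for c in categories if c != inter])
                elif inter == RANDOM_FROM_SET:
                    inter = rng.choice([c for c in categories if c != card])
                if card == inter:
                    raise DataError(
                        f"condition {cond.name!r} realized identical categories"
                    )
                trials.append(
                    TrialRecord(
                        session_id=session_id,
                        trial_index=-1,
                        condition=cond.name,
                        log_ratio=float(level),
                        cardinal_category=str(card),
                        intercardinal_category=str(inter),
                    )
                )
    rng.shuffle(trials)
    for i, t in enumerate(trials):
        t.trial_index = i
    return trials


def generate_experiment_session(
    experiment: int, seed: int | None = None, session_id: str = "session"
) -> list[TrialRecord]:
    """Preset designs: experiment 1 -> 704 trials; experiment 2 -> 880."""
    if experiment == 1:
        return generate_session(
            experiment1_conditions(), LOG_RATIO_LEVELS, copies=8, seed=seed,
            categories=EXP1_CATEGORIES, session_id=session_id,
        )
    if experiment == 2:
        return generate_session(
            experiment2_conditions(), LOG_RATIO_LEVELS, copies=10, seed=seed,
            categories=EXP2_CATEGORIES, session_id=session_id,
        )
    raise ValueError(f"experiment must be 1 or 2, got {experiment}")


def code_response(
    trial: TrialRecord,
    valid_labels: Sequence[str] | None = None,
) -> TrialRecord:
    """Code a raw 4-alternative response against the trial's components.

    Returns a copy with ``response_is_cardinal`` set to "cardinal" if the
    response names the cardinal component's category, "intercardinal" if it
    names the intercardinal one, and "neither" otherwise (a shown label whose
    category was absent from this hybrid).  How "neither" enters the binomial
    denominator is an analysis-time policy (see psychometrics).
    """
    if trial.response_category is None:
        raise DataError("trial has no recorded response")
    if valid_labels is not None and trial.response_category not in valid_labels:
        raise DataError(
            f"response {trial.response_category!r} not among shown labels {valid_labels}"
        )
    if trial.response_category == trial.cardinal_category:
        coded = "cardinal"
    elif trial.response_category == trial.intercardinal_category:
        coded = "intercardinal"
    else:
        coded = "neither"
    return replace(trial, response_is_cardinal=coded)


# --------------------------------------------------------------------------
# tabular I/O

_COLUMNS = [
    "session_id", "trial_index", "condition", "log_ratio",
    "cardinal_category", "intercardinal_category",
    "response_category", "response_is_cardinal",
]


def records_to_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records], columns=_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[TrialRecord]:
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            TrialRecord(
                session_id=str(row.session_id),
                trial_index=int(row.trial_index),
                condition=str(row.condition),
                log_ratio=float(row.log_ratio),
                cardinal_category=str(row.cardinal_category),
                intercardinal_category=str(row.intercardinal_category),
                response_category=None if pd.isna(row.response_category) else str(row.response_category),
                response_is_cardinal=None if pd.isna(row.response_is_cardinal) else str(row.response_is_cardinal),
            )
        )
    return records


def write_session(records: Sequence[TrialRecord] | pd.DataFrame, path: str | Path) -> None:
    """Write a session as UTF-8 CSV, one trial per row."""
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    frame.to_csv(path, index=False, encoding="utf-8")


def read_session(path: str | Path) -> pd.DataFrame:
    """Read a session CSV written by :func:`write_session`."""
    frame = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in _COLUMNS[:6] if c not in frame.columns]
    if missing:
        raise DataError(f"session file {path!r} lacks columns {missing}")
    return frame
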