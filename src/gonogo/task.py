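"""Motivational Go/NoGo task generation.

The task crosses cue valence (Win: reward vs. nothing; Avoid: nothing vs.
punishment) with required action (Go: press; NoGo: withhold). A session
consists of ``n_blocks`` blocks; each block introduces a fresh set of four
cues, one per valence-by-action cell, each repeated ``repetitions_per_cue``
times in a uniformly random order. Feedback is probabilistic: a correct
response yields the desired outcome (reward, or omitted punishment) with
probability ``feedback_validity`` (default 0.8), an incorrect response with
probability ``1 - feedback_validity``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

WIN = "win"
AVOID = "avoid"
GO = "go"
NOGO = "nogo"

VALENCES = (WIN, AVOID)
ACTIONS = (GO, NOGO)

#: valence-by-required-action cells, in the fixed order used for cue ids
CUE_CELLS = ((WIN, GO), (WIN, NOGO), (AVOID, GO), (AVOID, NOGO))


class ConfigurationError(ValueError):
    """Raised when a task configuration is internally inconsistent."""


@dataclass(frozen=True)
class Cue:
    """One task cue: an (initially unknown) valence and a required action."""

    id: int
    valence: str
    required_action: str

    def __post_init__(self) -> None:
        if self.valence not in VALENCES:
            raise ValueError(f"valence must be one of {VALENCES}, got {self.valence!r}")
        if self.required_action not in ACTIONS:
            raise ValueError(
                f"required_action must be one of {ACTIONS}, got {self.required_action!r}"
            )

    @property
    def valence_value(self) -> float:
        """Cue valence V: +0.5 for Win cues, -0.5 for Avoid cues."""
        return 0.5 if self.valence == WIN else -0.5


@dataclass
class TrialRecord:
    """One trial of the task; response/outcome are unset until played."""

    session_id: str
    block_index: int  # 1-based
    trial_index_in_block: int  # 1-based
    cue: Cue
    response: str | None = None
    outcome: int | None = None
    # pre-drawn feedback validity flag (exact-ratio mode only)
    feedback_valid: bool | None = None

    @property
    def complete(self) -> bool:
        return self.response is not None and self.outcome is not None


@dataclass(frozen=True)
class TaskConfig:
    """Design constants of a session; defaults reproduce the standard task."""

    n_blocks: int = 4
    trials_per_block: int = 80
    cues_per_block: int = 4
    repetitions_per_cue: int = 20
    feedback_validity: float = 0.8
    reward_magnitude: int = 1
    punishment_magnitude: int = -1
    neutral_magnitude: int = 0
    #: draw exactly round(validity * repetitions) valid-feedback trials per cue
    exact_feedback_ratio: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.trials_per_block != self.cues_per_block * self.repetitions_per_cue:
            raise ConfigurationError(
                "trials_per_block must equal cues_per_block * repetitions_per_cue "
                f"({self.trials_per_block} != {self.cues_per_block} x "
                f"{self.repetitions_per_cue})"
            )
        if self.cues_per_block != len(CUE_CELLS):
            raise ConfigurationError(
                "cues_per_block must be 4 (one cue per valence x required-action cell)"
            )
        if not 0.0 < self.feedback_validity <= 1.0:
            raise ConfigurationError("feedback_validity must lie in (0, 1]")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    @classmethod
    def from_file(cls, path: str | Path) -> "TaskConfig":
        """Load a config from YAML or JSON mirroring the field names."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def make_cues(block_index: int, cues_per_block: int = 4) -> list[Cue]:
    """Fresh cues for one (1-based) block, one per valence x action cell."""
    base = (block_index - 1) * cues_per_block
    return [
        Cue(id=base + i, valence=v, required_action=a)
        for i, (v, a) in enumerate(CUE_CELLS)
    ]


def make_session(
    config: TaskConfig | None = None,
    rng: np.random.Generator | int | None = None,
    session_id: str = "s1",
) -> list[TrialRecord]:
    """Generate one session's cue schedule with responses/outcomes unset.

    Each block gets its own child random stream derived from the session
    stream, so regenerating block k does not depend on the other blocks.
    """
    config = config or TaskConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    block_rngs = rng.spawn(config.n_blocks)
    trials: list[TrialRecord] = []
    for b in range(1, config.n_blocks + 1):
        brng = block_rngs[b - 1]
        cues = make_cues(b, config.cues_per_block)
        schedule = np.repeat(np.arange(config.cues_per_block), config.repetitions_per_cue)
        brng.shuffle(schedule)
        valid_flags: dict[int, list[bool]] | None = None
        if config.exact_feedback_ratio:
            n_valid = int(round(config.feedback_validity * config.repetitions_per_cue))
            valid_flags = {}
            for c in range(config.cues_per_block):
                flags = np.array(
                    [True] * n_valid
                    + [False] * (config.repetitions_per_cue - n_valid)
                )
                brng.shuffle(flags)
                valid_flags[c] = list(flags)
        seen: dict[int, int] = {c: 0 for c in range(config.cues_per_block)}
        for t, c in enumerate(schedule, start=1):
            fv = None
            if valid_flags is not None:
                fv = bool(valid_flags[int(c)][seen[int(c)]])
                seen[int(c)] += 1
            trials.append(
                TrialRecord(
                    session_id=session_id,
                    block_index=b,
                    trial_index_in_block=t,
                    cue=cues[int(c)],
                    feedback_valid=fv,
                )
            )
    return trials


def sample_feedback(
    cue: Cue,
    response: str,
    validity: float,
    rng: np.random.Generator,
    valid: bool | None = None,
) -> int:
    """Sample a trial outcome r in {-1, 0, +1}.

    Win cues yield +1 or 0; Avoid cues yield 0 or -1. A correct response
    obtains the desired outcome with probability ``validity``; an incorrect
    response with probability ``1 - validity``. Pass ``valid`` to force the
    feedback-validity draw (exact-ratio mode).
    """
    if response not in ACTIONS:
        raise ValueError(f"response must be one of {ACTIONS}, got {response!r}")
    correct = response == cue.required_action
    if valid is None:
        valid = bool(rng.random() < validity)
    desired = correct == valid  # desired outcome iff (correct and valid) or (incorrect and invalid)
    if cue.valence == WIN:
        return 1 if desired else 0
    return 0 if desired else -1


# ---------------------------------------------------------------------------
# tabular I/O and array views

_COLUMNS = [
    "subject",
    "session",
    "block",
    "trial",
    "cue_id",
    "valence",
    "required_action",
    "response",
    "outcome",
]


def trials_to_frame(trials: Sequence[TrialRecord], subject: str = "sub1") -> pd.DataFrame:
    """Tidy trial table (one row per trial, 1-based indices, NA for unset)."""
    rows = []
    for t in trials:
        rows.append(
            {
                "subject": subject,
                "session": t.session_id,
                "block": t.block_index,
                "trial": t.trial_index_in_block,
                "cue_id": t.cue.id,
                "valence": t.cue.valence,
                "required_action": t.cue.required_action,
                "response": t.response if t.response is not None else pd.NA,
                "outcome": t.outcome if t.outcome is not None else pd.NA,
            }
        )
    return pd.DataFrame(rows, columns=_COLUMNS)


def frame_to_trials(df: pd.DataFrame) -> list[TrialRecord]:
    """Inverse of :func:`trials_to_frame` for a single subject/session."""
    trials = []
    for row in df.itertuples(index=False):
        resp = None if pd.isna(row.response) else str(row.response)
        out = None if pd.isna(row.outcome) else int(row.outcome)
        trials.append(
            TrialRecord(
                session_id=str(row.session),
                block_index=int(row.block),
                trial_index_in_block=int(row.trial),
                cue=Cue(
                    id=int(row.cue_id),
                    valence=str(row.valence),
                    required_action=str(row.required_action),
                ),
                response=resp,
                outcome=out,
            )
        )
    return trials


def write_trials(path: str | Path, trials: Sequence[TrialRecord], subject: str = "sub1") -> None:
    sep = "\t" if str(path).endswith(".tsv") else ","
    trials_to_frame(trials, subject=subject).to_csv(path, sep=sep, index=False)


def read_trials(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith(".tsv") else ","
    return pd.read_csv(path, sep=sep)


@dataclass(frozen=True)
class TrialArrays:
    """Dense array view of an ordered trial list for the fast likelihood."""

    cue_idx: np.ndarray  # int64, dense 0..n_cues-1, order of first appearance
    cue_val: np.ndarray  # float64 per cue: +0.5 win / -0.5 avoid
    response: np.ndarray  # int8: 1 go, 0 nogo
    outcome: np.ndarray  # float64 in {-1, 0, +1}
    required: np.ndarray  # int8 per trial: 1 go, 0 nogo
    cue_ids: tuple = field(default=())  # original cue ids per dense index


def trials_to_arrays(trials: Sequence[TrialRecord]) -> TrialArrays:
    """Convert completed, ordered trials to arrays. Raises on unset fields."""
    n = len(trials)
    index: dict[int, int] = {}
    cue_val: list[float] = []
    cue_idx = np.empty(n, dtype=np.int64)
    response = np.empty(n, dtype=np.int8)
    outcome = np.empty(n, dtype=np.float64)
    required = np.empty(n, dtype=np.int8)
    for i, t in enumerate(trials):
        if not t.complete:
            raise ValueError(f"trial {i} has unset response/outcome")
        ci = index.setdefault(t.cue.id, len(index))
        if ci == len(cue_val):
            cue_val.append(t.cue.valence_value)
        cue_idx[i] = ci
        response[i] = 1 if t.response == GO else 0
        outcome[i] = float(t.outcome)
        required[i] = 1 if t.cue.required_action == GO else 0
    return TrialArrays(
        cue_idx=cue_idx,
        cue_val=np.asarray(cue_val, dtype=np.float64),
        response=response,
        outcome=outcome,
        required=required,
        cue_ids=tuple(index.keys()),
    )
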