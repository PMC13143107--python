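"""Simulate choice data from the model family and run posterior predictions.

``simulate_subject`` plays a model through a task session, sampling responses
from the softmax choice rule and outcomes from the probabilistic feedback
schedule. ``one_step_ahead`` computes the model's pre-choice p(Go) on each
trial of an *observed* dataset, conditioning on the subject's actual choices
and outcomes — the posterior predictive check used to compare fitted models
against behavior.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .models import (
    ModelSpec,
    ParameterVector,
    choice_probability,
    action_weights,
    init_state,
    predicted_go_probabilities,
    update_state,
    _unique_cues,
)
from .task import GO, NOGO, TrialRecord, sample_feedback


@dataclass
class SimulatedDataset:
    """Completed trials plus the generating model and parameters."""

    trials: list[TrialRecord]
    generating_model: ModelSpec
    generating_params: ParameterVector
    seed: int | None = None


def simulate_subject(
    task: Sequence[TrialRecord],
    params: ParameterVector,
    rng: np.random.Generator | int,
    validity: float = 0.8,
    seed: int | None = None,
) -> SimulatedDataset:
    """Play ``params`` through a session whose responses are unset.

    Iterates trials in order: samples a response from the choice rule,
    samples feedback, updates the agent state. The input session is not
    modified; completed copies are returned.
    """
    if not isinstance(rng, np.random.Generator):
        seed = int(rng)
        rng = np.random.default_rng(rng)
    state = init_state(_unique_cues(task), params)
    out: list[TrialRecord] = []
    for t in task:
        if t.response is not None:
            raise ValueError("task session must have responses unset")
        p_go = choice_probability(action_weights(state, t.cue, params))
        resp = GO if rng.random() < p_go else NOGO
        r = sample_feedback(t.cue, resp, validity, rng, valid=t.feedback_valid)
        update_state(state, t.cue, resp, r, params)
        out.append(dataclasses.replace(t, response=resp, outcome=r))
    return SimulatedDataset(
        trials=out, generating_model=params.spec, generating_params=params, seed=seed
    )


def one_step_ahead(
    trials: Sequence[TrialRecord],
    params: ParameterVector,
    spec: ModelSpec | None = None,
) -> np.ndarray:
    """Per-trial pre-choice p(Go), evolving state with the observed data.

    No sampling is involved; the returned probabilities are exactly the
    per-trial likelihood contributions (for Go responses) of
    :func:`gonogo.models.sequence_log_likelihood`.
    """
    for i, t in enumerate(trials):
        if not t.complete:
            raise ValueError(f"trial {i} incomplete; one-step-ahead needs observed data")
    if spec is not None and spec.model_id != params.spec.model_id:
        raise ValueError("spec does not match params.spec")
    return predicted_go_probabilities(trials, params)


def _curve_rows(
    trials: Sequence[TrialRecord], values: np.ndarray | None, subject: str
) -> list[dict]:
    reps: dict[int, int] = {}
    rows = []
    for i, t in enumerate(trials):
        reps[t.cue.id] = reps.get(t.cue.id, 0) + 1
        if values is None:
            val = 1.0 if t.response == GO else 0.0
        else:
            val = float(values[i])
        rows.append(
            {
                "subject": subject,
                "valence": t.cue.valence,
                "required_action": t.cue.required_action,
                "repetition": reps[t.cue.id],
                "value": val,
            }
        )
    return rows


def summarize_curves(
    trials_by_subject: Mapping[str, Sequence[TrialRecord]],
    probabilities: Mapping[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Trial-by-trial learning curves by cue condition.

    Groups by (valence x required action) and cue-repetition index (1-based
    encounter number of each cue), averaging first within subject and then
    across subjects; SEM is across subjects. ``probabilities`` switches from
    observed Go indicators to model p(Go) values (e.g. one-step-ahead).
    Returns tidy columns: valence, required_action, repetition, mean, sem, n.
    Conditions with no observations appear with NaN mean and n = 0.
    """
    if not trials_by_subject:
        raise ValueError("need at least one subject")
    rows: list[dict] = []
    for subject, trials in trials_by_subject.items():
        vals = probabilities.get(subject) if probabilities is not None else None
        rows.extend(_curve_rows(trials, vals, subject))
    df = pd.DataFrame(rows)
    per_subject = (
        df.groupby(["valence", "required_action", "repetition", "subject"])["value"]
        .mean()
        .reset_index()
    )
    grouped = per_subject.groupby(["valence", "required_action", "repetition"])["value"]
    def _sem(s: pd.Series) -> float:
        return float(s.std(ddof=1) / np.sqrt(len(s))) if len(s) > 1 else 0.0

    out = grouped.agg(mean="mean", sem=_sem, n="count")
    out = out.reset_index()
    max_rep = int(df["repetition"].max())
    full = pd.MultiIndex.from_product(
        [["win", "avoid"], ["go", "nogo"], range(1, max_rep + 1)],
        names=["valence", "required_action", "repetition"],
    ).to_frame(index=False)
    out = full.merge(out, how="left", on=["valence", "required_action", "repetition"])
    out["n"] = out["n"].fillna(0).astype(int)
    return out
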