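"""Descriptive bias statistics: Go rates, stay probabilities, effect sizes.

These are the model-free summaries of Pavlovian biases: the response bias
shows as more Go responses to Win than Avoid cues; the learning bias as a
stronger effect of valenced outcomes on response repetition after Go than
after NoGo responses; and the persistence bias as more repetitions for Win
than Avoid cues regardless of outcome. Paired condition contrasts are
quantified with Hedges' g (Cohen's d for the paired difference times the
small-sample factor J = 1 - 3/(4N - 5)) and bootstrap confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .task import GO, TrialRecord

OUTCOME_CONDITIONS = ("go_reward", "go_punishment", "nogo_reward", "nogo_punishment")
VALENCE_CONDITIONS = ("win", "avoid")


def bonferroni_alpha(alpha: float, n_tests: int) -> float:
    """Family-wise-corrected per-test alpha level, alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


@dataclass
class EffectSize:
    """Paired-design Cohen's d, Hedges' g, and bootstrap CI for g."""

    n: int
    mean_diff: float
    sd_diff: float
    cohen_d: float
    j: float
    hedges_g: float
    ci_low: float
    ci_high: float
    n_boot: int


def hedges_j(n: int) -> float:
    """Small-sample correction factor for a paired design (df = N - 1)."""
    return 1.0 - 3.0 / (4.0 * n - 5.0)


def paired_effect(
    x: Sequence[float],
    y: Sequence[float],
    n_boot: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> EffectSize:
    """Effect size of a within-subject contrast x - y.

    Cohen's d is the mean of the paired differences over their standard
    deviation; Hedges' g multiplies d by J = 1 - 3/(4N - 5). The CI
    resamples the difference vector with replacement ``n_boot`` times,
    computes d per resample, takes the 2.5/97.5 percentiles, and multiplies
    them by J.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D paired vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    diff = x - y
    sd = float(diff.std(ddof=1))
    if sd == 0.0:
        raise ValueError("zero variance of paired differences; effect size undefined")
    d = float(diff.mean()) / sd
    j = hedges_j(n)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot = diff[idx]
    boot_sd = boot.std(axis=1, ddof=1)
    valid = boot_sd > 0
    boot_d = boot[valid].mean(axis=1) / boot_sd[valid]
    lo, hi = np.percentile(boot_d, [2.5, 97.5])
    return EffectSize(
        n=n,
        mean_diff=float(diff.mean()),
        sd_diff=sd,
        cohen_d=d,
        j=j,
        hedges_g=d * j,
        ci_low=float(lo * j),
        ci_high=float(hi * j),
        n_boot=n_boot,
    )


def _transitions(trials: Sequence[TrialRecord]):
    """(prev_trial, next_trial) pairs of consecutive encounters per cue."""
    last_by_cue: dict[int, TrialRecord] = {}
    for t in trials:
        if not t.complete:
            raise ValueError("stay probabilities need complete trials")
        prev = last_by_cue.get(t.cue.id)
        if prev is not None:
            yield prev, t
        last_by_cue[t.cue.id] = t


def stay_probabilities(
    trials_by_subject: Mapping[str, Sequence[TrialRecord]],
) -> pd.DataFrame:
    """Probability of repeating a response on the next encounter of a cue.

    Two condition bases are tabulated per subject: ``outcome`` cells cross
    the previous response (Go/NoGo) with the previous outcome restricted to
    valenced outcomes (reward +1 / punishment -1); ``valence`` cells split
    all transitions by cue valence. The last encounter of a cue contributes
    no transition. Cells with no eligible transitions get NaN and n = 0.
    """
    rows = []
    for subject, trials in trials_by_subject.items():
        stays: dict[str, list[int]] = {
            c: [] for c in OUTCOME_CONDITIONS + VALENCE_CONDITIONS
        }
        for prev, nxt in _transitions(trials):
            stay = int(nxt.response == prev.response)
            stays[prev.cue.valence].append(stay)
            if prev.outcome != 0:
                resp = "go" if prev.response == GO else "nogo"
                out = "reward" if prev.outcome == 1 else "punishment"
                stays[f"{resp}_{out}"].append(stay)
        for basis, conds in (("outcome", OUTCOME_CONDITIONS), ("valence", VALENCE_CONDITIONS)):
            for c in conds:
                vals = stays[c]
                rows.append(
                    {
                        "subject": subject,
                        "basis": basis,
                        "condition": c,
                        "p_stay": float(np.mean(vals)) if vals else np.nan,
                        "n": len(vals),
                    }
                )
    return pd.DataFrame(rows)


def go_probability_summary(
    trials_by_subject: Mapping[str, Sequence[TrialRecord]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject p(Go) by valence x required action, plus group summary.

    Returns ``(per_subject, group)``. ``per_subject`` has one row per
    subject and cell plus a ``bias_index`` column repeated per subject:
    p(Go | Win) - p(Go | Avoid). ``group`` aggregates mean and SEM across
    subjects per cell.
    """
    rows = []
    for subject, trials in trials_by_subject.items():
        cells: dict[tuple[str, str], list[int]] = {}
        by_val: dict[str, list[int]] = {"win": [], "avoid": []}
        for t in trials:
            if t.response is None:
                raise ValueError("trials must have responses set")
            is_go = int(t.response == GO)
            cells.setdefault((t.cue.valence, t.cue.required_action), []).append(is_go)
            by_val[t.cue.valence].append(is_go)
        bias = float(np.mean(by_val["win"]) - np.mean(by_val["avoid"]))
        for (val, req), gos in sorted(cells.items()):
            rows.append(
                {
                    "subject": subject,
                    "valence": val,
                    "required_action": req,
                    "p_go": float(np.mean(gos)),
                    "n": len(gos),
                    "bias_index": bias,
                }
            )
    per_subject = pd.DataFrame(rows)
    grouped = per_subject.groupby(["valence", "required_action"])["p_go"]

    def _sem(s: pd.Series) -> float:
        return float(s.std(ddof=1) / np.sqrt(len(s))) if len(s) > 1 else 0.0

    group = grouped.agg(mean="mean", sem=_sem, n="count").reset_index()
    return per_subject, group
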