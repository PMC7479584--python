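"""Performance summaries and usability-questionnaire scoring.

Per-session performance is summarized as the number of trials completed,
the average response time per trial (seconds), the proportion of correct
responses (correct trials over completed trials), and the cumulative
response time.  Cumulative time sums the per-trial response times only —
loading and feedback intervals between trials are not part of it.

The usability instruments are scored as totals: a 16-item simulator
sickness questionnaire (each item 0-3, raw sum 0-48; the standard weighted
subscale scoring is available as an explicit alternative), the Borg rating
of perceived exertion (a single 6-20 rating), and a set of 0-100 visual
analog items about the experience.  Out-of-range input is rejected, never
clamped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import SessionLog
from .types import SummaryError, Task

N_SSQ_ITEMS = 16

# Subscale membership of the 16 sickness items in the standard instrument
# (N = nausea, O = oculomotor, D = disorientation), in canonical item order:
# general discomfort, fatigue, headache, eye strain, difficulty focusing,
# salivation, sweating, nausea, difficulty concentrating, fullness of head,
# blurred vision, dizziness (eyes open), dizziness (eyes closed), vertigo,
# stomach awareness, burping.
_SSQ_SUBSCALES: tuple[str, ...] = (
    "NO", "O", "O", "O", "OD", "N", "N", "ND",
    "NO", "D", "OD", "D", "D", "D", "N", "N",
)
_SSQ_WEIGHTS = {"N": 9.54, "O": 7.58, "D": 13.92}
_SSQ_TOTAL_FACTOR = 3.74


@dataclass(frozen=True)
class TaskSummary:
    n_trials_completed: int
    avg_time_per_trial_s: float
    proportion_correct: float
    cumulative_time_s: float


def summarize_task(log: SessionLog) -> TaskSummary:
    """Summarize one session log; seconds are reported at millisecond precision."""
    n = len(log.records)
    if n == 0:
        raise SummaryError("cannot summarize an empty session log")
    total_ms = sum(r.response_time.elapsed_ms for r in log.records)
    n_correct = sum(1 for r in log.records if r.correct)
    return TaskSummary(
        n_trials_completed=n,
        avg_time_per_trial_s=round(total_ms / n / 1000.0, 3),
        proportion_correct=n_correct / n,
        cumulative_time_s=round(total_ms / 1000.0, 3),
    )


@dataclass(frozen=True)
class QuestionnaireScores:
    ssq_total: int
    borg_rating: int
    vr_experience: dict[str, float]


def score_ssq(items: Sequence[int]) -> int:
    """Raw sum of the 16 sickness items, each rated 0-3 (total 0-48)."""
    if len(items) != N_SSQ_ITEMS:
        raise ValueError(f"expected {N_SSQ_ITEMS} sickness items, got {len(items)}")
    for i, v in enumerate(items, start=1):
        if not isinstance(v, int) or isinstance(v, bool) or not 0 <= v <= 3:
            raise ValueError(f"sickness item {i} must be an integer in 0..3, got {v!r}")
    return sum(items)


def score_ssq_weighted(items: Sequence[int]) -> dict[str, float]:
    """Standard weighted sickness scoring (explicit alternative to the raw sum).

    Returns the nausea, oculomotor, and disorientation subscale scores and
    the weighted total.
    """
    score_ssq(items)  # reuse range validation
    raw = {"N": 0, "O": 0, "D": 0}
    for value, membership in zip(items, _SSQ_SUBSCALES):
        for scale in membership:
            raw[scale] += value
    return {
        "nausea": raw["N"] * _SSQ_WEIGHTS["N"],
        "oculomotor": raw["O"] * _SSQ_WEIGHTS["O"],
        "disorientation": raw["D"] * _SSQ_WEIGHTS["D"],
        "total": (raw["N"] + raw["O"] + raw["D"]) * _SSQ_TOTAL_FACTOR,
    }


def score_questionnaires(
    ssq_items: Sequence[int],
    borg: int,
    vr_items: Mapping[str, float],
) -> QuestionnaireScores:
    """Validate and total the usability instruments."""
    ssq_total = score_ssq(ssq_items)
    if not isinstance(borg, int) or isinstance(borg, bool) or not 6 <= borg <= 20:
        raise ValueError(f"exertion rating must be an integer in 6..20, got {borg!r}")
    vr: dict[str, float] = {}
    for name, value in vr_items.items():
        if not 0 <= value <= 100:
            raise ValueError(f"experience item {name!r} must be in 0..100, got {value!r}")
        vr[name] = float(value)
    return QuestionnaireScores(ssq_total=ssq_total, borg_rating=borg, vr_experience=vr)


def batch_report(logs: Sequence[SessionLog]) -> pd.DataFrame:
    """Cross-session performance table, one row per task present.

    Each session contributes its own per-trial average first; means and SDs
    (ddof 1) are then taken across sessions.  Time columns are rounded to
    one decimal second; completed-trial counts are reported as a range.
    """
    rows = []
    by_task: dict[Task, list[TaskSummary]] = {}
    for log in logs:
        by_task.setdefault(log.task, []).append(summarize_task(log))
    for task in Task:
        summaries = by_task.get(task)
        if not summaries:
            continue
        counts = [s.n_trials_completed for s in summaries]
        times = np.array([s.avg_time_per_trial_s for s in summaries])
        accs = np.array([s.proportion_correct for s in summaries])
        sd = lambda x: float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
        rows.append(
            {
                "task": task.value,
                "n_sessions": len(summaries),
                "trials_completed_min": min(counts),
                "trials_completed_max": max(counts),
                "avg_time_per_trial_s_mean": round(float(times.mean()), 1),
                "avg_time_per_trial_s_sd": round(sd(times), 1),
                "proportion_correct_mean": float(accs.mean()),
                "proportion_correct_sd": sd(accs),
            }
        )
    return pd.DataFrame(rows)
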