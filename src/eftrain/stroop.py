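"""Game 1 — inhibitory control via a spatial Stroop task.

An arrow appears at one of four positions around an opponent character
(above, below, left, right) and points in one of the four directions.  The
position is a prepotent lure: the correct response is always the arrow's
*pointing direction*, regardless of where it appears.  Trials where position
and direction agree are *consistent*; the rest are *inconsistent*.

Congruency is balanced 50/50 over the session by a shuffled schedule rather
than independent uniform draws (which would give only 25% consistent trials);
both the condition label and the realized counts are logged so the policy is
auditable.  The opponent character rotates every ``CHARACTER_ROTATION``
trials purely for narrative pacing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import Condition, Direction, DIRECTIONS, ResponseTime

#: Trials per opponent character before rotating to the next one.
CHARACTER_ROTATION = 10


@dataclass(frozen=True)
class StroopTrial:
    trial_index: int
    arrow_position: Direction
    arrow_direction: Direction
    condition: Condition
    character_id: int


@dataclass(frozen=True)
class StroopRecord:
    trial_index: int
    arrow_position: Direction
    arrow_direction: Direction
    condition: Condition
    character_id: int
    response: Direction
    response_time: ResponseTime
    correct: bool


def classify_condition(position: Direction, direction: Direction) -> Condition:
    """Consistent iff the arrow points the way its position suggests."""
    return Condition.CONSISTENT if position == direction else Condition.INCONSISTENT


def character_for_trial(trial_index: int, rotation: int = CHARACTER_ROTATION) -> int:
    """Opponent id for a trial; piecewise constant over blocks of ``rotation``."""
    if trial_index < 0:
        raise ValueError("trial_index must be non-negative")
    return trial_index // rotation


def balanced_condition_schedule(
    n_trials: int, rng: np.random.Generator
) -> list[Condition]:
    """Shuffled half-consistent / half-inconsistent schedule.

    For odd ``n_trials`` the extra trial is inconsistent, so the absolute
    imbalance never exceeds one trial.
    """
    n_consistent = n_trials // 2
    schedule = [Condition.CONSISTENT] * n_consistent + [Condition.INCONSISTENT] * (
        n_trials - n_consistent
    )
    perm = rng.permutation(n_trials)
    return [schedule[i] for i in perm]


def score_stroop(
    trial: StroopTrial, response: Direction, rt: ResponseTime
) -> StroopRecord:
    """Score a response: correct iff it names the arrow's pointing direction."""
    return StroopRecord(
        trial_index=trial.trial_index,
        arrow_position=trial.arrow_position,
        arrow_direction=trial.arrow_direction,
        condition=trial.condition,
        character_id=trial.character_id,
        response=response,
        response_time=rt,
        correct=response == trial.arrow_direction,
    )


class StroopEngine:
    """Generates and scores the spatial-Stroop trial stream for one session."""

    def __init__(self, n_trials: int, rng: np.random.Generator) -> None:
        self.n_trials = n_trials
        self._rng = rng
        self._schedule = balanced_condition_schedule(n_trials, rng)

    def make_trial(self, trial_index: int) -> StroopTrial:
        rng = self._rng
        position = DIRECTIONS[int(rng.integers(4))]
        condition = self._schedule[trial_index]
        if condition is Condition.CONSISTENT:
            direction = position
        else:
            others = [d for d in DIRECTIONS if d != position]
            direction = others[int(rng.integers(3))]
        return StroopTrial(
            trial_index=trial_index,
            arrow_position=position,
            arrow_direction=direction,
            condition=condition,
            character_id=character_for_trial(trial_index),
        )

    def score(
        self, trial: StroopTrial, response: Direction, rt: ResponseTime
    ) -> StroopRecord:
        return score_stroop(trial, response, rt)

    def observe(self, record: StroopRecord) -> None:
        """Stroop difficulty is static; nothing carries between trials."""

    def context(self) -> dict:
        return {}
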