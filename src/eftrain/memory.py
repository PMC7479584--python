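"""Game 2 — working memory via adaptive sequence recall.

A sequence of characters is shown on a locked door; the player reproduces it
in forward or reverse order (drawn 50/50 per trial).  Difficulty follows a
2-up / 2-down staircase on sequence length: two consecutive correct recalls
lengthen the next sequence by one item, two consecutive errors shorten it by
one.  The session starts at length 2 and the length carries over across the
five door blocks (one fifth of the trials at each door) — doors are cosmetic
and never reset the staircase.

Each door has its own set of ``DOOR_CHARSET_SIZE`` characters; sequences are
sampled with replacement except that the same character never appears twice
in a row (an immediate repeat is visually ambiguous in a recall task).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .types import Order, ResponseTime

N_DOORS = 5
DOOR_CHARSET_SIZE = 8

DEFAULT_FLOOR_LENGTH = 1
DEFAULT_START_LENGTH = 2
#: Length ceiling; generous enough that a flawless run of the default
#: 50-trial session (which tops out at length 27) is never clamped.
DEFAULT_CAP_LENGTH = 30


@dataclass(frozen=True)
class StaircaseState:
    """State of the 2-consecutive up/down staircase on sequence length.

    At rest both streak counters are below 2: the moment either reaches 2
    the length steps by one (clamped to ``[floor_length, cap_length]``) and
    both counters reset.  An outcome always zeroes the opposite counter, so
    the two are never simultaneously positive.
    """

    current_length: int = DEFAULT_START_LENGTH
    consecutive_correct: int = 0
    consecutive_incorrect: int = 0
    floor_length: int = DEFAULT_FLOOR_LENGTH
    start_length: int = DEFAULT_START_LENGTH
    cap_length: int = DEFAULT_CAP_LENGTH

    def __post_init__(self) -> None:
        if not (self.floor_length <= self.current_length <= self.cap_length):
            raise ValueError(
                f"current_length {self.current_length} outside "
                f"[{self.floor_length}, {self.cap_length}]"
            )
        if self.consecutive_correct and self.consecutive_incorrect:
            raise ValueError("streak counters cannot both be positive")


def update_staircase(state: StaircaseState, correct: bool) -> StaircaseState:
    """Advance the staircase by one recall outcome.

    Returns a new state; the input is not mutated.
    """
    if correct:
        cc, ci = state.consecutive_correct + 1, 0
    else:
        cc, ci = 0, state.consecutive_incorrect + 1
    length = state.current_length
    if cc >= 2:
        length = min(length + 1, state.cap_length)
        cc = ci = 0
    elif ci >= 2:
        length = max(length - 1, state.floor_length)
        cc = ci = 0
    return replace(
        state,
        current_length=length,
        consecutive_correct=cc,
        consecutive_incorrect=ci,
    )


def door_for_trial(trial_index: int, n_trials: int) -> int:
    """Door (block) index: five contiguous blocks, one fifth of trials each.

    Block sizes differ by at most one; any remainder goes to the earliest
    doors, e.g. 12 trials split as (3, 3, 2, 2, 2).
    """
    if not 0 <= trial_index < n_trials:
        raise ValueError(f"trial_index {trial_index} out of range for {n_trials} trials")
    base, rem = divmod(n_trials, N_DOORS)
    boundary = 0
    for door in range(N_DOORS):
        boundary += base + (1 if door < rem else 0)
        if trial_index < boundary:
            return door
    raise AssertionError("unreachable")  # pragma: no cover


def door_charset(door_index: int) -> tuple[int, ...]:
    """Character identifiers shown at a given door (8 per door, disjoint)."""
    lo = door_index * DOOR_CHARSET_SIZE
    return tuple(range(lo, lo + DOOR_CHARSET_SIZE))


@dataclass(frozen=True)
class MemoryTrial:
    trial_index: int
    door_index: int
    order: Order
    presented_sequence: tuple[int, ...]
    level: int  # staircase length at generation; equals len(presented_sequence)


@dataclass(frozen=True)
class MemoryRecord:
    trial_index: int
    door_index: int
    order: Order
    presented_sequence: tuple[int, ...]
    level: int
    response_sequence: tuple[int, ...]
    response_time: ResponseTime
    correct: bool

    @property
    def number_of_items(self) -> int:
        return len(self.presented_sequence)


def expected_response(trial: MemoryTrial) -> tuple[int, ...]:
    """The exactly-correct reproduction for a trial's recall order."""
    if trial.order is Order.FORWARD:
        return trial.presented_sequence
    return tuple(reversed(trial.presented_sequence))


def score_memory(
    trial: MemoryTrial, response: tuple[int, ...], rt: ResponseTime
) -> MemoryRecord:
    """Exact-match scoring; any partial or reordered recall is incorrect."""
    return MemoryRecord(
        trial_index=trial.trial_index,
        door_index=trial.door_index,
        order=trial.order,
        presented_sequence=trial.presented_sequence,
        level=trial.level,
        response_sequence=tuple(response),
        response_time=rt,
        correct=tuple(response) == expected_response(trial),
    )


def sample_sequence(
    length: int, charset: tuple[int, ...], rng: np.random.Generator
) -> tuple[int, ...]:
    """Sample with replacement, forbidding immediate repeats."""
    seq: list[int] = []
    for _ in range(length):
        if not seq:
            seq.append(charset[int(rng.integers(len(charset)))])
        else:
            pool = [c for c in charset if c != seq[-1]]
            seq.append(pool[int(rng.integers(len(pool)))])
    return tuple(seq)


class MemoryEngine:
    """Generates, scores, and adapts the sequence-recall stream for one session."""

    def __init__(
        self,
        n_trials: int,
        rng: np.random.Generator,
        staircase: StaircaseState | None = None,
    ) -> None:
        self.n_trials = n_trials
        self._rng = rng
        self.staircase = staircase if staircase is not None else StaircaseState()

    def make_trial(self, trial_index: int) -> MemoryTrial:
        rng = self._rng
        door = door_for_trial(trial_index, self.n_trials)
        length = self.staircase.current_length
        seq = sample_sequence(length, door_charset(door), rng)
        order = Order.FORWARD if rng.random() < 0.5 else Order.BACKWARD
        return MemoryTrial(
            trial_index=trial_index,
            door_index=door,
            order=order,
            presented_sequence=seq,
            level=length,
        )

    def score(
        self, trial: MemoryTrial, response: tuple[int, ...], rt: ResponseTime
    ) -> MemoryRecord:
        return score_memory(trial, response, rt)

    def observe(self, record: MemoryRecord) -> None:
        self.staircase = update_staircase(self.staircase, record.correct)

    def context(self) -> dict:
        return {}
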