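"""Sequence recall: the 2-up/2-down staircase, door blocks, exact scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eftrain import (
    Order,
    ResponseTime,
    StaircaseState,
    Task,
    door_for_trial,
    score_memory,
    update_staircase,
)
from eftrain.memory import (
    DOOR_CHARSET_SIZE,
    MemoryEngine,
    MemoryTrial,
    door_charset,
    expected_response,
)


@pytest.mark.parametrize(
    "state, correct, expected",
    [
        # second consecutive correct lengthens by one and resets the counters
        (dict(current_length=2, consecutive_correct=1), True, (3, 0, 0)),
        # second consecutive error shortens by one
        (dict(current_length=5, consecutive_incorrect=1), False, (4, 0, 0)),
        # a single outcome only counts; the opposite streak is zeroed
        (dict(current_length=4, consecutive_incorrect=1), True, (4, 1, 0)),
        # floor clamp: length never drops below 1
        (dict(current_length=1, consecutive_incorrect=1), False, (1, 0, 0)),
    ],
)
def test_staircase_update_rules(state, correct, expected):
    out = update_staircase(StaircaseState(**state), correct)
    assert (
        out.current_length,
        out.consecutive_correct,
        out.consecutive_incorrect,
    ) == expected


def test_alternating_outcomes_never_move_the_length():
    state = StaircaseState()
    for i in range(20):
        state = update_staircase(state, correct=(i % 2 == 0))
    assert state.current_length == 2


def test_perfect_streak_closed_form():
    state = StaircaseState()
    for t in range(1, 51):
        state = update_staircase(state, correct=True)
        assert state.current_length == min(2 + t // 2, state.cap_length)
    assert state.current_length == 27


def test_always_incorrect_reaches_the_floor_at_two_and_stays():
    state = StaircaseState()
    for t in range(1, 21):
        state = update_staircase(state, correct=False)
        if t >= 2:
            assert state.current_length == 1


@settings(derandomize=True)
@given(st.lists(st.booleans(), min_size=1, max_size=200))
def test_staircase_invariants_hold_on_any_outcome_sequence(outcomes):
    state = StaircaseState()
    for correct in outcomes:
        state = update_staircase(state, correct)
        assert state.floor_length <= state.current_length <= state.cap_length
        assert not (state.consecutive_correct and state.consecutive_incorrect)
        assert state.consecutive_correct < 2 and state.consecutive_incorrect < 2


@pytest.mark.parametrize(
    "trial_index, n_trials, door",
    [(0, 50, 0), (9, 50, 0), (10, 50, 1), (49, 50, 4), (3, 12, 1)],
)
def test_door_block_schedule(trial_index, n_trials, door):
    assert door_for_trial(trial_index, n_trials) == door


def test_remainder_goes_to_the_earliest_doors():
    sizes = [0] * 5
    for i in range(12):
        sizes[door_for_trial(i, 12)] += 1
    assert sizes == [3, 3, 2, 2, 2]


@pytest.mark.parametrize("trial_index", [-1, 50])
def test_door_index_out_of_range(trial_index):
    with pytest.raises(ValueError):
        door_for_trial(trial_index, 50)


def test_first_trial_presents_two_characters():
    engine = MemoryEngine(50, np.random.default_rng(0))
    assert len(engine.make_trial(0).presented_sequence) == 2


def test_sequences_have_no_adjacent_duplicates_and_use_the_door_charset():
    engine = MemoryEngine(100, np.random.default_rng(1))
    for i in range(100):
        t = engine.make_trial(i)
        charset = set(door_charset(t.door_index))
        assert set(t.presented_sequence) <= charset
        for a, b in zip(t.presented_sequence, t.presented_sequence[1:]):
            assert a != b
        engine.observe(
            score_memory(t, expected_response(t), ResponseTime(100))
        )  # let the staircase climb so longer sequences are exercised


def test_forward_backward_split_is_about_even():
    engine = MemoryEngine(10_000, np.random.default_rng(9))
    forward = sum(
        engine.make_trial(i).order is Order.FORWARD for i in range(10_000)
    )
    assert abs(forward / 10_000 - 0.5) < 0.02


@pytest.mark.parametrize(
    "presented, order, response, correct",
    [
        ((0, 1, 2), Order.BACKWARD, (2, 1, 0), True),
        ((0, 1), Order.FORWARD, (0, 1), True),
        ((0, 1, 2), Order.FORWARD, (0, 2, 1), False),  # exact match required
        ((0, 1, 2), Order.FORWARD, (0, 1), False),  # partial recall is wrong
    ],
)
def test_exact_match_scoring(presented, order, response, correct):
    trial = MemoryTrial(
        trial_index=0,
        door_index=0,
        order=order,
        presented_sequence=presented,
        level=len(presented),
    )
    assert score_memory(trial, response, ResponseTime(100)).correct is correct


def test_door_charsets_are_disjoint():
    seen = set()
    for door in range(5):
        charset = set(door_charset(door))
        assert len(charset) == DOOR_CHARSET_SIZE
        assert not charset & seen
        seen |= charset
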