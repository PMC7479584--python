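"""Simulated responders: definitions, determinism, and strategy oracles."""

import pytest

from eftrain import (
    AgentSpec,
    ResponseTime,
    Rule,
    Task,
    make_agent,
    run_session,
    simulate_cohort,
    summarize_task,
)
from eftrain.sorting import RULE_PERIOD, RULES, matching_targets
from eftrain.types import DIRECTIONS


@pytest.mark.parametrize("task", list(Task))
def test_perfect_agent_is_always_correct(config_factory, perfect_spec, task):
    log = run_session(config_factory(task=task), make_agent(perfect_spec))
    assert summarize_task(log).proportion_correct == 1.0


def test_uniform_random_agent_hits_one_in_four_on_stroop(config_factory):
    log = run_session(
        config_factory(task=Task.INHIBITORY_CONTROL, n_trials=10_000),
        make_agent(AgentSpec(kind="uniform_random")),
    )
    assert abs(summarize_task(log).proportion_correct - 0.25) < 0.02


def test_span_limited_agent_fails_exactly_beyond_its_span(config_factory):
    log = run_session(
        config_factory(task=Task.WORKING_MEMORY, n_trials=100),
        make_agent(AgentSpec(kind="span_limited", span=4, lapse_rate=0.0)),
    )
    lengths = {len(r.presented_sequence) for r in log.records}
    assert max(lengths) >= 5  # the staircase did probe beyond the span
    for r in log.records:
        assert r.correct == (len(r.presented_sequence) <= 4)


def test_agent_rts_are_positive_and_round_trip(config_factory, perfect_spec):
    log = run_session(config_factory(task=Task.INHIBITORY_CONTROL), make_agent(perfect_spec))
    for r in log.records:
        assert r.response_time.elapsed_ms > 0
        assert ResponseTime.parse(r.response_time.format()) == r.response_time


def test_cohort_simulation_is_deterministic(config_factory):
    specs = [
        AgentSpec(kind="perfect"),
        AgentSpec(kind="uniform_random"),
        AgentSpec(kind="span_limited", span=5, lapse_rate=0.05),
        AgentSpec(kind="rule_elimination"),
    ]
    config = config_factory(task=Task.WORKING_MEMORY)
    once = simulate_cohort(specs, config, n_replicates=1)
    twice = simulate_cohort(specs, config, n_replicates=1)
    assert len(once) == 4
    assert all(len(log.records) == 50 for log in once)
    assert once == twice


def oracle_elimination_replay(records, targets):
    """Independent brute-force replay of the elimination strategy.

    Walks the logged stimulus/rule stream keeping the candidate-rule set by
    the declared policy and predicts every choice and outcome from scratch.
    """
    candidates = list(RULES)
    outcomes = []
    for rec in records:
        used = candidates[0]
        chosen = matching_targets(rec.stimulus, targets)[used]
        correct = targets[chosen].attribute(rec.active_rule) == rec.stimulus.attribute(
            rec.active_rule
        )
        outcomes.append((chosen, correct))
        if correct:
            candidates = [used]
        else:
            candidates = [r for r in candidates if r is not used]
            if not candidates:
                candidates = [r for r in RULES if r is not used]
    return outcomes


@pytest.mark.parametrize("seed", range(100))
def test_elimination_agent_matches_the_brute_force_oracle(config_factory, seed):
    from eftrain.sorting import DEFAULT_TARGETS

    log = run_session(
        config_factory(task=Task.COGNITIVE_FLEXIBILITY, seed=seed),
        make_agent(AgentSpec(kind="rule_elimination")),
    )
    predicted = oracle_elimination_replay(log.records, DEFAULT_TARGETS)
    actual = [(r.chosen_target, r.correct) for r in log.records]
    assert actual == predicted

    # after the first block the strategy loses at most twice per rule switch
    for start in range(RULE_PERIOD, 50, RULE_PERIOD):
        block = log.records[start : start + RULE_PERIOD]
        assert sum(not r.correct for r in block) <= 2


def test_perseverative_agent_keeps_sorting_by_the_old_rule(config_factory):
    log = run_session(
        config_factory(task=Task.COGNITIVE_FLEXIBILITY),
        make_agent(AgentSpec(kind="perseverative", perseveration_prob=1.0)),
    )
    # with certain perseveration, the dimension used never changes after the
    # first choice, so whole blocks under other rules are entirely wrong
    used = [r.matched_dimension for r in log.records]
    assert len(set(used)) == 1
    stuck = used[0]
    for r in log.records:
        assert r.correct == (r.active_rule is stuck)


def test_span_recovery_from_the_staircase(config_factory):
    """The staircase should settle near a span-limited agent's true span."""
    spec = AgentSpec(kind="span_limited", span=5, lapse_rate=0.05)
    total, count = 0.0, 0
    for rep in range(10):
        log = run_session(
            config_factory(task=Task.WORKING_MEMORY, n_trials=100, seed=100 + rep),
            make_agent(spec.model_copy(update={"agent_seed": rep})),
        )
        tail = log.records[-40:]
        total += sum(len(r.presented_sequence) for r in tail)
        count += len(tail)
    assert abs(total / count - 5) <= 1.0
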