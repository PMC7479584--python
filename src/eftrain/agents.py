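"""Parameterized simulated responders.

These agents stand in for child participants so the battery can be
exercised, validated, and simulated at population scale without human data:

* ``perfect`` — always applies each game's correctness rule (in the card
  sort it is omniscient about the active rule).
* ``uniform_random`` — guesses uniformly among the available responses.
* ``stroop_lure`` — succumbs to the spatial lure, answering with the arrow's
  *position* with probability ``p_lure`` (else the true direction); its
  accuracy therefore equals the session's consistent-trial fraction when
  ``p_lure = 1``.
* ``span_limited`` — recalls a sequence correctly iff its length is at most
  ``span`` and no attentional lapse occurs (probability ``lapse_rate``);
  the staircase should converge near ``span``.
* ``rule_elimination`` — infers the sorting rule by elimination: it keeps
  the set of rules consistent with all feedback since its last error,
  discards the rule it was using when an error arrives, and always plays
  the lowest-indexed consistent rule.
* ``perseverative`` — like the eliminator, but with probability
  ``perseveration_prob`` it repeats its previous dimension choice instead,
  the classic set-shifting failure mode.

Response times are drawn from a lognormal family (``median_ms`` scale,
``sigma`` shape) — the standard positively skewed reaction-time model; the
parameters are user-set and purely synthetic.  Each agent owns its RNG,
seeded independently of the session stream, so stimuli and behavior vary
independently; (spec, agent seed, session seed) fully determine every
response.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from . import memory, sorting
from .io import SessionLog
from .session import SessionConfig, run_session
from .types import ConfigurationError, Direction, DIRECTIONS, Rule, RULES, Task


class AgentKind(str, Enum):
    PERFECT = "perfect"
    UNIFORM_RANDOM = "uniform_random"
    STROOP_LURE = "stroop_lure"
    SPAN_LIMITED = "span_limited"
    RULE_ELIMINATION = "rule_elimination"
    PERSEVERATIVE = "perseverative"


class AgentSpec(BaseModel):
    """Validated description of a simulated responder."""

    model_config = ConfigDict(frozen=True)

    kind: AgentKind
    span: int = Field(default=4, ge=1)
    lapse_rate: float = Field(default=0.0, ge=0.0, le=1.0)
    p_lure: float = Field(default=1.0, ge=0.0, le=1.0)
    perseveration_prob: float = Field(default=0.5, ge=0.0, le=1.0)
    rt_median_ms: float = Field(default=1500.0, gt=0.0)
    rt_sigma: float = Field(default=0.35, ge=0.0)
    agent_seed: int = 0


@dataclass(frozen=True)
class _Feedback:
    rule_used: Rule
    correct: bool


class Agent:
    """Base responder: perfect play on every game, lognormal response times.

    Subclasses override the per-game answer methods; the base class supplies
    the omniscient answers so an agent limited in one domain (e.g. memory
    span) behaves cleanly elsewhere.
    """

    def __init__(self, spec: AgentSpec) -> None:
        self.spec = spec
        self.rng = np.random.default_rng(spec.agent_seed)

    # -- Responder contract -------------------------------------------------

    def begin_session(self, task: Task) -> None:
        """Reset any within-session state; agents are stateless across sessions."""

    def respond(self, task: Task, trial, context: dict) -> tuple:
        if task is Task.INHIBITORY_CONTROL:
            answer = self.answer_stroop(trial)
        elif task is Task.WORKING_MEMORY:
            answer = self.answer_memory(trial)
        else:
            answer = self.answer_sorting(trial, context["targets"])
        return answer, self._draw_rt()

    def feedback(self, task: Task, trial, record) -> None:
        """Correct/incorrect feedback after each choice; default ignores it."""

    # -- per-game answers ----------------------------------------------------

    def answer_stroop(self, trial) -> Direction:
        return trial.arrow_direction

    def answer_memory(self, trial) -> tuple[int, ...]:
        return memory.expected_response(trial)

    def answer_sorting(self, trial, targets) -> int:
        return sorting.matching_targets(trial.stimulus, targets)[trial.active_rule]

    def _draw_rt(self) -> int:
        ms = self.spec.rt_median_ms * float(
            np.exp(self.spec.rt_sigma * self.rng.standard_normal())
        )
        return max(1, int(round(ms)))


class PerfectAgent(Agent):
    pass


class UniformRandomAgent(Agent):
    def answer_stroop(self, trial) -> Direction:
        return DIRECTIONS[int(self.rng.integers(4))]

    def answer_memory(self, trial) -> tuple[int, ...]:
        charset = memory.door_charset(trial.door_index)
        n = len(trial.presented_sequence)
        return tuple(charset[int(i)] for i in self.rng.integers(len(charset), size=n))

    def answer_sorting(self, trial, targets) -> int:
        return int(self.rng.integers(4))


class StroopLureAgent(Agent):
    def answer_stroop(self, trial) -> Direction:
        if self.rng.random() < self.spec.p_lure:
            return trial.arrow_position
        return trial.arrow_direction


class SpanLimitedAgent(Agent):
    def answer_memory(self, trial) -> tuple[int, ...]:
        right = memory.expected_response(trial)
        over_span = len(right) > self.spec.span
        lapsed = self.rng.random() < self.spec.lapse_rate
        if not over_span and not lapsed:
            return right
        # a wrong recall: corrupt the first item to a different character
        charset = memory.door_charset(trial.door_index)
        wrong_first = next(c for c in charset if c != right[0])
        return (wrong_first,) + right[1:]


class RuleEliminationAgent(Agent):
    """Deterministic rule inference by elimination.

    Maintains the ordered set of rules consistent with all feedback since
    the last error; a correct outcome on an unambiguous trial pins the rule,
    an error discards the rule just used (reopening the other two when the
    pinned rule stops working).  Always plays the lowest-indexed candidate.
    """

    def begin_session(self, task: Task) -> None:
        self._candidates: list[Rule] = list(RULES)
        self._last_used: Optional[Rule] = None

    def _choose_rule(self, trial) -> Rule:
        return self._candidates[0]

    def answer_sorting(self, trial, targets) -> int:
        rule = self._choose_rule(trial)
        self._last_used = rule
        return sorting.matching_targets(trial.stimulus, targets)[rule]

    def feedback(self, task: Task, trial, record) -> None:
        if task is not Task.COGNITIVE_FLEXIBILITY or self._last_used is None:
            return
        used = self._last_used
        if record.correct:
            # unambiguous stimulus: a correct match identifies the rule
            self._candidates = [used]
        else:
            self._candidates = [r for r in self._candidates if r != used]
            if not self._candidates:
                self._candidates = [r for r in RULES if r != used]


class PerseverativeAgent(RuleEliminationAgent):
    """Eliminator that sticks with its previous dimension despite feedback."""

    def begin_session(self, task: Task) -> None:
        super().begin_session(task)
        self._previous: Optional[Rule] = None

    def _choose_rule(self, trial) -> Rule:
        if self._previous is not None and self.rng.random() < self.spec.perseveration_prob:
            return self._previous
        return self._candidates[0]

    def answer_sorting(self, trial, targets) -> int:
        choice = super().answer_sorting(trial, targets)
        self._previous = self._last_used
        return choice


_AGENT_CLASSES: dict[AgentKind, type[Agent]] = {
    AgentKind.PERFECT: PerfectAgent,
    AgentKind.UNIFORM_RANDOM: UniformRandomAgent,
    AgentKind.STROOP_LURE: StroopLureAgent,
    AgentKind.SPAN_LIMITED: SpanLimitedAgent,
    AgentKind.RULE_ELIMINATION: RuleEliminationAgent,
    AgentKind.PERSEVERATIVE: PerseverativeAgent,
}


def make_agent(spec: AgentSpec) -> Agent:
    """Instantiate the responder described by a spec."""
    try:
        cls = _AGENT_CLASSES[spec.kind]
    except KeyError as exc:  # pragma: no cover - pydantic blocks this earlier
        raise ConfigurationError(f"unknown agent kind {spec.kind!r}") from exc
    return cls(spec)


def _derived_seed(base: int, *indices: int) -> int:
    """Deterministic child seed below 2**31."""
    ss = np.random.SeedSequence([base, *indices])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def simulate_cohort(
    agent_specs: list[AgentSpec],
    session_config: SessionConfig,
    n_replicates: int = 1,
) -> list[SessionLog]:
    """Run independent seeded sessions for every (agent, replicate) pair.

    Each pair gets its own session seed and agent seed derived
    deterministically from the config seed, so the whole cohort replays
    exactly; the logs are schema-identical to human sessions.
    """
    logs: list[SessionLog] = []
    for a, spec in enumerate(agent_specs):
        for rep in range(n_replicates):
            cfg = session_config.model_copy(
                update={"seed": _derived_seed(session_config.seed, a, rep, 0)}
            )
            agent = make_agent(
                spec.model_copy(
                    update={"agent_seed": _derived_seed(spec.agent_seed, a, rep, 1)}
                )
            )
            logs.append(run_session(cfg, agent))
    return logs
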