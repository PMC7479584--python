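"""Session configuration and the therapist-style control-flow state machine.

A session runs one game for one participant.  The controls mirror a clinical
operator console: *Tutorial* (a short, unrecorded demonstration run),
*Training* (the full recorded run), *Reset* (interrupt the current trial and
re-present the same stimulus), *Back* (abandon the session, flushing a
partial log marked incomplete), and *Next* (advance to the next game in the
fixed order).

All randomness flows from a single numpy Generator seeded from the session
config, so identical (config, responder) pairs reproduce byte-identical
logs.  Only the study ID and session number identify a session; no other
person-level data is ever represented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, TYPE_CHECKING

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .types import (
    ConfigurationError,
    ControlError,
    Mode,
    Phase,
    ResponseTime,
    Task,
    TASK_ORDER,
)

if TYPE_CHECKING:  # pragma: no cover
    from .io import SessionLog

#: Trials in a tutorial run — enough to demonstrate the mechanics.
TUTORIAL_LENGTH = 5

SCHEMA_VERSION = "1"


class SessionConfig(BaseModel):
    """Who plays what, for how many trials, under which seed.

    ``study_id`` is an opaque label; together with ``session_number`` it is
    the only identifying information a session ever records.
    """

    model_config = ConfigDict(frozen=True)

    study_id: str = Field(min_length=1)
    session_number: int = Field(ge=1)
    task: Task
    n_trials: int = Field(default=50, ge=1)
    mode: Mode = Mode.TRAINING
    seed: int = Field(default=0, ge=0)
    output_path: Optional[Path] = None

    @property
    def effective_n_trials(self) -> int:
        """Trial count actually run: the tutorial length in tutorial mode."""
        return TUTORIAL_LENGTH if self.mode is Mode.TUTORIAL else self.n_trials


def make_config(**kwargs: Any) -> SessionConfig:
    """Build a validated config, mapping validation failures to ConfigurationError."""
    try:
        return SessionConfig(**kwargs)
    except Exception as exc:  # pydantic.ValidationError
        raise ConfigurationError(str(exc)) from exc


@dataclass
class SessionState:
    """Snapshot of a running session's control state."""

    config: SessionConfig
    trial_index: int
    phase: Phase
    rng_state: dict = field(repr=False, default_factory=dict)


def _make_engine(config: SessionConfig, rng: np.random.Generator, **engine_kwargs):
    from . import memory, sorting, stroop

    n = config.effective_n_trials
    if config.task is Task.INHIBITORY_CONTROL:
        return stroop.StroopEngine(n, rng, **engine_kwargs)
    if config.task is Task.WORKING_MEMORY:
        return memory.MemoryEngine(n, rng, **engine_kwargs)
    if config.task is Task.COGNITIVE_FLEXIBILITY:
        return sorting.SortingEngine(n, rng, **engine_kwargs)
    raise ConfigurationError(f"unknown task: {config.task!r}")  # pragma: no cover


class Session:
    """One game run, driven trial by trial.

    The phase cycle is ``presenting -> awaiting_response -> feedback`` per
    trial; ``reset()`` is legal while presenting or awaiting a response and
    re-presents the *same* stimulus with any partial response discarded (a
    reset attempt never produces a log row).
    """

    def __init__(
        self,
        config: SessionConfig,
        resume_from: "SessionLog | None" = None,
        **engine_kwargs: Any,
    ) -> None:
        if config.n_trials < 1:
            raise ConfigurationError("n_trials must be >= 1")
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.engine = _make_engine(config, self.rng, **engine_kwargs)
        self.records: list = []
        self.phase = Phase.IDLE
        self.trial_index = 0
        self.completed = False
        self._current_trial = None
        if resume_from is not None:
            self._fast_forward(resume_from)

    def _fast_forward(self, log: "SessionLog") -> None:
        """Replay a prior partial log so trial numbering and adaptive state continue.

        The prior log must come from the same config and seed: the stimulus
        stream is regenerated deterministically and the logged outcomes are
        fed back into the adaptive state (staircase, rule history).
        """
        if log.task is not self.config.task or log.seed != self.config.seed:
            raise ConfigurationError(
                "resume log does not match this session's task and seed"
            )
        for i, rec in enumerate(log.records):
            if rec.trial_index != i:
                raise ConfigurationError("resume log has non-contiguous trial indices")
            self.engine.make_trial(i)  # consume the same RNG draws
            self.engine.observe(rec)
            self.records.append(rec)
        self.trial_index = len(log.records)

    # -- control verbs -----------------------------------------------------

    def start(self) -> SessionState:
        if self.phase is not Phase.IDLE:
            raise ControlError("session already started")
        if self.trial_index >= self.config.effective_n_trials:
            self.phase = Phase.FINISHED
            self.completed = True
        else:
            self._current_trial = self.engine.make_trial(self.trial_index)
            self.phase = Phase.PRESENTING
        return self.state

    def present(self):
        """Show the current stimulus and open the response window."""
        if self.phase is not Phase.PRESENTING:
            raise ControlError(f"cannot present in phase {self.phase.value}")
        self.phase = Phase.AWAITING_RESPONSE
        return self._current_trial

    def submit(self, response: Any, rt: ResponseTime):
        """Commit a response; scores it and enters the feedback phase."""
        if self.phase is not Phase.AWAITING_RESPONSE:
            raise ControlError(f"cannot submit in phase {self.phase.value}")
        record = self.engine.score(self._current_trial, response, rt)
        self.records.append(record)
        self.engine.observe(record)
        self.phase = Phase.FEEDBACK
        return record

    def advance(self) -> SessionState:
        """Leave feedback and move to the next trial (or finish)."""
        if self.phase is not Phase.FEEDBACK:
            raise ControlError(f"cannot advance in phase {self.phase.value}")
        self.trial_index += 1
        if self.trial_index >= self.config.effective_n_trials:
            self.phase = Phase.FINISHED
            self.completed = True
            self._current_trial = None
        else:
            self._current_trial = self.engine.make_trial(self.trial_index)
            self.phase = Phase.PRESENTING
        return self.state

    def reset(self) -> SessionState:
        """Interrupt the trial and re-present the same stimulus.

        The partial attempt is discarded and never logged; the stimulus is
        identical on re-presentation because the trial keeps its initialized
        state rather than drawing a new one.
        """
        if self.phase not in (Phase.PRESENTING, Phase.AWAITING_RESPONSE):
            raise ControlError(f"cannot reset in phase {self.phase.value}")
        self.phase = Phase.PRESENTING
        return self.state

    def abandon(self) -> SessionState:
        """Back to the home screen: flush what exists, marked incomplete."""
        if self.phase is Phase.FINISHED and self.completed:
            raise ControlError("session already finished")
        self.phase = Phase.FINISHED
        self.completed = False
        self._current_trial = None
        return self.state

    # -- views -------------------------------------------------------------

    @property
    def state(self) -> SessionState:
        return SessionState(
            config=self.config,
            trial_index=self.trial_index,
            phase=self.phase,
            rng_state=self.rng.bit_generator.state,
        )

    def to_log(self) -> "SessionLog":
        from .io import SessionLog

        if self.config.mode is Mode.TUTORIAL:
            raise ControlError("tutorial runs are not recorded")
        return SessionLog(
            study_id=self.config.study_id,
            session_number=self.config.session_number,
            task=self.config.task,
            seed=self.config.seed,
            n_trials=self.config.n_trials,
            mode=self.config.mode,
            completed=self.completed,
            records=list(self.records),
        )


def start_session(config: SessionConfig, **engine_kwargs: Any) -> Session:
    """Validate the config and return a started session at trial 0."""
    session = Session(config, **engine_kwargs)
    session.start()
    return session


def run_session(
    config: SessionConfig,
    responder,
    resume_from: "SessionLog | None" = None,
    **engine_kwargs: Any,
) -> "SessionLog":
    """Run a full training session with a responder and return its log.

    The responder sees each stimulus plus the engine context (e.g. the target
    cards in the card sort) and returns ``(response, elapsed_ms)``; after
    scoring it receives the record as feedback, which is what lets
    rule-inference agents learn.
    """
    session = Session(config, resume_from=resume_from, **engine_kwargs)
    if hasattr(responder, "begin_session"):
        responder.begin_session(config.task)
    context = session.engine.context()
    session.start()
    while session.phase is not Phase.FINISHED:
        trial = session.present()
        response, elapsed_ms = responder.respond(config.task, trial, context)
        record = session.submit(response, ResponseTime(int(elapsed_ms)))
        if hasattr(responder, "feedback"):
            responder.feedback(config.task, trial, record)
        session.advance()
    return session.to_log()


@dataclass(frozen=True)
class TutorialReport:
    """In-memory result of a tutorial run; nothing is ever persisted."""

    task: Task
    n_trials: int
    n_correct: int

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_trials


def run_tutorial(config: SessionConfig, responder) -> TutorialReport:
    """Run the short unrecorded demonstration version of a game."""
    tut_config = config.model_copy(update={"mode": Mode.TUTORIAL})
    session = Session(tut_config)
    if hasattr(responder, "begin_session"):
        responder.begin_session(tut_config.task)
    context = session.engine.context()
    session.start()
    while session.phase is not Phase.FINISHED:
        trial = session.present()
        response, elapsed_ms = responder.respond(tut_config.task, trial, context)
        record = session.submit(response, ResponseTime(int(elapsed_ms)))
        if hasattr(responder, "feedback"):
            responder.feedback(tut_config.task, trial, record)
        session.advance()
    n_correct = sum(1 for r in session.records if r.correct)
    return TutorialReport(
        task=tut_config.task,
        n_trials=tut_config.effective_n_trials,
        n_correct=n_correct,
    )


def next_task(current: SessionConfig | SessionState) -> SessionConfig:
    """Config for the next game in the fixed order; error past the last game."""
    config = current.config if isinstance(current, SessionState) else current
    idx = TASK_ORDER.index(config.task)
    if idx + 1 >= len(TASK_ORDER):
        raise ControlError("no game after the last one")
    return config.model_copy(update={"task": TASK_ORDER[idx + 1]})
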