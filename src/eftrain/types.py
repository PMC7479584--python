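"""Shared enumerations, the response-time representation, and error types.

The battery trains three executive-function cores, each as a separate game:
inhibitory control (a spatial Stroop conflict task), working memory (an
adaptive sequence-recall staircase), and cognitive flexibility (an
undisclosed-rule card sort in the Wisconsin Card Sorting tradition).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum


class Task(str, Enum):
    """The three training games, in their fixed narrative order."""

    INHIBITORY_CONTROL = "inhibitory_control"
    WORKING_MEMORY = "working_memory"
    COGNITIVE_FLEXIBILITY = "cognitive_flexibility"


#: Fixed progression order of the games within a visit.
TASK_ORDER: tuple[Task, ...] = (
    Task.INHIBITORY_CONTROL,
    Task.WORKING_MEMORY,
    Task.COGNITIVE_FLEXIBILITY,
)


class Mode(str, Enum):
    TUTORIAL = "tutorial"
    TRAINING = "training"


class Phase(str, Enum):
    """Control-flow phase of a running session."""

    IDLE = "idle"
    PRESENTING = "presenting"
    AWAITING_RESPONSE = "awaiting_response"
    FEEDBACK = "feedback"
    FINISHED = "finished"


class Direction(str, Enum):
    """Arrow position or pointing direction in the Stroop game."""

    UP = "up"
    DOWN = "down"
    LEFT = "left"
    RIGHT = "right"


DIRECTIONS: tuple[Direction, ...] = tuple(Direction)


class Condition(str, Enum):
    """Stroop congruency: consistent iff position equals direction."""

    CONSISTENT = "consistent"
    INCONSISTENT = "inconsistent"


class Order(str, Enum):
    """Recall order for a working-memory trial."""

    FORWARD = "forward"
    BACKWARD = "backward"


class Rule(str, Enum):
    """Sorting dimension for the cognitive-flexibility game."""

    COLOR = "color"
    SHAPE = "shape"
    AMOUNT = "amount"


RULES: tuple[Rule, ...] = (Rule.COLOR, Rule.SHAPE, Rule.AMOUNT)


class ConfigurationError(ValueError):
    """Invalid session or agent configuration."""


class ControlError(RuntimeError):
    """A session-control verb used in a phase where it is not allowed."""


class PrivacyError(ValueError):
    """An attempt to persist a field outside the declared, de-identified schema."""


class ParseError(ValueError):
    """A session CSV row or header that cannot be interpreted."""


class VersionError(ParseError):
    """A session CSV written under an unknown schema version."""


class SummaryError(ValueError):
    """A summary requested for an empty log."""


# Valid textual form: zero-padded 2+ digit minutes (no excess leading zeros),
# seconds 00-59, milliseconds 000-999.  This makes format/parse exact inverses.
_RT_PATTERN = re.compile(r"^(\d{2}|[1-9]\d{2,}):([0-5]\d):(\d{3})$")


@dataclass(frozen=True, order=True)
class ResponseTime:
    """Elapsed time from stimulus onset to committed response.

    Stored as integer milliseconds; serialized in the log files as
    ``minutes:seconds:milliseconds`` (e.g. ``00:03:250`` for 3.25 s).
    """

    elapsed_ms: int

    def __post_init__(self) -> None:
        if not isinstance(self.elapsed_ms, int) or isinstance(self.elapsed_ms, bool):
            raise TypeError("elapsed_ms must be an integer number of milliseconds")
        if self.elapsed_ms < 0:
            raise ValueError("elapsed_ms must be non-negative")

    @property
    def seconds(self) -> float:
        return self.elapsed_ms / 1000.0

    def format(self) -> str:
        minutes, rem = divmod(self.elapsed_ms, 60_000)
        secs, ms = divmod(rem, 1000)
        return f"{minutes:02d}:{secs:02d}:{ms:03d}"

    @classmethod
    def parse(cls, text: str) -> "ResponseTime":
        m = _RT_PATTERN.match(text)
        if m is None:
            raise ParseError(f"not a minutes:seconds:milliseconds time: {text!r}")
        minutes, secs, ms = (int(g) for g in m.groups())
        return cls(minutes * 60_000 + secs * 1000 + ms)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.format()
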