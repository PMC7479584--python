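"""Trial-level CSV persistence for session logs.

One file per (study_id, session_number, task).  The file starts with
``# key=value`` header lines (study ID, session number, task, seed, trial
count, mode, completion flag, schema version) followed by an RFC-4180 CSV
section whose columns are the task's declared schema — and nothing else:
the writer refuses any field outside that schema, which is how the logs stay
free of protected health information by construction.

Response times serialize as ``minutes:seconds:milliseconds``; character
sequences as dash-joined identifier strings; booleans as ``yes``/``no``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from . import memory, sorting, stroop
from .types import (
    Condition,
    Direction,
    Mode,
    Order,
    ParseError,
    PrivacyError,
    ResponseTime,
    Rule,
    Task,
    VersionError,
)

SCHEMA_VERSION = "1"

#: The only header keys a session file may carry.
ALLOWED_HEADER_KEYS = (
    "study_id",
    "session_number",
    "task",
    "seed",
    "n_trials",
    "mode",
    "completed",
    "schema_version",
)

COLUMNS: dict[Task, tuple[str, ...]] = {
    Task.INHIBITORY_CONTROL: (
        "location_of_arrow",
        "direction_of_arrow",
        "condition",
        "response",
        "response_time",
        "correct",
        "trial_index",
        "character_id",
    ),
    Task.WORKING_MEMORY: (
        "order",
        "number_of_items",
        "level",
        "response_time",
        "correct",
        "trial_index",
        "door",
        "presented_sequence",
        "response_sequence",
    ),
    Task.COGNITIVE_FLEXIBILITY: (
        "rule_applied",
        "stimulus_amount",
        "stimulus_color",
        "stimulus_shape",
        "response",
        "response_time",
        "correct",
        "trial_index",
        "unambiguous",
    ),
}


@dataclass
class SessionLog:
    """A session header plus its completed trial records, in trial order."""

    study_id: str
    session_number: int
    task: Task
    seed: int
    n_trials: int
    mode: Mode
    completed: bool
    records: list = field(default_factory=list)
    extra_header: dict = field(default_factory=dict)

    def validate(self) -> None:
        for k in self.extra_header:
            raise PrivacyError(
                f"header field {k!r} is outside the declared de-identified schema"
            )
        for i, rec in enumerate(self.records):
            if rec.trial_index != i:
                raise ParseError(
                    f"records out of order: position {i} holds trial {rec.trial_index}"
                )


def _yesno(flag: bool) -> str:
    return "yes" if flag else "no"


def _parse_yesno(text: str, row: int) -> bool:
    if text == "yes":
        return True
    if text == "no":
        return False
    raise ParseError(f"row {row}: expected yes/no, got {text!r}")


def _join_seq(seq: tuple[int, ...]) -> str:
    return "-".join(str(c) for c in seq)


def _split_seq(text: str, row: int) -> tuple[int, ...]:
    if text == "":
        return ()
    try:
        return tuple(int(part) for part in text.split("-"))
    except ValueError as exc:
        raise ParseError(f"row {row}: bad character sequence {text!r}") from exc


def _stroop_row(rec: stroop.StroopRecord) -> list[str]:
    return [
        rec.arrow_position.value,
        rec.arrow_direction.value,
        rec.condition.value,
        rec.response.value,
        rec.response_time.format(),
        _yesno(rec.correct),
        str(rec.trial_index),
        str(rec.character_id),
    ]


def _memory_row(rec: memory.MemoryRecord) -> list[str]:
    return [
        rec.order.value,
        str(rec.number_of_items),
        str(rec.level),
        rec.response_time.format(),
        _yesno(rec.correct),
        str(rec.trial_index),
        str(rec.door_index),
        _join_seq(rec.presented_sequence),
        _join_seq(rec.response_sequence),
    ]


def _sorting_row(rec: sorting.SortingRecord) -> list[str]:
    matched = rec.matched_dimension.value if rec.matched_dimension else "none"
    return [
        rec.active_rule.value,
        str(rec.stimulus.amount),
        rec.stimulus.color,
        rec.stimulus.shape,
        f"{rec.chosen_target}:{matched}",
        rec.response_time.format(),
        _yesno(rec.correct),
        str(rec.trial_index),
        _yesno(rec.unambiguous),
    ]


_ROW_WRITERS = {
    Task.INHIBITORY_CONTROL: _stroop_row,
    Task.WORKING_MEMORY: _memory_row,
    Task.COGNITIVE_FLEXIBILITY: _sorting_row,
}


def write_session_csv(log: SessionLog, path: str | Path) -> Path:
    """Write a session log; returns the path written.

    Tutorial runs are never persisted, and any field outside the declared
    schema is refused with :class:`PrivacyError`.
    """
    if log.mode is Mode.TUTORIAL:
        raise PrivacyError("tutorial runs collect no data and cannot be written")
    log.validate()
    path = Path(path)
    row_writer = _ROW_WRITERS[log.task]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write(f"# study_id={log.study_id}\n")
        fh.write(f"# session_number={log.session_number}\n")
        fh.write(f"# task={log.task.value}\n")
        fh.write(f"# seed={log.seed}\n")
        fh.write(f"# n_trials={log.n_trials}\n")
        fh.write(f"# mode={log.mode.value}\n")
        fh.write(f"# completed={_yesno(log.completed)}\n")
        fh.write(f"# schema_version={SCHEMA_VERSION}\n")
        writer = csv.writer(fh)
        writer.writerow(COLUMNS[log.task])
        for rec in log.records:
            writer.writerow(row_writer(rec))
    return path


def _parse_stroop(row: dict[str, str], n: int) -> stroop.StroopRecord:
    try:
        return stroop.StroopRecord(
            trial_index=int(row["trial_index"]),
            arrow_position=Direction(row["location_of_arrow"]),
            arrow_direction=Direction(row["direction_of_arrow"]),
            condition=Condition(row["condition"]),
            character_id=int(row["character_id"]),
            response=Direction(row["response"]),
            response_time=ResponseTime.parse(row["response_time"]),
            correct=_parse_yesno(row["correct"], n),
        )
    except (ValueError, KeyError) as exc:
        raise ParseError(f"row {n}: {exc}") from exc


def _parse_memory(row: dict[str, str], n: int) -> memory.MemoryRecord:
    try:
        presented = _split_seq(row["presented_sequence"], n)
        rec = memory.MemoryRecord(
            trial_index=int(row["trial_index"]),
            door_index=int(row["door"]),
            order=Order(row["order"]),
            presented_sequence=presented,
            level=int(row["level"]),
            response_sequence=_split_seq(row["response_sequence"], n),
            response_time=ResponseTime.parse(row["response_time"]),
            correct=_parse_yesno(row["correct"], n),
        )
        if int(row["number_of_items"]) != len(presented):
            raise ParseError(
                f"row {n}: number_of_items disagrees with the presented sequence"
            )
        return rec
    except ParseError:
        raise
    except (ValueError, KeyError) as exc:
        raise ParseError(f"row {n}: {exc}") from exc


def _parse_sorting(row: dict[str, str], n: int) -> sorting.SortingRecord:
    try:
        chosen_text, _, matched_text = row["response"].partition(":")
        matched = None if matched_text in ("none", "") else Rule(matched_text)
        return sorting.SortingRecord(
            trial_index=int(row["trial_index"]),
            stimulus=sorting.Stimulus(
                color=row["stimulus_color"],
                shape=row["stimulus_shape"],
                amount=int(row["stimulus_amount"]),
            ),
            active_rule=Rule(row["rule_applied"]),
            unambiguous=_parse_yesno(row["unambiguous"], n),
            chosen_target=int(chosen_text),
            matched_dimension=matched,
            response_time=ResponseTime.parse(row["response_time"]),
            correct=_parse_yesno(row["correct"], n),
        )
    except ParseError:
        raise
    except (ValueError, KeyError) as exc:
        raise ParseError(f"row {n}: {exc}") from exc


_ROW_PARSERS = {
    Task.INHIBITORY_CONTROL: _parse_stroop,
    Task.WORKING_MEMORY: _parse_memory,
    Task.COGNITIVE_FLEXIBILITY: _parse_sorting,
}


def read_session_csv(path: str | Path) -> SessionLog:
    """Read a session file back into typed records.

    Raises :class:`ParseError` naming the offending data row, or
    :class:`VersionError` for an unknown schema version.
    """
    path = Path(path)
    header: dict[str, str] = {}
    data_lines: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                header[key.strip()] = value
            else:
                data_lines.append(line)
    missing = [k for k in ALLOWED_HEADER_KEYS if k not in header]
    if missing:
        raise ParseError(f"missing header fields: {', '.join(missing)}")
    if header["schema_version"] != SCHEMA_VERSION:
        raise VersionError(f"unknown schema version {header['schema_version']!r}")
    try:
        task = Task(header["task"])
    except ValueError as exc:
        raise ParseError(f"unknown task {header['task']!r}") from exc
    parser = _ROW_PARSERS[task]
    reader = csv.DictReader(data_lines)
    expected = COLUMNS[task]
    if data_lines and tuple(reader.fieldnames or ()) != expected:
        raise ParseError(
            f"column header {reader.fieldnames!r} does not match the "
            f"{task.value} schema"
        )
    records = []
    for n, row in enumerate(reader):
        if None in row or any(v is None for v in row.values()):
            raise ParseError(f"row {n}: wrong number of fields")
        records.append(parser(row, n))
    log = SessionLog(
        study_id=header["study_id"],
        session_number=int(header["session_number"]),
        task=task,
        seed=int(header["seed"]),
        n_trials=int(header["n_trials"]),
        mode=Mode(header["mode"]),
        completed=_parse_yesno(header["completed"], -1),
        records=records,
    )
    log.validate()
    return log
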