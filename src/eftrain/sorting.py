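"""Game 3 — cognitive flexibility via an undisclosed-rule card sort.

The player matches a stimulus (a creature wearing a symbol with a color, a
shape, and an amount) to one of four target cards, without being told which
dimension currently governs the match.  Feedback after every choice is the
only signal; the active rule silently changes every ``RULE_PERIOD`` trials
to a different rule, in the Wisconsin Card Sorting tradition.

The four targets form a *key card* set: their colors are all distinct, their
shapes all distinct, and their amounts all distinct, so a stimulus matches
exactly one target per dimension.  Stimuli are additionally rejection-sampled
to be *unambiguous* — the color-, shape-, and amount-matching targets are
three different cards — otherwise feedback could not identify the rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import ConfigurationError, ResponseTime, Rule, RULES

RULE_PERIOD = 7

COLORS: tuple[str, ...] = ("red", "blue", "green", "yellow")
SHAPES: tuple[str, ...] = ("circle", "square", "triangle", "star")
AMOUNTS: tuple[int, ...] = (1, 2, 3, 4)


@dataclass(frozen=True)
class Stimulus:
    color: str
    shape: str
    amount: int

    def attribute(self, rule: Rule):
        return getattr(self, rule.value)


@dataclass(frozen=True)
class Target:
    color: str
    shape: str
    amount: int

    def attribute(self, rule: Rule):
        return getattr(self, rule.value)


#: Latin-square default target set: every color, shape, and amount distinct.
DEFAULT_TARGETS: tuple[Target, ...] = tuple(
    Target(color=COLORS[i], shape=SHAPES[i], amount=AMOUNTS[i]) for i in range(4)
)


def validate_target_set(targets: tuple[Target, ...]) -> None:
    """Enforce the key-card property: four targets, distinct on every dimension."""
    if len(targets) != 4:
        raise ConfigurationError("a target set must contain exactly 4 targets")
    for rule in RULES:
        values = {t.attribute(rule) for t in targets}
        if len(values) != 4:
            raise ConfigurationError(
                f"target set violates the key-card property on {rule.value}"
            )


def matching_targets(
    stimulus: Stimulus, targets: tuple[Target, ...]
) -> dict[Rule, int]:
    """Index of the (unique) target matching the stimulus on each dimension."""
    out: dict[Rule, int] = {}
    for rule in RULES:
        for i, t in enumerate(targets):
            if t.attribute(rule) == stimulus.attribute(rule):
                out[rule] = i
                break
    return out


def is_unambiguous(stimulus: Stimulus, targets: tuple[Target, ...]) -> bool:
    """True iff the three dimension-matching targets are pairwise distinct."""
    match = matching_targets(stimulus, targets)
    return len(set(match.values())) == 3


@dataclass(frozen=True)
class SortingTrial:
    trial_index: int
    stimulus: Stimulus
    active_rule: Rule
    unambiguous: bool


@dataclass(frozen=True)
class SortingRecord:
    trial_index: int
    stimulus: Stimulus
    active_rule: Rule
    unambiguous: bool
    chosen_target: int
    matched_dimension: Rule | None
    response_time: ResponseTime
    correct: bool


def score_sort(
    trial: SortingTrial,
    chosen_target: int,
    rt: ResponseTime,
    targets: tuple[Target, ...],
) -> SortingRecord:
    """Correct iff the chosen card matches the stimulus on the active rule.

    Also records which dimension (if any) the chosen card did match, which is
    what the feedback lets the player infer; with unambiguous stimuli a card
    matches on at most one dimension.
    """
    if not 0 <= chosen_target <= 3:
        raise ValueError(f"chosen_target {chosen_target} out of range 0..3")
    chosen = targets[chosen_target]
    matched = None
    for rule in RULES:
        if chosen.attribute(rule) == trial.stimulus.attribute(rule):
            matched = rule
            break
    correct = chosen.attribute(trial.active_rule) == trial.stimulus.attribute(
        trial.active_rule
    )
    return SortingRecord(
        trial_index=trial.trial_index,
        stimulus=trial.stimulus,
        active_rule=trial.active_rule,
        unambiguous=trial.unambiguous,
        chosen_target=chosen_target,
        matched_dimension=matched,
        response_time=rt,
        correct=correct,
    )


def n_rule_blocks(n_trials: int) -> int:
    """Number of rule blocks in a session: ceil(n_trials / RULE_PERIOD)."""
    return -(-n_trials // RULE_PERIOD)


class SortingEngine:
    """Generates and scores the rule-switching card-sort stream for one session.

    The rule is constant within each block of ``RULE_PERIOD`` trials; at each
    block boundary a new rule is drawn uniformly from the two rules not
    currently active (the first block's rule is uniform over all three), so
    adjacent blocks always differ.
    """

    def __init__(
        self,
        n_trials: int,
        rng: np.random.Generator,
        targets: tuple[Target, ...] = DEFAULT_TARGETS,
    ) -> None:
        validate_target_set(targets)
        self.n_trials = n_trials
        self.targets = targets
        self._rng = rng
        self._rule: Rule | None = None

    def _draw_stimulus(self) -> Stimulus:
        rng = self._rng
        while True:
            stim = Stimulus(
                color=COLORS[int(rng.integers(4))],
                shape=SHAPES[int(rng.integers(4))],
                amount=AMOUNTS[int(rng.integers(4))],
            )
            if is_unambiguous(stim, self.targets):
                return stim

    def _rule_for(self, trial_index: int) -> Rule:
        if trial_index % RULE_PERIOD == 0 or self._rule is None:
            rng = self._rng
            if self._rule is None:
                self._rule = RULES[int(rng.integers(3))]
            else:
                others = [r for r in RULES if r != self._rule]
                self._rule = others[int(rng.integers(2))]
        return self._rule

    def make_trial(self, trial_index: int) -> SortingTrial:
        rule = self._rule_for(trial_index)
        stim = self._draw_stimulus()
        return SortingTrial(
            trial_index=trial_index,
            stimulus=stim,
            active_rule=rule,
            unambiguous=True,
        )

    def score(
        self, trial: SortingTrial, response: int, rt: ResponseTime
    ) -> SortingRecord:
        return score_sort(trial, response, rt, self.targets)

    def observe(self, record: SortingRecord) -> None:
        """Rule switching is clocked by trial count, not by performance."""

    def context(self) -> dict:
        return {"targets": self.targets}
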