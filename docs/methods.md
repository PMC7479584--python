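# Methods

## Scope and model

`eftrain` implements the *logic* of a three-game executive-function training
battery — trial generation, adaptive difficulty, scoring, session control,
logging, and metrics — as a deterministic headless library. Everything a
renderer would own (graphics, audio, narrative art, controller handling) is
out of scope; the operator console survives as library verbs and a CLI.

A session runs one game for one `(study_id, session_number)` pair under a
single seed. All stimulus randomness flows from one numpy PCG64 generator
seeded from the config, and agents carry their own independently seeded
generators, so stimulus streams and simulated behavior vary independently and
`(config, agent spec, seeds)` fully determine every log byte.

## Game 1: spatial Stroop (inhibitory control)

Each trial places an arrow at one of four positions around an opponent and
points it in one of four directions; the response is correct iff it names the
pointing direction. Congruency (`consistent` iff position = direction) is
balanced 50/50 by a schedule shuffled once per session rather than by
independent uniform draws, which would yield only 25% consistent trials:
balanced congruency is the norm in Stroop-style conflict tasks and makes the
consistent-trial fraction a known quantity for analysis. For an odd trial
count the extra trial is inconsistent (the training-relevant condition), so
the imbalance never exceeds one. Positions are uniform per trial; on
inconsistent trials the direction is uniform over the three non-matching
values. The opponent character rotates every 10 trials (five characters over
the default 50 trials); rotation is narrative only and affects no statistic.
There is no response deadline: trials wait indefinitely and the response time
is logged as supplied.

## Game 2: adaptive sequence recall (working memory)

Sequence length follows a 2-up/2-down staircase starting at 2: the second
consecutive correct recall raises length by one, the second consecutive error
lowers it by one; each outcome zeroes the opposite streak counter and a
length change resets both, so the two counters are never simultaneously
positive and three correct answers in a row cannot trigger two increments.
Under this rule a perfect responder reaches length `2 + floor(t/2)` after `t`
trials (27 after 50) and an always-failing one reaches the floor at trial 2.

Bounds: the floor is 1 (length 0 is meaningless, and a floor below the start
keeps the decrement rule observable) and the cap is 30 — high enough that no
default-length session can clamp the perfect-responder closed form, while
still bounding memory and file size. Both are configurable on
`StaircaseState`.

Each session visits five doors in contiguous blocks of one fifth of the
trials (remainder to the earliest doors, e.g. 12 → 3,3,2,2,2); the staircase
carries across door boundaries — doors are cosmetic. Each door has its own
disjoint set of 8 characters; sequences sample with replacement but never
repeat a character twice in a row, since an immediate repeat is visually
ambiguous in a recall display. Recall order is forward or backward, drawn
50/50 independently per trial and logged so any schedule is auditable.
Scoring is exact match against the presented sequence (or its reversal);
partial recalls are incorrect. The log keeps both `level` (staircase length
at generation) and `number_of_items` (realized sequence length); they are
equal by construction and both retained for schema fidelity.

## Game 3: undisclosed-rule card sort (cognitive flexibility)

The rule set is {color, shape, amount}. The active rule is constant within
each block of 7 trials and, at every block boundary, redrawn uniformly from
the two rules *not* currently active — "the rule changes" is read literally,
so adjacent blocks always differ; the first rule is uniform over all three. A
50-trial session therefore has 8 blocks (7 of length 7 plus a final length-1
block, kept rather than truncated).

The four target cards form a key-card set (all colors, shapes, and amounts
distinct), so a stimulus matches exactly one target per dimension. Stimuli
are drawn uniformly from the 4×4×4 attribute product and rejection-sampled
until *unambiguous* — their color-, shape-, and amount-matching targets are
three different cards (24 of the 64 stimuli under the default Latin-square
target set). Without this constraint, feedback could not identify the rule: a
card matching on two dimensions makes a correct outcome uninformative. The
default target set is a fixed Latin-square assignment so sessions are
comparable; any key-card set can be passed instead. A choice is correct iff
the chosen card matches the stimulus on the active rule's dimension; the
dimension the chosen card did match (at most one, by unambiguity) is logged
as part of the response.

## Simulated responders

Agents stand in for child participants for validation and cohort simulation;
they make no cognitive-modeling claims and are never fit to human data.
Response times are lognormal (`median_ms` = 1500, `sigma` = 0.35 by default),
the standard positively skewed reaction-time family; `sigma = 0` gives
constant times for byte-level replay tests. Kinds:

- `perfect` applies each game's correctness rule (omniscient in the sort).
- `uniform_random` guesses uniformly (¼ accuracy on the Stroop task).
- `stroop_lure` answers with the arrow's position with probability `p_lure`,
  so at `p_lure = 1` its accuracy equals the session's consistent fraction.
- `span_limited` recalls correctly iff length ≤ `span` and no lapse
  (probability `lapse_rate`); wrong recalls corrupt the first item.
- `rule_elimination` keeps the set of rules consistent with all feedback
  since its last error, discards the rule it was using on an error
  (reopening the other two when that empties the set), and always plays the
  lowest-indexed candidate. On unambiguous stimuli a correct outcome pins
  the rule, so the strategy loses at most twice per rule switch.
- `perseverative` is the eliminator but repeats its previous dimension with
  probability `perseveration_prob` — the classic set-shifting failure.

`simulate_cohort` derives per-(agent, replicate) session and agent seeds from
the config seed via `SeedSequence`, so whole cohorts replay exactly.

What the agents do *not* emulate: motor noise and anticipations, learning or
fatigue across trials, partial-credit recall behavior, and any correlation
between accuracy and response time. Tests passing on these agents validate
the *task logic* (schedules, staircase, scoring, logging), not claims about
children's performance.

## Session control and logging

The control verbs mirror an operator console: tutorial (a 5-trial
demonstration whose data are never collected or writable), training, reset
(re-presents the *same* stimulus — the trial keeps its initialized state —
and the discarded attempt is never logged, so each completed trial index
appears exactly once), back (abandonment: the partial log is flushed marked
incomplete), and next (advance through the fixed game order). A session can
resume from a prior partial log with the same task and seed: the stimulus
stream is regenerated deterministically and the logged outcomes replayed
into the adaptive state, so a session split across sittings equals the same
session run straight through.

Logs are one CSV per (study, session, task): `# key=value` header lines
(study ID, session number, task, seed, trial count, mode, completion,
schema version) and one RFC-4180 row per completed trial. The writer refuses
any field outside the declared schema, which keeps the files de-identified by
construction. Times serialize as `minutes:seconds:milliseconds` (two-digit
zero-padded minutes, exact round-trip both ways); sequences as dash-joined
identifiers; booleans as yes/no.

## Metrics and questionnaires

Per-session summaries report completed trials, average response time per
trial, proportion correct (correct over *completed* trials; abandoned or
reset attempts are excluded), and cumulative response time — response times
only, excluding inter-trial loading and feedback intervals, which the battery
does not measure. Seconds are stored at millisecond precision and rounded to
one decimal only in the cross-session report, which takes each session's own
per-trial average first and then means and SDs (ddof 1) across sessions —
the per-subject-then-across convention.

The simulator-sickness questionnaire is scored primarily as the raw sum of
its 16 items (each 0–3, total 0–48); the standard weighted scoring (nausea /
oculomotor / disorientation subscales weighted 9.54 / 7.58 / 13.92, total
×3.74) is provided as an explicitly separate function. Perceived exertion is
a single 6–20 rating and the experience survey a set of 0–100 items; all
out-of-range input is rejected, never clamped.

## Numerical and testing choices

Everything is integer or exact rational except summary seconds (rounded to
3 decimals) and agent response-time draws. Property tests use derandomized
hypothesis; stochastic frequency checks use fixed seeds and the sizes stated
in the test (10,000 trials for ±2% frequency bands, 10,000 blocks for rule
frequencies, 50 replicates × 100 trials per span for staircase span
recovery). The validation scripts run full sessions rather than unit calls
wherever feasible, so schedules, engines, agents, and I/O are exercised
together.

## Known limitations

- Text-mode interactive play trivially reveals the Stroop stimulus (there is
  no spatial rendering), so human text-mode data are not comparable to the
  original task; the interactive mode exists to exercise the control flow.
- The staircase estimates span with a positive bias of about half an item
  (it oscillates between `span` and `span + 1` for a deterministic agent);
  this is inherent to a 2-up/2-down rule, not corrected for.
- The rule set and 7-trial period are configurable but untested against
  2-rule variants beyond the key-card validation.
- Multi-session resume requires the original seed; resuming under a new seed
  is refused rather than approximated.
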