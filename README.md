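# eftrain

A headless, deterministic implementation of a three-game executive-function
training battery for pediatric cognitive rehabilitation, plus the session
control, trial-level logging, simulated responders, and performance/usability
metrics needed to exercise and validate the training logic without any VR
hardware or graphics.

The battery targets the three core executive functions:

1. **Inhibitory control — spatial Stroop.** An arrow appears at one of four
   positions around an opponent (up/down/left/right) and points in one of the
   four directions. The position is a prepotent lure; the correct response is
   the arrow's *pointing direction*. Trials where position and direction agree
   are *consistent*, the rest *inconsistent*; congruency is balanced 50/50
   over the session by a shuffled schedule.
2. **Working memory — adaptive sequence recall.** A character sequence is
   presented and must be reproduced in forward or reverse order (drawn 50/50
   per trial). Sequence length follows a 2-up/2-down staircase: two
   consecutive correct recalls lengthen the next sequence by one item, two
   consecutive errors shorten it by one, starting from length 2. The session
   runs across five doors (one fifth of trials each); the length carries over
   door boundaries.
3. **Cognitive flexibility — undisclosed-rule card sort.** A stimulus with a
   color, shape, and amount must be matched to one of four key cards whose
   attributes are distinct on every dimension. Only correct/incorrect feedback
   is given; the governing rule (color, shape, or amount) silently changes to
   a different rule every 7 trials, in the Wisconsin Card Sorting tradition.

Sessions are driven either interactively (text mode) or by parameterized
simulated agents (perfect, uniform-random, Stroop-lure, span-limited,
rule-eliminating, perseverative). Every completed trial is logged to a
de-identified CSV (study ID and session number only), with response times in
`minutes:seconds:milliseconds`; logs round-trip losslessly and identical
configurations and seeds replay byte-identically.

## Worked example

```python
import eftrain as ef

config = ef.make_config(
    study_id="S01", session_number=1,
    task=ef.Task.WORKING_MEMORY, n_trials=50, seed=7,
)
agent = ef.make_agent(ef.AgentSpec(kind="span_limited", span=4, lapse_rate=0.0))
log = ef.run_session(config, agent)
print(ef.summarize_task(log))
print("final staircase level:", log.records[-1].level)
```

prints

```
TaskSummary(n_trials_completed=50, avg_time_per_trial_s=1.71, proportion_correct=0.56, cumulative_time_s=85.477)
final staircase level: 4
```

The agent recalls perfectly up to span 4, so the staircase climbs from 2,
oscillates between 4 and 5 (hence a proportion correct near one half once it
gets there), and the last trial is presented at level 4. Response times are
drawn from the agent's lognormal model, giving about 1.7 s per trial and
85.5 s cumulative over 50 trials.

The same battery is available from the shell:

```sh
eftrain simulate --task working_memory --study-id S01 --trials 50 --seed 7 \
        --agent span_limited --agent-param span=4 --out-dir logs/
eftrain report logs/*.csv
eftrain score-questionnaire --ssq 0,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0 --borg 8 --vr fun=72
```

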