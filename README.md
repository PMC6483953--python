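# edahab

Electrodermal habituation scoring, an adaptive auditory detection-threshold
staircase, and the surrounding group statistics — built as a reusable
library plus a four-step analysis pipeline, exercised end to end on
synthetic cohorts with known ground truth.

## The problem

In autonomic psychophysiology, habituation to a repeated auditory stimulus
is read off the skin conductance response (SCR): a transient trough-to-peak
rise in skin conductance. A participant hears a 3-s tone (or siren) 15
times with a 20–35 s jittered interstimulus interval. The trace, sampled at
1000 S/s, is low-pass filtered (10 Hz, 4th-order Butterworth) and scanned
for peaks via first-derivative sign changes; for each peak the algorithm
searches backward up to 4 s for the trough or bend that marks response
onset. A trial counts as a response when the trough-to-peak amplitude is at
least 0.03 µS and the response falls 1–4 s after stimulus onset.
Habituation is complete at the first two consecutive response-free trials;
the score is the number of trials before that pair (respond on trials 1–4,
nothing on 5 and 6 → score 4). Participants with no qualifying SCR in a
condition's first two trials are non-responders and are excluded from
habituation analyses.

A companion task measures the auditory detection threshold by the method of
limits: a 1000 Hz tone starts at 60 dB HL and descends in 5-dB steps until
the listener stops reporting it, then ascends in 5-dB steps until it is
heard again; that level is the pass threshold, and passes repeat until two
consecutive passes agree. The statistics stage screens variables by
skewness/kurtosis z-scores, winsorizes 3×IQR outliers to the nearest
non-outlier value ± one measurement unit, compares groups by one-way ANOVA
with pooled-SD Cohen's d (d = (m₂ − m₁)/s_pooled), correlates habituation
and ratings with self-reported auditory sensitivity, Bonferroni-corrects
families of comparisons, and fits a 3-block × 2-group mixed-design
repeated-measures ANOVA to the SCR magnitude slope.

No raw participant data are available, so the `synthetic` module generates
every input with known ground truth: schedules, traces (biexponential SCR
kernels with geometrically decaying amplitudes over tonic level, drift and
noise), psychometric yes/no observers for the staircase, and two-group
cohorts with configurable effect sizes, non-responder fractions and a
latent-variable rank correlation between arousal ratings and questionnaire
scores.

## Worked example

```sh
python analysis/01_simulate_cohort.py --seed 0
python analysis/02_score_participants.py --seed 0
python analysis/03_staircase_characterisation.py --seed 0
python analysis/04_group_statistics.py --seed 0
```

Step 02 prints, for the default two-group cohort (33 + 31 participants):

```
scored 64 participants at 1000 Hz
  ASD: 10 non-responders (30.3%), habituation tone 7.83 siren 6.83 trials, threshold 18.3 dB
  TD: 8 non-responders (25.8%), habituation tone 8.48 siren 6.91 trials, threshold 15.5 dB
responder classification matches generator ground truth on 85.9% of participants
```

i.e. responders habituate after roughly 7–9 trials (the generator's decay
ratio 0.73 predicts 9 for the analytic noise-free case), and measured
thresholds sit one grid step above the true means, the staircase's known
upward bias. Step 04 prints the group comparison table (the synthetic
questionnaire effect is recovered at d ≈ −1.4), the correlation panel, and
the block-slope ANOVA, whose block effect is large (F ≈ 330) because
amplitudes decay across blocks while the group × block interaction stays
near 1 — the habituation-slope null built into the default cohort.

Library use mirrors the scripts:

```python
from edahab import (make_schedule, ScrGenParams, generate_eda_trace,
                    lowpass_butterworth, detect_scr_events, score_trials,
                    trials_to_habituation)
schedule = make_schedule(seed=1)                     # 15 trials, 3 s, ISI 20-35 s
params = ScrGenParams(initial_amplitude_uS=0.5, decay_ratio=0.73)
trace, truth = generate_eda_trace(schedule, params)
events = detect_scr_events(lowpass_butterworth(trace))
scores = score_trials(events, schedule)
print(trials_to_habituation(scores).trials_to_habituation)   # -> 9
```

A thin CLI wraps the same functions: `edahab simulate|score|threshold|analyze`.

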