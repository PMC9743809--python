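# cogload

Analysis pipeline for **cognitive-workload experiments built on the
N-back task**, combining three synchronized data streams: behavioral
logs from the task itself, four-channel consumer-headband EEG
(TP9/AF7/AF8/TP10), and eye-tracker gaze/pupillometry streams. It is
written for researchers who manipulate working-memory load with 1-back
vs 2-back blocks and want to quantify the workload difference with
event-related EEG band-power changes, pupil dilation, and
fixation/saccade dynamics.

## What it computes

**ERD/ERS.** For each stimulus, band-limited EEG power is averaged over
a reference window (R) and over the activation window from letter onset
to the response (A), and the relative change is

```
ERD/ERS% = (R − A) / R × 100
```

Positive values mean the band power dropped during activation
(desynchronization); negative values mean it rose. Two reference
strategies are supported: a 200 ms *near* baseline immediately before
each letter, and a single 3 s *away* baseline taken from the eyes-open
rest at the start of the session.

**Eye metrics.** Per stimulus interval: averaged and maximum
baseline-corrected pupil dilation per eye, averaged/maximum fixation and
saccade durations, and fixation/saccade counts per second. Capture rate
(fraction of valid tracker samples) screens participants; it correlates
negatively with astigmatism, summarized as the mean of the two eyes'
degrees.

**Behavior.** Reaction time (onset → response) and accuracy rate
(correct / scoreable responses) per condition, with the two experiment
letter blocks sharing an identical YES/NO response key by design.

**Statistics.** A Shapiro–Wilk normality gate, Mann–Whitney–Wilcoxon
comparisons reported with the rank-sum W convention (W = sum of the
pooled ranks of the first sample; exact enumeration p for small untied
samples, tie/continuity-corrected normal approximation otherwise),
Spearman correlation, and result tables in the column order
`Measure, N back, N, Mean, SD, Median, W, p-value`.

**Synthetic sessions.** Because raw recordings from such experiments are
rarely shareable, `cogload.simulate` generates full sessions with known
ground truth — oscillatory EEG over 1/f noise with condition-specific
band-power changes injected by an amplitude factor √(1−d), gaze streams
with condition-dependent pupil shifts and astigmatism-coupled
missingness, lognormal RTs and Bernoulli accuracy — so every pipeline
stage is tested against injected truth.

## Worked example

```python
from cogload.io import RunConfig, run_all

res = run_all(RunConfig(n_participants=6, dropout=(), seed=42))
print(res.tables["behavior"].head(2))
print(res.recovery)
```

prints (abridged):

```
      Measure  N back   N   Median       W  p-value sig
Reaction time       1 120 1.027463 11697.0 0.000002 ***
Reaction time       2 116 1.356990     NaN      NaN

           Measure  N back   N    Median       W  p-value sig
Alpha_ERD_AF7_near       1 120 -0.103363 16997.0 0.000002 ***
Alpha_ERD_AF7_near       2 120 -0.139671     NaN      NaN

                    quantity  truth  estimate   n  abs_error
         erd[Alpha,AF7,high]  -0.17 -0.136635 120   0.033365
       pupil_shift[high-low]   0.09  0.102384   0   0.012384
```

Reading this: pooled reaction times are significantly slower in the
2-back condition (medians 1.03 vs 1.36 s); Alpha-band power at AF7
rises during activation (negative ERD fraction), more in the 2-back
block; and the recovery report confirms the pipeline's estimates track
the injected ground truth (the injected Alpha-AF7 change of −0.17 is
estimated at −0.137 — the per-trial near baseline carries a small,
documented attenuation from filter transients — and the 0.09 mm pupil
shift difference is recovered at 0.102 mm).

The same pipeline is available from the shell:

```
cogload run-all --seed 42 --n-participants 6 --out results/
cogload derive-key --sequence DAABEEDRRODHHRDSSELDD --n 1
cogload simulate --seed 3 --n-participants 2 --out sim/
cogload process-eeg --eeg sim/eeg_101.csv --log sim/task_101.csv --baseline near
```

File dialects (EEG CSV, gaze TSV, task-log CSV) are documented in
`cogload.io` and round-trip losslessly with the synthetic writers.

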