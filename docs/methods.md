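# Methods

This note documents the models behind `cogload`, the parameters that
matter, what the synthetic generators do and do not emulate, and the
numerical choices made where the design was genuinely open.

## Task model

An N-back block is a letter sequence; the subject answers whether the
current letter equals the one shown n positions earlier. The stock
experiment blocks are a 21-letter 1-back block (low workload) and a
22-letter 2-back block (high workload), each yielding 20 scoreable
responses, and constructed so that both blocks share the identical
response key `NYNNYNNYNNNYNNNYNNNY`. The key distributed with the
original stimulus set (`YNNNYNNNYNNYNNYNNYN…`) is inconsistent with the
letters; since both blocks independently derive the same key — clearly
the design intent — the letters are treated as authoritative and the
distributed key is kept only as a documented constant
(`task.DISTRIBUTED_RESPONSE_KEY`).

Scoring: the first n stimuli of a block are unscoreable and excluded
from the accuracy denominator; trials with no response inside the
3,000 ms timeout score incorrect and contribute no reaction time. Block
order is counterbalanced by participant-ID parity (odd → low block
first). Timing defaults: 3,000 ms stimulus timeout, uniform 1–2 s
inter-stimulus interval, 5 s inter-block rest, 10 s eyes-open rest
before the first block.

## ERD/ERS

For band power averaged over a reference window (R) and an activation
window (A), `erd(R, A)` returns `(R − A)/R` as a fraction and ×100 as a
percent. The implementation is literal: positive = power decrease.
Terminological conventions differ across the literature (some authors
label power increases "desynchronization"); the result object carries a
`sign_note` rather than reinterpreting the arithmetic. Both the
fraction and the percent are emitted because published workload tables
are sometimes on the fraction scale despite a ×100 definition.

Quantification follows the classical four steps: zero-phase band-pass
filtering (4th-order Butterworth applied forward–backward; order
configurable), squaring of amplitude samples to power, per-window
averaging with half-open `[start, end)` timestamp semantics, and
per-condition averaging across trials. Band edges default to Theta
4–8 Hz, Alpha 8–13 Hz, Beta 13–30 Hz and are configurable everywhere.
An optional 50/60 Hz zero-phase notch runs before band filtering.

Baselines: *near* = the 200 ms ending at each letter onset; *away* = a
single 3 s window at the start of the eyes-open rest, shared by all
trials. Activation = onset to response (timeouts get the full 3 s and a
flag). Trials whose reference or activation window yields no samples,
or a non-positive reference power, are excluded and counted — exclusion
accounting is a first-class output because per-measure Ns legitimately
vary.

**Filter-transient attenuation.** A zero-phase filter smears the
amplitude step at window edges in both time directions. The short near
baseline sits directly against the onset step, so per-trial
near-baseline ERD estimates are attenuated toward zero by roughly
0.03–0.13·d depending on band width and activation length; the single
away baseline, far from any step, is nearly free of this (measured
error ≤ 0.015 on noiseless tones across d ∈ [−0.5, 0.6]). This is a
property of any zero-phase pipeline with a 200 ms pre-stimulus
reference, not of this implementation; the recovery tests quantify it
and the tolerances in the test suite account for it explicitly.

## Eye metrics

Pupil dilation is diameter minus a per-eye baseline, the mean over
valid samples of the 10 s eyes-open rest (a per-trial pre-stimulus
baseline is available as an option). Ten metrics are computed per
stimulus interval; events (fixations/saccades) are assigned to an
interval by their start time and durations are not clipped — with
typical ~1.4 s intervals and ~200 ms fixations the edge effect is
bounded by two event durations. Metrics that cannot be computed are
flagged `None`, never silently zero; zero-event *rates* are an honest
0.0.

When only raw samples are available, I-VT velocity-threshold detection
is provided (defaults: 30 deg/s, 60 ms minimum fixation —
vendor-typical values); precomputed tracker events bypass detection.
Capture-rate validity requires both eyes valid by default (per-eye
policies available), and participant screening defaults to a 0.6
capture-rate threshold; the screening report always states the
threshold used. Astigmatism is summarized as the mean of the two eyes'
degrees.

## Statistics

Shapiro–Wilk gates the parametric/nonparametric choice (3 ≤ n ≤ 5000;
constant input is a degenerate-input error). The two-sample comparison
is Mann–Whitney–Wilcoxon reported with W = rank sum of the first
sample. For n1+n2 ≤ 16 without ties, the two-sided p enumerates the
exact null distribution of W (subset-sum counting); the null is
symmetric, so doubling the smaller tail equals the |W−E[W]| definition.
Otherwise a normal approximation with midrank tie correction and 0.5
continuity correction is used (cross-checked against
`scipy.stats.mannwhitneyu` in the tests, which is never the
implementation). Tests are two-sided throughout; no multiple-testing
correction is applied by default, with Holm and Benjamini–Hochberg
available per table. Spearman's rho is the Pearson correlation of
midranks, with an exact permutation p for n ≤ 8 and the t-approximation
otherwise.

One caveat is reproduced deliberately: per-trial observations are
pooled across participants as independent samples in the comparison
tables. That inflates effective n relative to a mixed-effects
treatment; the pipeline replicates the pooled design rather than
endorsing it, and the table metadata (per-measure Ns) makes the pooling
visible.

## Synthetic generators

The generators encode the study conditions so that tests have ground
truth. What they emulate, and their defaults:

* **Behavior** — RT lognormal per condition, (µ, σ) = (0.0583, 0.304)
  low and (0.3577, 0.447) high, i.e. medians 1.06/1.43 s and means
  1.11/1.58 s; accuracy Bernoulli 0.94/0.85. Sampled RTs ≥ 3 s become
  timeouts, so the realized accuracy is the Bernoulli p times the
  probability of answering in time (the recovery report uses this
  corrected truth). The unscoreable lead-in stimuli display for the
  full timeout with no response.
* **EEG** — 256 Hz, four channels. One sinusoidal carrier per band
  (6/10/20 Hz) with per-channel random phase, amplitudes 8/15/6 µV,
  over 1/f noise (2 µV RMS by default; exponent 1). A fractional power
  change d per (band, channel, condition) scales the carrier amplitude
  by √(1−d) inside activation intervals, so window mean power drops by
  exactly d (closed-form tested). Defaults are set to magnitudes on
  the scale consumer-headband N-back studies report (|d| ≈ 0.05–0.5,
  Theta positive, Alpha/Beta negative, larger in the high-workload
  condition). Blink/muscle artifacts are not modeled; line noise is
  off by default and available at 50/60 Hz.
* **Gaze** — 60 Hz; alternating lognormal fixations (median 170 ms
  in-task, 250 ms at rest, σ=0.55) and saccades (median 25 ms, σ=0.25);
  pupil = 3.5 mm baseline ± a small anisocoria offset + condition shift
  (0.11/0.20 mm) + slow drift (0.30 mm SD, ~5 s timescale) + white
  noise (0.08 mm). Samples drop i.i.d. (both eyes together) at a
  per-participant missing probability. No main-sequence saccade
  kinematics and no luminance model (the protocol controls lighting).
* **Astigmatism ↔ capture rate** — a Gaussian copula couples a
  lognormal astigmatism margin (median 150 degrees, σ=0.9) to a uniform
  missing-probability margin on [0.05, 0.80]. The copula correlation is
  set from the target Spearman via r = 2·sin(πρ/6); Spearman invariance
  under monotone margins makes the injected *population* correlation
  exact (default −0.55).
* **Interval-level pupil dilations** — for statistical power studies,
  `sample_interval_dilations` draws per-interval averaged dilations as
  a contaminated normal centered at the requested median: 93% of
  intervals at 0.644×SD, 7% at 2.96×SD (total SD equals the requested
  SD). The heavy tail reflects blink-recovery and tracking-jitter
  outliers that inflate pupillometry SDs; a pure normal cannot match
  the observed median/SD pairs of workload tables without implying
  implausibly noisy core measurements.

A cohort applies ID-parity counterbalancing (IDs default to 101…) and
can mark dropout IDs whose device streams were never recorded; those
bundles carry ground truth but no data, so analyzable-participant
counts fall out naturally.

What passing tests show — and do not. Recovery tests demonstrate that
the pipeline is a consistent estimator of effects *of the injected
form*: stationary narrowband oscillations, instantaneous power steps,
i.i.d. sample dropout, monotone copula coupling. Real EEG has
broadband nonstationary dynamics, artifacts, and electrode drift; real
pupillometry has blinks, luminance responses and bursty tracking loss.
Passing here validates the computation, not the physiology.

## Problem sizes and determinism

Every stochastic step runs from an explicit `numpy` Generator seeded
from user-supplied integers; sessions are seeded as
`[seed, participant_id]`, so cohorts are reproducible element-wise, and
re-running `run_all` with an identical config hash reproduces every
table byte-for-byte. Test-suite problem sizes were chosen as the
smallest that make the targeted property statistically unambiguous
(e.g. 6-session cohorts for ERD recovery, 2000 null replicates for the
type-I check, 500 replicates of n=18 for the Spearman recovery); they
are package choices, not statements about the hardware.

## Known limitations

* Clock alignment between streams assumes a shared Unix clock; only a
  constant-offset correction is provided, no drift model.
* The near-baseline attenuation described above is intrinsic; studies
  needing unbiased per-trial ERD magnitudes should prefer the away
  baseline or model the attenuation.
* No artifact rejection/ICA, no ERP component analysis, no
  gaze-to-AOI mapping or scanpath measures.
* The comparison tables inherit the pooled-trials independence caveat.
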