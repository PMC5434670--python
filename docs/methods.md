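# Methods

## RSA estimation

The estimator is the classic time-domain band-variance method: the R–R
interval series is interpolated as a piecewise-linear heart-period
function through (beat onset, interval) knots, sampled on a regular
10 Hz grid, band-passed with a 241-tap linear-phase FIR over
0.12–0.40 Hz (windowed-sinc design, Hamming window), and summarized per
30-s epoch as the natural log of the filtered signal's population
variance, in ln(ms²).

Design notes:

* **Filter-whole-record, epoch afterwards.** A 241-tap filter at 10 Hz
  spans 24 s. Filtering each 30-s epoch separately would leave almost no
  transient-free samples, so the record is filtered once and epochs are
  cut from the filtered signal. Epochs must lie at least half the filter
  length (12 s) inside the record; sessions therefore need a short
  lead-in/lead-out, which the session simulator provides (15 s).
* **Validation by response, not coefficients.** The historical tool's
  coefficients are not public; the design is instead held to response
  invariants: DC gain < 0.01, gain within 5% of unity at band centre,
  ≥ 20 dB attenuation at 0.05 and 0.50 Hz, exact coefficient symmetry.
  Its equivalent noise bandwidth is 0.248 Hz against the nominal
  0.28 Hz band (the −6 dB band edges of a windowed-sinc design), which
  the white-noise calibration test accounts for.
* **Heart period, not heart rate, is interpolated**: the ln(ms²) unit
  identifies the quantity as period variance, and period interpolation
  is the convention of the time-domain RSA literature.
* **Population variance** (divide by n) per epoch; at 300 samples per
  epoch the n vs n−1 choice moves ln-variance by < 0.004 and is fixed
  here once.
* **Degenerate inputs**: a constant epoch raises `"degenerate epoch"`
  instead of returning −∞; epochs touching the filter transient raise
  `"epoch not covered"`.

### Known bias: beat-rate sampling attenuation

Linear interpolation of a series sampled at the beat rate acts as a
triangle (Bartlett) reconstruction kernel. A respiratory oscillation at
frequency *f* with mean beat interval *T* seconds survives with
amplitude gain sinc²(*f·T*); the reported ln-variance is low by
4·ln sinc(*f·T*). At 75 bpm and *f* = 0.25 Hz that is −0.27 ln-units —
e.g. a 60 ms oscillation yields ≈ 7.23 rather than ln(60²/2) = 7.50.
The bias is a function of heart rate only, so it cancels in
baseline-referenced reactivity and in amplitude-ratio properties
(doubling the amplitude still shifts RSA by 2 ln 2), but absolute RSA
values are systematically below the continuous-signal value.
`rsa.interp_amplitude_gain(f, mean_rr_ms)` exposes the factor; the
parameter-recovery tests assert recovery of the analytic in-band
variance *through* this transfer, which the pipeline matches within
±0.05 ln-units on noise-free records.

## R-peak detection and artifact editing

Detection is a Pan–Tompkins-style chain: 5–15 Hz band-pass, squared
derivative, 150 ms moving-window integration, threshold at 20% of the
maximum, refractory period equal to `min_separation` (default 300 ms),
then refinement of each detection to the extremum of a ~20 ms-smoothed
copy of the raw signal (robust to sample-level noise, exact for
symmetric QRS shapes). Flat records raise `"no beats found"`. The
detector recovers ≥ 99% of planted peaks within ±1 sample at noise up
to 10% of R amplitude. Polarity is inferred from the dominant deflection
so inverted leads work unchanged.

Artifact flagging applies the 300 ms criterion to successive interval
differences, plus a second pass flagging intervals more than 300 ms from
the series median — the latter covers the first interval and runs of
mutually-consistent aberrant intervals (the two fragments left by a
spurious beat), which a pure successive-difference rule misses.

Editing resolves flags against the local median of clearly sound
context (excluding flagged intervals and their immediate successors),
with a ±20% tolerance:

* an interval ≈ (k+1)× median is divided into k+1 integer parts whose
  sum is exactly the original (k missed beats);
* a run of short intervals summing ≈ median is collapsed (spurious
  beat), preferring the candidate — forward run or merge with the
  predecessor — closest to the median;
* a flagged interval that itself matches the median has its flag
  cleared (it was implicated only by an aberrant neighbour);
* anything else stays flagged and is reported via a warning — the
  programmatic surrogate for the visual inspection step of manual
  workflows; nothing is ever edited silently.

Both edits conserve total recorded time exactly; rounding costs at most
1 ms per edit.

## Heartbeat counting

Per-interval score 1 − |recorded − counted|/recorded, averaged over the
task's four intervals. The formula goes negative when counted >
2×recorded; since the score is defined on [0, 1], negative values are
clamped to 0 with a logged warning rather than dropping the trial.
Recorded reference counts use the half-open window [start, end) over
beat onsets.

## Statistics

* Spearman is computed literally as Pearson on mid-ranks (average ranks
  for ties); p-values from the t transform, two-sided by default with
  the one-sided tail also reported, since some published Spearman
  p-values in this literature are one-sided.
* ANCOVA is a between-subjects general linear model (Type II F tests);
  adjusted marginal means are evaluated at the covariate grand means by
  default or at user-supplied values. Constant covariates are dropped
  with a warning so the model reduces exactly to one-way ANOVA. Effect
  size is partial η² = SS_effect/(SS_effect + SS_error) throughout —
  the convention of the statistical software era this battery mirrors.
  A repeated-measures ANCOVA over a 2-level within factor (e.g.
  baseline vs recovery) is handled by running the ANCOVA on subject
  means for the between effect.
* The mixed ANOVA (three 2-level within factors × two groups) uses the
  exact contrast decomposition: every within effect reduces to one
  per-subject contrast score; testing the unweighted group-mean of the
  contrast gives the within effect and the group comparison gives its
  interaction. For 2-level factors this reproduces the classical
  subject-stratified ANOVA F values exactly (verified against R's
  `aov` with `Error(subject/(a*b*c))` to all printed digits); no
  sphericity correction is needed with 2 levels.
* Tukey HSD uses the studentized-range distribution with the one-way
  error df (Tukey–Kramer for unequal n); verified against both direct
  studentized-range evaluation and statsmodels.
* Reciprocal normalization is x → 1/x for positive distances; summaries
  are reported back on the raw cm scale.
* Multivariate outlier screening uses squared Mahalanobis distance
  against the χ² quantile at 1 − α (default α = 0.001) — a labelled,
  reproducible stand-in for ad-hoc manual screening; it flags, never
  excludes.

## Synthetic data

The RR generator is a sinusoid plus white noise at the beat rate:
RR_k = mean_rr + A·sin(2π f t_k) + ε_k, chosen over integral-pulse
frequency modulation for closed-form in-band variance (A²/2 plus the
noise share 2·σ²·bandwidth/beat-rate). Defaults emulate a resting young
adult: 800 ms mean RR, 0.25 Hz respiratory frequency, 40 ms modulation.
ECG synthesis plants a raised-cosine QRS-like spike (40 ms, 1 mV) at
each beat; sessions follow the proxemics protocol (2-min baseline, two
counterbalanced 16-trial blocks of 30 s trials with 15 s inter-trial
intervals over thin/fat × far/near × gaze/no-gaze, 2-min recovery).

Cohorts draw (IA, resting RSA) per group from a bivariate normal with a
programmable correlation (+0.4 in controls, −0.4 in patients by
default), group moments taken from the published cohort this emulates
(n = 24/25; RSA 3.7 vs 5.3 ln(ms²), SD 1.4; IA 0.53 vs 0.41, SD 0.17;
covariate moments likewise), and comfort distance linear in RSA with a
standardized slope of −0.47 in controls and 0 in patients. The planted
4-way-interaction generator raises one cell by 0.4 ln-units in one
group against 0.15 cell noise — a standardized two-sample effect of
d ≈ 0.94, i.e. ≈ 90% power at n = 24/group, calibrated analytically.

What the generators do *not* emulate: real QRS morphology (P/T waves,
ectopy), respiratory-frequency drift and amplitude nonstationarity,
IPFM-style beat timing, or covariate–physiology correlations. Passing
the parameter-recovery tests therefore demonstrates correctness of the
computational chain under the stated signal model, not robustness to
every physiological irregularity of real recordings.

## Problem sizes

Simulation-based tests use 5-minute records (≈ 375 beats), 2-minute
records for artifact round-trips, 200 replicates for the mixed-ANOVA
power check, and 300–500 replicates for cohort calibration — sizes at
which the binomial error of every rate being asserted is several times
smaller than its margin.

## Known limitations

* Absolute RSA carries the sinc² sampling attenuation described above;
  comparisons across heart rates inherit a small differential bias.
* The 300 ms flagging rule is insensitive to spurious beats splitting
  an interval into two near-plausible halves only when both halves also
  sit within 300 ms of the series median (rare at resting heart rates).
* Mixed ANOVA supports 2-level within factors (which covers this
  design class exactly); general multi-level within designs are out of
  scope.
* Editing assumes a locally stationary rhythm; runs of arrhythmic beats
  are surfaced as unresolved flags rather than edited.
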