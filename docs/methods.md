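# Methods

## The task and its model

`tiltlab` models a two-alternative forced-choice (2AFC) orientation
identification experiment run with the method of constant stimuli.  On each
trial a *standard* Gabor at a fixed orientation (0°, 90°, −45° or +45°) is
paired with a *comparison* rotated by one of seven fixed offsets, the sign of
the rotation randomised per trial; the observer reports which interval
(temporal task) or which screen side (spatial task) contained the standard.
Cardinal standards use fine offsets (0.71–5.00°), obliques coarse ones
(3.57–25.00°), because orientation discrimination is several-fold worse at
oblique orientations (the oblique effect).  A run presents each offset level
ten times in random order; five runs give 350 trials per condition.

Proportion correct rises from 50% (chance) to 100% with offset and is
modelled by the two-parameter logistic

    y(x) = 50 + 50 / (1 + exp((x − a) / b)),

whose midpoint `a` — the offset yielding exactly 75% correct — is the
threshold and `b` its slope.  As printed this form is increasing only for
`b < 0`; the fitter works internally with a positive slope scale β in
`exp(−(x − a)/β)` and stores `b = −β`, so reported values match the printed
parameterisation without a sign trap.  There is no lapse parameter: the upper
asymptote is fixed at 100%, matching the two-free-parameter model.

## Fitting, uncertainty and exclusion

Fitting minimises the unweighted sum of squared differences between observed
percent correct (counts pooled over runs and rotation signs) and the
logistic, via Levenberg–Marquardt/TRF (`scipy.optimize.curve_fit`) with a
deterministic, scale-aware start: `a₀` interpolated at the observed
75%-point, `β₀` a quarter of the offset range.  Optimiser failure sets
`converged=False` rather than raising.

Two threshold standard errors are available:

* **asymptotic** (default): from the Jacobian-based covariance of the
  least-squares estimate.  Because unweighted least squares ignores the
  binomial variance profile of percent-correct data, this SE *underestimates*
  the sampling variability of `a` (simulation at a=10°, 50 trials/level:
  empirical SD ≈ 0.94° vs mean asymptotic SE ≈ 0.63°; a ±2·SE interval
  covers ≈ 74% rather than ≈ 95%).  It is retained as the default because it
  is the conventional companion of a least-squares fit, but it should be read
  as a lower bound.
* **bootstrap** (`se_method="bootstrap"`): parametric resampling of trial
  counts within levels.  Its ±2·SE interval attains ≈ 97% coverage in the
  same simulation and is what the test suite holds to nominal coverage.

A participant is excluded when any required condition (2 tasks × 4
orientations per session) fails to "reach threshold": the condition's maximum
observed proportion correct must be ≥ 75% and the fit must converge with `a`
inside the tested offset range.  Missing conditions count as failures.  The
operationalisation of "reaching threshold" beyond the 75% criterion is a
package decision.

## Synthetic observers

The generator provides ground truth for every downstream stage.  True
thresholds are log-normal:

    log a(i, s, task, orient) = μ(task, class) + S_i + E_{i,s} + ε,

with independent Gaussian subject (S), session (E) and residual (ε)
components.  The implied test–retest intraclass correlation of log thresholds
is σ_S²/(σ_S² + σ_E² + σ_ε²), so agreement is one controllable dial
(`ObserverPopulationConfig.with_true_icc`).  Slopes scale with the threshold
(`b = 0.30·a`), a constant Weber-like log-slope.  Responses are Bernoulli
draws from the logistic.

Defaults (geometric-mean thresholds: temporal cardinal 1.4°, temporal oblique
8°, spatial cardinal 2.2°, spatial oblique 12°; σ_S = 0.45, σ_E = 0.10,
σ_ε = 0.12, implied ICC ≈ 0.89) encode a strong cardinal/oblique split, a
temporal-task advantage and high web/lab agreement.  They produce a realistic
side effect: a tail of observers whose oblique thresholds exceed the largest
tested offset and are excluded (typically 1–3 of 18).  Web and lab are
exchangeable by default; `session_bias_factor` injects a systematic lab/web
bias and `learning_factor` a multiplicative second-session change, for
testing bias and learning detection.

What the generator does **not** emulate: attention lapses (no lapse rate),
display-dependent rendering error in the web arm, within-run nonstationarity
(fatigue/learning inside a session), and response-key errors.  Passing tests
therefore show the *analysis chain* is correct and well calibrated for data
that follow its assumptions, not that real web data do.

## Group inference

The threshold table is analysed with a two-way fully within-subjects ANOVA
(task × orientation), using the exact balanced-design decomposition with
subject, task, orientation and interaction strata, each within effect tested
against its own subject-interaction error.  Greenhouse–Geisser ε comes from
the covariance of orthonormally contrasted cell scores (Kronecker contrasts
for the interaction), bounded in [1/(k−1), 1]; Mauchly's W uses the standard
χ² approximation (p = 1 trivially at k = 2).  The headline p-value uses
GG-corrected df when Mauchly rejects at 0.05 and uncorrected df otherwise;
both are always reported, along with partial η² = SS/(SS + SS_error).
No Huynh–Feldt correction is offered.

Paired contrasts use Bonferroni correction (raw p × m, capped at 1).  Printed
Cohen's d values for paired designs are convention-dependent, so both `d_av`
(mean difference over the average condition SD) and `d_z` (mean difference
over the SD of differences) are reported.

## Agreement

* **ICC(2,1)** — single-measurement absolute agreement under a two-way
  random-effects model, from the row/column/error mean squares, with the
  standard F-based 95% CI.  Implemented directly; the test suite verifies
  exact agreement with `pingouin`'s ICC(A,1) and with a direct-summation
  oracle.  Pairs are pooled within task across the four orientation
  conditions (4 pairs per participant per task), with pooling level
  switchable.
* **Log Bland–Altman** — differences of natural-log thresholds; the antilog
  of the mean difference is the mean lab/web ratio (1 = no bias, > 1 = larger
  lab thresholds) and the antilogged mean ± 1.96 SD are ratio-scale limits of
  agreement.  Natural logs are a presentation choice; every reported quantity
  is a base-invariant ratio.  Shapiro–Wilk checks the log differences; a
  violation warns and flags but still reports.
* **Median absolute ratio** — median and IQR of exp(|log difference|), a
  direction-free typical measurement error, ≥ 1 by construction.
* **Learning check** — antilog of the mean first-minus-second-session log
  difference across participant-conditions; 1 means no order effect, and a
  20% second-session improvement maps to 1.25.
* **Sample-size planner** — Walter's F-based approximation for testing an
  acceptable against an expected ICC with k ratings per subject, rounded up.
  The default one-sided α matches the published reliability tables this
  planner reproduces (0.50 vs 0.75 with k = 8, α = 0.05, power 0.80 → 15
  subjects); a Monte-Carlo oracle in the tests confirms ≈ 80% one-sided
  rejection power at the planned n.

## Numerical and design choices

* Visual-angle conversion uses the exact `2·d·tan(0.5°)` chord, not the
  small-angle approximation — the difference matters at the spatial task's 8°
  eccentricity.
* Gabor rendering uses an odd-sized pixel grid so one pixel sits exactly at
  the envelope centre (mid-grey, sine phase); the Gaussian envelope is
  hard-truncated to zero beyond the truncation radius, and truncation smaller
  than the space constant warns rather than rejects.
* Orientations are degrees anticlockwise from horizontal; the ±45° labels are
  symmetric under the alternative vertical reference, recorded in config
  metadata because the analysis cannot distinguish the two.
* All scheduling/simulation randomness flows through a single
  `numpy.random.Generator`; the same seed reproduces schedules, responses and
  whole studies bit-for-bit.
* Timing fields (300 ms stimulus, 500 ms ISI, 800 ms response delay) are
  carried as configuration metadata only; no real-time presentation is
  simulated.

## Problem sizes used by the test suite

Simulation-backed checks run at deliberately chosen scales: 20 replicates of
a full 18-participant single-session study (50 400 trials and 144 fits each)
for the oblique-effect reproduction; 500 replicates at n = 200 pairs for ICC
bias/coverage; 10⁴ pairs for Bland–Altman calibration; 500–1000 replicates
for null-calibration of the ANOVA and Mauchly tests.  These sizes give
Monte-Carlo standard errors several times smaller than the asserted bands.

## Known limitations

* The asymptotic threshold SE underestimates (see above); use the bootstrap
  SE when the uncertainty itself matters.
* Mauchly's χ² approximation is first-order; p-values can differ in the third
  decimal from implementations carrying higher-order terms.
* The ANOVA requires a complete balanced table and refuses imputation, as
  does the ICC; participants failing exclusion simply drop out.
* The planner's Walter formula is itself an approximation; its power is
  nominal to within a few percentage points at small n.
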