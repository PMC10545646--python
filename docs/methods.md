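# Methods

`pulsegap` simulates and analyzes a pair of visuo-tactile temporal
psychophysics experiments: binary rate categorization of jittered pulse
trains, and 2IFC gap detection with unimodal and bimodal stimuli. This note
documents the models, the numerical choices, and what the synthetic-data
generator does and does not emulate.

## Stimulus model

**Rate trains.** A trial presents up to ten 50-ms pulses at a nominal rate of
4 Hz (nominal period k = 250 ms, nominal IPI 200 ms) or 6 Hz (k = 166 ms,
IPI 116 ms; the rounded 166 is used deliberately, not 1000/6). Each of the
nine IPIs is independently perturbed by additive Gaussian noise
x_i ~ N(0, sigma^2) with sigma = level * k for level in
{0, .05, .10, .20, .40}. Draws at or below the 1-ms floor are **redrawn**
(rejection sampling), not clipped: the resulting IPI distribution is a
truncated normal with no atom at the bound. Truncation matters only at 40%
noise, where it shrinks the IPI spread below sigma and raises the mean IPI
above nominal by ~5-6 ms; both effects are asserted by tests and propagate
into the observer calibration below.

The full isochronous 6-Hz train spans 9 x 166 + 50 = 1544 ms; the 4-Hz train
spans 9 x 250 + 50 = 2300 ms. The package reports these exact spans.

**Schedules.** Experiment 1: 16 blocks x 50 trials, modality (V/T)
alternating block to block with a counterbalance arm, and exactly 5 trials
per rate x noise cell in every block, so each modality x rate x noise cell
holds 40 trials and exactly 20% of trials are isochronous. The sources
describe the within-block allocation only as randomized; exact balance was
chosen so the printed design proportions are exact. Experiment 2: 9 blocks x
50 trials, three blocks per modality condition (V, T, VT) in randomized
order, 10 trials per gap {2, 4, 8, 16, 32} ms per block (30 per modality x
gap cell); the double-pulse/single-pulse order is randomized per trial, and
the single pulse always lasts 100 ms + gap so total duration carries no gap
information. Trial timing metadata (tones, delays, response windows, ITIs)
is recorded for completeness but never analyzed. All randomness flows from
one caller-supplied integer seed; schedules and simulations are bit-for-bit
reproducible.

## Synthetic observers

No generative observer accompanies the experimental design; the two models
here are the minimal stochastic observers that produce every qualitative
pattern the analyses are built to detect.

**Rate observer.** Perceived IPI_i' = max(0, IPI_i - rho_m) + eps_i with
eps_i ~ N(0, sigma_m^2); decision statistic = geometrically weighted mean of
the nine perceived IPIs (weights decay^i, i = 0..8, earlier intervals
weighted more — the functional form of early-interval weighting is a
stand-in, as no published form exists); respond "slow" iff the statistic
exceeds criterion c; lapse with probability `lapse` (fair coin response).
The persistence parameter rho models the sensory response outlasting the
pulse and filling the start of the empty interval; the visual default
exceeds the tactile one, which is the mechanism that biases visual trains
toward "fast" and yields criterion b > 1 on visual trials.

Defaults (calibrated by pre-freeze analysis and simulation scans so the
headline orderings emerge, then frozen): sigma = 60 ms (V) / 50 ms (T),
rho = 25 ms (V) / 5 ms (T), c = 152 ms, decay = 0.8, lapse = 0.02. The
criterion was placed by scanning for the value at which tactile miss and
false-alarm rates balance across noise levels *including* the truncation
shift at 40% noise; that is what keeps tactile b statistically
indistinguishable from 1 everywhere while visual b stays well above 1 at
low noise.

**Gap observer.** Each unimodal channel m detects the gap with probability
p_m(x) = 0.5 + (0.5 - lapse) * Phi((x - tau_m)/slope_m); tau_m is the gap at
channel d' = 1 (75% correct at zero lapse). Bimodal trials are judged by the
tactile channel alone with probability pi (`tactile_reliance`) and by the
visual channel otherwise. A probability mixture was chosen over optimal
variance-weighted integration deliberately: empirically, bimodal thresholds
sit slightly *above* tactile thresholds, which optimal integration cannot
produce but a pi < 1 mixture does. Defaults: tau_T = 5 ms, tau_V = 15.5 ms,
slope = 4 ms, pi = 0.85, lapse = 0.02 (visual threshold approximately three
times tactile).

**Between-subject heterogeneity.** Both observers carry `subject_cv`
(unit-mean lognormal scale factors per subject: on sigma and rho for the
rate observer, on each channel's tau for the gap observer; rate default
0.15, gap default 0.25), and the rate observer additionally
`criterion_jitter_cv` = 0.08 on c. These fields exist for two reasons.
First, without heterogeneity every across-subject correlation is pure
binomial noise, and the unimodal-bimodal dominance analysis has nothing to
detect. Second, t-tests of b against 1 over near-identical subjects become
sensitive to the small finite-sample bias of the nonparametric b estimator
(a few hundredths at 40 trials/cell); realistic subject spread keeps those
tests calibrated. The criterion CV is kept smaller than the sensory CV
because criterion displacement also erodes measured sensitivity.

**Response failures.** Small fractions of trials are simulated as
no-response (0.4% in the rate task, 0.9% in the gap task) and premature
responses (0.2%, rate task only) so the exclusion stage is exercised at the
empirically observed rates.

The generator does **not** emulate: reaction-time structure (RTs are
decorative lognormals), sequential early-stopping responding (the observer
always uses all nine intervals; `pulses_observed` is reported but constant),
learning or fatigue across blocks, or inter-channel correlation in subject
ability. Passing tests therefore certify the *analysis machinery* and the
qualitative effect structure, not any quantitative claim about human
observers.

## Exclusions and nonparametric signal detection

Rate-task exclusions: no-response trials, and premature responses (RT before
the second pulse's onset, i.e. before any rate information exists).
Gap-task exclusions: no-response trials only — short-RT 2IFC trials are
valid measurements and are retained. Exclusion accounting is conserved and
reported per reason.

Scoring maps "slow"|4 Hz to hits and "slow"|6 Hz to false alarms. Rates of
exactly 0 or 1 are corrected to 1/(2N) and 1 - 1/(2N) (N = trials of that
type in the cell); the correction stabilizes b and is applied uniformly.
Sensitivity A and criterion b are the Zhang-Mueller nonparametric
estimators (three-branch closed forms, transcribed in `sdt.py`); chosen over
parametric d' because the two rates' IPI distributions have unequal variance
at every nonzero noise level. Necessary identities are enforced by tests:
A = 0.5 whenever H = F; b = 1 whenever H = 1 - F; continuity across branch
boundaries (tolerance 1e-9); and b > 1 exactly when misses outnumber false
alarms (off the chance diagonal, where b = 1 by construction). Sub-chance
cells (H < F, unobserved in practice) are handled by reflection —
A -> 1 - A(F,H), b -> 1/b(F,H) — and flagged; the error-direction reading
does not extend to reflected cells. Estimates are computed per subject per
cell, then averaged for group summaries.

## Psychometric fitting and thresholds

The gap data are binomial counts per gap level. The model is the
two-parameter logistic with guess rate fixed at 0.5,
p(x) = 0.5 + 0.5 * logistic(b0 + b1 x), with gap duration in ms on a linear
scale (a log2 transform is available behind a flag for sensitivity
analysis). No lapse parameter is estimated; the generative lapse of 0.02
therefore appears as a small upward threshold bias (see below). Group fits
pool trials across subjects by default (subject-mean aggregation behind a
flag); subject-level fits are independent per-subject maximum likelihood —
a deliberate simplification of a random-slope mixed model, sufficient for
the correlation and slope analyses that consume subject summaries.

Numerics: quasi-Newton (BFGS) on the binomial negative log-likelihood with
analytic gradient, gradient tolerance 1e-8. The 2AFC link makes the
likelihood non-concave, and the conventional fixed start (0, 0.1) can land
in a negative-slope local optimum when low-gap cells sit near chance; the
fit therefore runs that start plus a deterministic linearized start (least
squares on logit(2p-1)) and keeps the better optimum, so fits remain
deterministic for fixed input. Complete separation (all levels perfect) and
runaway linear predictors are flagged as non-converged; no threshold is
derived from such fits.

The threshold is the inverse of the fitted curve at target proportion
correct 0.76 = Phi(1/sqrt(2)), the unbiased 2IFC performance at d' = 1:
x* = (logit(2*0.76 - 1) - b0)/b1. Bootstrap SEs resample trials with
replacement within each gap x modality cell (5000 resamples by default);
because trials within a cell are exchangeable Bernoulli outcomes this is
realized as a binomial redraw of each cell count at its observed proportion.
Non-converged resamples are dropped and counted, with a warning above 20%.

**Recovery target.** Tests verify that the group threshold recovered from
100 replicate simulated studies (14 subjects x 30 trials/cell) lies within
15% of the generating curve's true 76%-correct gap, obtained by directly
inverting the generative channel model (closed form for unimodal channels,
root-finding for the mixture). The true gap — not tau — is the right
comparison point: tau is the d' = 1 point of the zero-lapse channel, and
with the default lapse the observable 76% point already sits ~8% above
tau_T before any estimation error, with a further ~7% bias from fitting a
lapse-free logistic to lapse-attenuated probit data. Both biases are
properties of the published analysis applied to a lapsing observer, and
both are visible in the reported numbers.

## Secondary statistics

* b vs 1: one-sample t-tests per modality x noise cell, Bonferroni-corrected
  for the 10 cells (p multiplied, capped at 1; CIs widened to 1 - alpha/10).
* Simple effects of modality: paired t-tests per noise level, unadjusted
  (reported as such in output).
* Within-subject error bars: Cousineau subject-centering with the Morey
  sqrt(C/(C-1)) correction — the method is unspecified in the source
  analyses; Cousineau-Morey is the field standard. Both within- and
  between-subject intervals are computed and labelled.
* Unimodal-bimodal dominance: Pearson correlation between per-subject mean
  accuracies, plus the OLS slope of bimodal on unimodal accuracy tested
  against 1 (the complete-dominance prediction).

Omnibus two-way repeated-measures ANOVAs (with sphericity corrections) are
deliberately out of scope; they are routine and orthogonal to the pipeline's
contribution.

## Problem sizes and determinism

Default analyses run the full published design (28 simulated subjects x 800
trials; 14 subjects x 450 trials; 5000 bootstrap resamples). The test suite
uses smaller cohorts for unit tests, 100 replicates for recovery checks, a
million draws for the IPI-floor property, and five replicate 14-subject
cohorts when asserting the correlation ordering (a single cohort of 14 is
noisy). Every stochastic stage consumes a `numpy.random.Generator` seeded
from the caller; reruns are bit-identical.

## Known limitations

* The nonparametric b estimator carries a small negative finite-sample bias
  at 40 trials/cell; it is visible only with unrealistically homogeneous
  subjects.
* Pooled-trial group psychometric fits flatten slightly under subject
  heterogeneity, inflating group thresholds by a few percent relative to the
  subject-mean curve.
* The external-data adapter's default column mapping is an educated guess
  documented in `io.py`; deposited datasets may need an explicit mapping
  file.
* Visual criterion bias in the rate observer does not relax toward neutral
  at 40% noise as human criteria do; modelling that would need a
  noise-dependent criterion, which the analyses under test do not require.
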