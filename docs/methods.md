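# Methods

## Problem setting

EEG recorded during fMRI carries artifacts with no clean ground truth to
score their removal against. The package implements two coupled pieces of
machinery around this problem:

1. **Joint decorrelation (JD)** — a spatial-filter method that estimates and
   removes the residual ballistocardiogram (BCG) artifact, the
   heartbeat-locked contamination that survives average-artifact subtraction
   and carbon-wire-loop regression; and
2. **a microstate-based reliability framework** — noise reduction is judged
   by whether it *raises the test-retest reliability* of EEG microstate
   metrics between a contaminated recording and a clean reference recording,
   on the premise that a clean in-scanner recording should agree with an
   out-of-scanner recording of the same person as well as two out-of-scanner
   recordings agree with each other.

Everything is exercisable on synthetic data with known ground truth; no
recorded EEG ships with the package.

## Joint decorrelation

Epochs of 0.7 s starting 0.2 s before each ECG R-peak are collected into a
tensor (channels x epochs x samples). Blocks of N = 25 consecutive epochs
are averaged — phase-locked artifact survives averaging, ongoing brain
activity is suppressed by roughly 1/N in variance — and the averages are
concatenated. The same is done for an equal number of uniformly random
reference triggers. With C_art and C_ref the spatial covariances of the two
stacked-average matrices, the generalized eigendecomposition

    C_art W = C_ref W diag(lambda),    W' C_ref W = I

yields components ordered by the ratio of heartbeat-locked to reference
variance. Raw eigenvalues are inflated by the averaging itself, so the
noise-reduction ratio gamma_bar — the mean diagonal of W' C_ref_raw W,
where C_ref_raw is the covariance of the *unaveraged* reference epochs — is
measured empirically and the eigenvalues rescaled:

    lambda~ = (lambda - 1) / gamma_bar + 1.

For independent epochs gamma_bar is about N (verified in the tests at 15%);
autocorrelated data give smaller values, which is exactly why the ratio is
measured rather than assumed. lambda~ = 1 means heartbeat locking explains
nothing beyond averaging; a threshold (1.05 loose … 1.20 strict) applied to
lambda~ selects components to reject, and the cleaned data are
X - A_rej (W_rej' X) with patterns A = C_ref W (so A W' = I and unrejected
component time courses pass through unchanged). At threshold 1.00 sampling
noise alone puts about half the eigenvalues above threshold, which the
acceptance script reproduces; this null calibration is the reason practical
thresholds sit above 1.

Because the reference triggers are random the fit is replicated (default 10
seeds). Numerical choices: epochs are channel-demeaned before covariance
computation (config-exposed); C_ref receives shrinkage
(1-eps) C_ref + eps tr(C_ref)/C I with eps = 1e-6 so that average-referenced
(rank C-1) data remain solvable; reference epochs may overlap R-peak epochs
(no exclusion by default); ties at the threshold are kept.

## Microstate pipeline

Topography maps are sampled at peaks of global field power (GFP, the
population SD across average-referenced channels — a per-sample measure of
topographic signal strength). Maps are clustered with
atomize-and-agglomerate hierarchical clustering (AAHC), chosen for
determinism: starting from singleton clusters, the cluster contributing the
least global explained variance (GEV, GFP-weighted squared spatial
correlation with the prototype) is dissolved and its members reassigned to
the best-matching survivors, until k clusters remain. Prototypes are the
dominant eigenvector of the members' outer-product sum, which makes the
procedure exactly polarity-invariant; plain averaging would cancel maps of
opposite sign. Two-level clustering (per subject, then across pooled
subject prototypes) yields group templates; a `max_maps` parameter (default
1000 in the two-level path) evenly subsamples GFP peaks to bound the
quadratic clustering cost on long recordings.

Templates are ordered by Hungarian assignment of absolute spatial
correlation against four analytic canonical maps built on the sensor
positions (two oblique dipolar fields, an anterior-posterior gradient and a
fronto-central radial blob). These canonical maps are a stable ordering
anchor, not an empirical claim about scalp physiology.

Backfitting assigns each GFP-peak map to the template with the highest
absolute spatial correlation; non-peak samples inherit the nearest peak's
label (ties to the earlier peak). Temporal smoothing then absorbs segments
shorter than a 20 ms window into the neighboring label with the better mean
fit; the non-smoothness `penalty` (default 1) is the margin by which a short
segment's own fit must beat the best neighbor to survive — at 1 (a full
correlation unit) absorption is unconditional. The exact smoothing objective
of the established toolboxes is not published in a closed form; this rule is
documented, deterministic and config-exposed.

Metrics per template: mean segment **duration** (ms), **occurrence**
(segments per second of assigned time), **coverage** (% of assigned time),
and **transition** probabilities between distinct types (diagonal zero, rows
normalized over boundaries leaving the type). Coverage sums to 100% and
coverage_fraction = duration x occurrence when the sequence is fully
assigned; both are enforced in tests.

## Reliability

Per metric and per template (and per transition cell), agreement between two
sessions over n subjects is the two-way random, single-measure,
**absolute-agreement** ICC — ICC(A,1) in McGraw-Wong terms:

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)),  k = 2,

which, unlike the consistency form, penalizes systematic session offsets.
Cells with a constant column are flagged missing and excluded. Per-metric
means are Fisher-z aggregated (tanh of the mean atanh; values at ±1 clamped
to ±(1-1e-6)); negative ICCs are retained un-floored to avoid biasing the
mean. Significance uses a permutation test (default 1000 shuffles of one
session's subject order, one-sided, add-one estimator) rather than
parametric confidence intervals, which are uninformative at small n. Mean
ICCs are labelled poor (< .50), moderate ([.50, .75)), good ([.75, .90)),
excellent (>= .90); boundaries closed on the left.

The implementation is a direct ANOVA-sums-of-squares computation; the test
suite cross-checks it against an independent variance-components oracle
(1e-10) and against pingouin's ICC(A,1).

## Evaluation workflow

The three-step procedure: (1) confirm reliability between two clean
reference sessions; (2) sweep the JD threshold over a grid (default 1.05 to
1.20 in 0.01 steps, plus a "none" control that skips the JD step) with
several random-reference replicates, scoring each (threshold, replicate)
cell by the mean ICC of the cleaned in-scanner metrics against the
reference metrics, and marking cells where duration, occurrence and
coverage all reach 0.5; (3) cross the candidates of two recording days and
pick the passing combination with the smallest threshold difference, ties
toward lower thresholds. "Wider and more continuous passing range" is made
mechanical as the longest contiguous passing run per replicate, ties broken
by total passes then replicate index. Welch PSD and baseline-corrected
evoked responses are provided as conventional quality checks.

## Synthetic data

The generator produces the minimal structure the methods assume, with full
ground truth:

* **Microstate EEG**: K = 4 smooth average-referenced unit-GFP template
  maps (random degree-<=3 polynomial fields of electrode position, pairwise
  |corr| < 0.5 by rejection sampling), a semi-Markov label sequence with
  gamma dwell times (mean 80 ms, CV 0.5 — typical resting-state values),
  next state uniform over the others, a GFP envelope of rectified 4-12 Hz
  noise at mean 10 uV (making GFP peaks as dense as in band-passed resting
  EEG, one or more per state), plus white sensor noise (2 uV default).
* **BCG artifact**: R-peaks at 1 Hz with 50 ms RR jitter; each beat spawns
  3 damped-oscillation component waveforms (3-8 Hz, 0.21 s delay after the
  peak) mixed through fixed spatial patterns. Artifact patterns are a
  smooth field plus an electrode-level rough component: wire/electrode
  motion couples less smoothly across the scalp than neural fields, and
  this also prevents the artifact subspace from collapsing onto the
  template subspace, which no realistic channel count would exhibit.
  `bcg_snr` is the artifact RMS relative to the clean-signal RMS; all
  artifact terms are additive, so zero amplitude reproduces the clean
  recording bit-for-bit under the same seed.
* **Optional** gradient-like periodic artifact with volume triggers, and
  CWL channels sharing a low-pass motion source with the EEG.
* **Cohorts**: per-template subject means mu_{s,k} ~ N(80, sigma_b^2) and
  session means mu + N(0, sigma_w^2) with sigma_b^2/(sigma_b^2 + sigma_w^2)
  equal to the requested ICC (total SD 20% of the mean — a realistic
  between-subject spread of mean microstate duration), independently per
  template so duration, occurrence and coverage all carry subject-level
  signal. The measured end-to-end ICC is attenuated below the generative
  value by metric estimation noise, which shrinks with recording length;
  at 3-minute recordings the attenuation is within the tolerances the
  tests assert.

What the generator does **not** emulate: 1/f background spectra, alpha
topography structure, eye/muscle artifacts, heart-rate variability beyond
RR jitter, nonstationary artifact topographies, and volume-conduction
realism. Passing tests therefore demonstrate the estimators' correctness
and calibration under the stated model, not performance on recorded EEG.

## Problem sizes used in the test suite

The suite and acceptance script run the study logic at reduced scale,
chosen as the smallest sizes at which the estimators are well conditioned:
null calibration on 16-channel 10-minute recordings over 20 seeds;
end-to-end reliability recovery with n = 100 subjects and 3-minute
recordings; the sweep experiment with 12 subjects, 32 channels and
4-minute sessions. Four minutes of 1 Hz heartbeats give ~9 averaged blocks
of N = 25 epochs; with fewer (e.g. 2-minute recordings, 4 blocks) the JD
covariances are too noisy for stable filters, which is visible as erratic
cleaning rather than failure of the method.

## Known limitations

* The smoothing rule and the non-peak interpolation rule are documented
  reconstructions of under-published toolbox behavior, config-exposed
  rather than claimed as ground truth.
* Backfitting locates state boundaries only to within half the inter-peak
  spacing, so generative coverage is reproduced to a couple of percentage
  points, not exactly.
* The JD out-projection is oblique (it preserves unrejected component time
  courses, not Euclidean geometry); when the artifact dominates the
  reference covariance it distorts the surviving topographies more, which
  is the practical reason the evaluation prefers moderate thresholds over
  aggressive ones.
* ICA/ICLabel component classification is out of scope; the pipeline
  accepts an externally produced rejection projection instead.
* EDF writing pads the last data record to a whole second (a format
  constraint); round trips are exact for whole-second recordings.
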