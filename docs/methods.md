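# Methods

This note documents the models, parameter choices and numerical decisions
behind `enosecp`, and what the synthetic-data experiments do and do not
demonstrate about real e-nose data.

## Signal model

A MOS gas sensor's resistance changes when volatile organic compounds
adsorb on its heated oxide surface.  The simulator reproduces the three
phases of a measurement cycle — by default 20 s of pre-injection baseline,
200 s of reaction, and 120 s of cleaning — with first-order kinetics:

- baseline phase: `B + m·t + noise`, with per-recording drift slope `m`
  drawn from N(0, drift_slope_sd²);
- reaction phase: `B · (1 + A_eff · (1 − exp(−t/τ_rise))) + m·t + noise`;
- cleaning phase: exponential decay toward baseline with time constant
  `τ_decay`.

First-order exponentials are the minimal-parameter shape matching the
saturating rise and decay of real MOS transients.  Class identity enters
only through the amplitude matrix `A[class, sensor]`; the effective
amplitude of a specimen is the class amplitude times a lognormal factor
with unit mean and coefficient of variation `within_class_cv`
(multiplicative, so responses stay sign-consistent).  Defaults:
baseline 1.0 signal unit (the baseline normalisation removes its value
anyway), `τ_rise` ∈ [15, 30] s, `τ_decay` ∈ [20, 40] s per sensor,
`within_class_cv` = 0.1, `noise_sd` = 0.01, `drift_slope_sd` = 10⁻⁴ /s —
values giving signal-to-noise and drift magnitudes typical of bench-top
MOS arrays.  The default sampling rate is 10 Hz rather than the 100 Hz of
typical DAQ hardware: every extracted feature depends on the curve shape,
not the raw rate, and the lower rate keeps simulated datasets small.  The
rate is configurable for anyone who wants the full-rate regime.

In `make_signatures`, class amplitude rows are a shared per-sensor base
pattern plus `separation` times a fixed Gaussian offset (scale 0.2), so
mean pairwise between-class distance is exactly linear in `separation`
and `separation = 0` collapses all classes onto one pattern.

The fast path `simulate_feature_table` skips signals entirely and draws
80-dimensional feature vectors from class-conditional isotropic Gaussians
whose means are `separation` times standard-normal vectors.  Nothing in
the real measurement chain is Gaussian-guaranteed; this generator exists
to give the conformal machinery data with controlled exchangeability and
class overlap, not to mimic sensor physics.

`MODERATE_SEPARATION = 0.35` is the default and the value used throughout
the statistical test suites.  It was fixed once, because at the suite's
problem sizes it puts 10-class forced accuracy in the 70–80 % band that
realistic e-nose studies report — classes overlap enough that reliability
information is meaningful, yet structure is clearly learnable.

## Preprocessing

Readout electronics measure the voltage across a load resistor in series
with the sensor; `voltage_to_resistance` inverts the divider,
`Rs = R_load · (V_supply − V)/V`, rejecting samples outside
(0, V_supply).  The divider constants of any particular instrument are
configuration, not constants of the method; data already in resistance
units can skip the step.  `baseline_correct` computes
R = (Rs − Rb)/Rb with Rb the per-sensor mean over the declared baseline
window (the entire pre-injection phase).  This makes traces dimensionless,
removes per-sensor gain, and is invariant to positive rescaling of a
trace.  A zero baseline mean is rejected rather than patched.

## Features

Per sensor: `Rmax = max|R|`; `Rint` = trapezoidal integral of R over the
full recorded window; and the maximum absolute exponential moving average
of the first difference, `y(k) = (1−a)·y(k−1) + a·(R(k) − R(k−1))` with
`y(0) = 0`, at a ∈ {0.005, 0.05, 0.5}.  Three decisions were genuinely
open:

- *EMA input interpretation.*  The recurrence is read as the EMA of the
  first difference, `a·(R(k) − R(k−1))`; the alternative reading
  `a·R(k) − R(k−1)` is not a dimensionally coherent moving average.
- *EMA range.*  The recurrence runs over the full corrected series.  The
  feature is a maximum dominated by the injection transient, so running it
  on a decimated series changes little; an optional `decimate_to` flag
  exposes that variant.
- *Integration window.*  The integral spans the whole recording (baseline
  through cleaning) as the least arbitrary choice; the baseline window
  contributes ≈ 0 after correction.

All five features are positively homogeneous of degree 1 in R, which the
property tests exploit.

## Conformal prediction

The nonconformity measure is `α = 1 − p̂(label | x)`, the standard
classification measure, applied uniformly to both underlying models: an
RBF-kernel SVM (C = 6000, γ = 0.001) with sigmoid (Platt) calibration on
internally cross-validated decision values, and a 500-tree random forest
using vote fractions.  SVM features are z-scored with statistics fitted on
the proper-training portion only; forest features are left raw.  The
measure sits behind `FittedScorer` so margin-based alternatives can be
plugged in.

ICP uses a stratified proper-training/calibration split, defaulting to
2/3 / 1/3 — common ICP practice; the fraction materially affects
efficiency, so it is an explicit argument.  P-values use the +1-smoothed
count with inclusive ties (α_j ≥ α_c), unsmoothed; every p-value is
therefore at least 1/(n_cal + 1).

ACP draws K = 5 stratified bootstrap resamples of the full training size.
The in-bag draw (duplicates retained) fits the fold scorer; the
out-of-bag examples — about 36.8 % of the data for large classes — form
the fold's calibration set; fold p-values are averaged.  A draw whose
out-of-bag set is empty or whose in-bag part loses a class is redrawn up
to a bounded retry count.  All randomness flows from one user seed
through derived per-fold seeds, so a fitted ACP is reproducible.

Forced prediction returns the label of the highest p-value, breaking ties
toward the lowest label index and logging the tie.  Confidence is
1 minus the second-highest p-value; credibility is the highest p-value.

### Validity of aggregated p-values

Each fold's ICP p-value is exactly valid under exchangeability, but an
average of K imperfectly correlated valid p-values is not: it is
conservative at small significance levels and anti-conservative at large
ones, because averaging pulls extreme p-values toward the middle.  In the
test suites this is visible for ACP-SVM, whose empirical error rate
exceeds ε by up to ~0.15 for ε ∈ [0.7, 0.9]; ACP-RF stays within the
3-SE band because its fold p-values are more strongly correlated.  This
is a property of p-value averaging, not an implementation artifact, and
it matches the behaviour reported for aggregated predictors in the
conformal literature.  At the small ε values that matter in practice,
aggregation is conservative and improves forced accuracy.

## Evaluation protocol

Stratified, seeded k-fold cross-validation (default 10-fold) emits one
p-value vector per specimen.  Reported quantities: overall and
fold-averaged forced accuracy; the calibration curve (error rate = share
of specimens whose region excludes the true label, i.e. whose true-label
p-value is ≤ ε) and the efficiency curve (mean region size) on an ε grid
of 0.01…0.99 step 0.01, fine enough to resolve both curves; indicator
means and SDs; and a mean-centred 2-component PCA with explained-variance
fractions.  Curves are written as CSV, plots (optional) as images, so no
test depends on rendering.

## What the synthetic experiments show — and what they do not

Passing suites demonstrate that the conformal machinery is correct (oracle
equivalence, aggregation identity, nesting), that validity holds where
theory promises it, and that aggregation's accuracy advantage appears
under controlled moderate overlap (ACP − ICP ≈ +5 to +8 accuracy points
at the suite's problem sizes, for both underlying models).  They do not
certify behaviour on real e-nose data: the generators have no sensor
chemistry, no humidity/temperature confounds, no session drift
correlations between specimens, and Gaussian class-conditionals are an
idealisation.  Claims about a real instrument require recordings from
that instrument.

## Problem sizes and numerical notes

The statistical suites use 10 classes with 40–65 specimens per class and
80 features, with held-out test sets of 100–150 specimens and 10 dataset
seeds for the accuracy comparison; the end-to-end determinism check runs
the full signal pipeline at 10 classes × 10 specimens and 1 Hz.  These
sizes give stable Monte-Carlo estimates (binomial SE bands are computed
explicitly in the tests) while keeping a full run inexpensive.

Degenerate inputs are rejected rather than repaired: empty series,
out-of-range smoothing factors or significance levels, single-class
training sets, splits without calibration examples, classes smaller than
the fold count, zero baselines.  The ACP aggregation identity is asserted
to 10⁻¹²; closed-form feature checks use relative tolerances of 10⁻⁶ or
tighter; exact rational p-values are compared exactly.
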