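# Methods

`posturekit` implements a wearable posture-detection pipeline with two
branches: upper-limb gesture recognition from two-channel surface EMG
(sEMG), and lower-limb gait-mode recognition from a triaxial ankle
accelerometer fused with forefoot/heel plantar-pressure sensors.  Both
branches feed a multiclass RBF-kernel SVM whose hyperparameters (C, γ) are
tuned by a genetic algorithm scored with cross-validated accuracy.  No
recordings ship with the package; a synthetic-data module generates
trials with known ground truth so the whole pipeline can be evaluated
end to end.

## sEMG active-segment detection

The detection statistic is the moving-average energy of the band-passed
signal x(i):

    E(i)   = x(i)²                                  (instantaneous energy)
    MA(i)  = (1/N) Σ_{j=i..i+N−1} E(j)              (forward window, length N)
    T      = 0.02 · max_i MA(i)                     (relative threshold)

A motion onset is declared at the first index t where MA(t) ≥ T and the
entire window of N samples from t onward stays ≥ T; an offset requires a
sustained sub-threshold run of the same length.  Ties MA == T count as
supra-threshold, which makes the identically-zero case deterministic (an
all-zero record yields no segments and a warning).  Because T is a fixed
fraction of the sequence maximum, detection is invariant to overall
amplitude scaling, and the maximum is taken per record.

Defaults: N = 128 samples; threshold fraction 0.02; minimum segment
length N; merge gap N/2.  Gap-merging is applied before the minimum-
length filter so a chattery burst whose merged extent is long enough is
kept.  Segment indices are reported in raw-signal coordinates with the
averaging window anchored at its left edge; a burst still open at the end
of the record is closed at the final sample and logged.  On synthetic
bursts with burst-to-baseline energy ratio ≥ 100 the detector recovers
every burst with boundary error ≤ N samples of an exhaustive-scan oracle
(this is one of the acceptance checks).

## Filtering

All filters are Butterworth, order 4, applied forward–backward
(`sosfiltfilt`) so the zero-phase response leaves segment boundaries
unshifted.  sEMG is band-passed 20–450 Hz, the conventional surface-EMG
band; acceleration and pressure are low-passed at 20 Hz.  The corner
frequencies are package defaults, exposed in the function signatures, not
facts about any particular recording system.  No notch filter is applied:
the synthetic data contain no power-line interference.

## Feature banks

**sEMG branch** (per detected segment, per channel):

* standard deviation of the amplitude, population divisor N
  (SD = √((1/N) Σ (x_i − x̄)²));
* the largest singular value of each subband of a level-3 discrete
  wavelet transform (basis db4 by default; levels 3–5 supported, giving
  level+1 subbands a_L, d_L, …, d_1).

A 1-D coefficient vector has no singular values, so each subband is
embedded as a Hankel trajectory matrix with `svd_embed_rows` rows
(default 10) — row r is the subband lagged by r samples — and σ_max of
that matrix is the feature.  With one embedding row this degenerates to
the subband's Euclidean norm.  One σ per subband keeps the feature count
at level+1 per channel; with 2 channels and level 3 the vector has
2 × (1 + 4) = 10 entries.  The trajectory-matrix embedding and the
one-σ-per-subband choice are the package's design decisions; the largest
singular value summarises the dominant oscillatory energy of the subband
and is stable under small perturbations.

Transforms use periodization boundary handling after zero-padding the
segment to a multiple of 2^level, which keeps the decomposition
orthonormal: total coefficient energy equals signal energy to floating-
point precision (verified to 1e-8 relative in the tests).

**Gait branch** (per sliding window; 2 s windows, 50% overlap):

* per-axis acceleration mean, SD and variance (population divisor), 9
  values;
* the 8 terminal-node energies E(j) = Σ d(j)² of a db1 (Haar) level-3
  wavelet-packet decomposition of each axis, in natural frequency order,
  24 values;
* the mean forefoot-minus-heel pressure difference
  F̄ = (1/N) Σ (F_i − f_i), positive when forefoot loading dominates,
  1 value.

The fusion vector is exactly the concatenation of the acceleration-only
(33) and pressure-only (1) vectors, 34 features in total.  Features are
z-scored with a scaler fitted on training data only; the scaler is stored
with the model.  RBF-SVMs are scale-sensitive, so standardization is part
of the training contract, not a preprocessing option.

## GA-optimized RBF-SVM

The binary classifier solves the soft-margin dual

    min_α ½ Σ_ij α_i α_j y_i y_j K(x_i, x_j) − Σ_i α_i
    s.t.  Σ_i α_i y_i = 0,  0 ≤ α_i ≤ C,
    K(x_i, x) = exp(−γ ‖x_i − x‖²),

with decision f(x) = sgn(Σ α̂_i y_i K(x_i, x) + b̂).  Multiclass problems
use one-vs-one: one machine per class pair, trained on that pair's
samples, majority voting at prediction with ties broken by the largest
aggregate signed margin and then lexicographic label order.  The inner
quadratic program is delegated to scikit-learn's SVC and treated as a
replaceable solver: the test suite independently verifies the box and
equality constraints of every trained machine (tolerance 1e-6) and checks
sign decisions against a dual solved from scratch with SLSQP on small
instances.

The genetic search evolves real-valued chromosomes (log₂C, log₂γ) over
the boxes log₂C ∈ [−5, 15], log₂γ ∈ [−15, 3] (the community-standard
search ranges).  Defaults: population 50, 50 generations, crossover
probability 0.8 (BLX-0.5 blend), mutation probability 0.1 (Gaussian,
σ = 1 in log₂ units), tournament selection of size 3, generation gap
0.95.  The gap's complement — the top 5% of the population — survives
each generation unchanged, which makes the best fitness non-decreasing;
generations are counted after the initial population.  Fitness is
stratified 5-fold cross-validated accuracy with the scaler refitted
inside each training fold; one fold assignment, drawn from the run's
seed, is used for every candidate so fitnesses are comparable.  One
individual of the initial population is always pinned to the conventional
default (C = 1, γ = 1/n_features), so the search can never return
something worse than that baseline under its own fitness.  All
randomness — fold assignment and every GA operator — flows from a single
seeded generator, making a run bit-reproducible from its config.

## Synthetic data

The generator produces the structures the pipeline consumes, not
physiology:

* **sEMG gestures** (left_turn / stop / right_turn; channels "biceps",
  "extensor"; 1 kHz; 3 s trials): band-limited (20–450 Hz) Gaussian noise
  amplitude-modulated by a Tukey envelope of 1 s at a random onset.  This
  amplitude-modulated-noise surrogate is standard for surface EMG because
  everything downstream consumes energy/variance structure only; no
  motor-unit dynamics are simulated.  Per-gesture envelope scales on the
  biceps channel (100 / 5 / 30 in baseline-noise units, baseline SD 0.5)
  reproduce the qualitative ordering left ≫ right ≫ stop observed on the
  biceps in real steering gestures, without targeting any particular
  printed values, which are subject-specific.  A `contrast` dial
  geometrically interpolates each gesture's amplitude toward the
  across-gesture mean: contrast 0 makes the classes identical, and
  downstream accuracy falls to chance — the null configuration used in
  the tests.

* **gait modes** (walking / waiting / upstairs / downstairs / falling;
  100 Hz; 10 s trials; 3 acceleration axes in g plus forefoot and heel
  pressure in arbitrary load units, load 10):

  - periodic modes are sinusoid-plus-second-harmonic accelerations at a
    mode cadence (walking 2.0 Hz, stairs 1.6 Hz) with anti-phase
    half-wave-rectified forefoot/heel pressure; the loading duty is
    shifted forefoot-ward for upstairs (1.4/0.6) and heel-ward for
    downstairs (0.6/1.4), so the pressure-difference mean is positive
    upstairs and negative downstairs by construction;
  - upstairs and downstairs deliberately share cadence and axis mix and
    differ only ~20% in overall intensity, while every trial draws a
    lognormal intensity jitter (σ = 0.15) and a cadence jitter
    (SD 0.05 Hz): acceleration alone therefore resolves the two stair
    modes only partially, and their reliable separation must come from
    the pressure channel — the designed mechanism behind the
    fusion > acceleration-only > pressure-only comparison;
  - waiting is a noise floor (accelerometer noise 0.008 g, slow 0.01 g
    postural sway) over a balanced static stance whose forefoot/heel
    weight distribution drifts as an Ornstein–Uhlenbeck process
    (stationary SD 1.1% of load, correlation time 2 s), chosen so the
    windowed pressure-difference spread matches walking's partial-cycle
    leakage: the single pressure feature cannot tell the two apart by an
    artificial variance signature;
  - falling is quiet stance until a single decaying 5 Hz oscillation
    (3 g, τ = 0.15 s) at a random time in the 50–70% span of the trial,
    after which both pressure channels read zero.  Pressure sensors add
    Gaussian noise with SD 10% of load (clipped at zero).

  Windowing is 2 s with 50% overlap.  Falling trials contribute only
  windows that cover at least half of the 0.5 s impact span: pre-fall
  stance windows and post-impact lying-still windows would mislabel
  other postures as "falling".  This makes the falling class smaller than
  the others (≈2 windows per trial versus 9), an imbalance the one-vs-one
  SVM tolerates.

What the generator does **not** emulate: inter-subject variability,
electrode placement and crosstalk, non-stationary fatigue drift,
gravity orientation and sensor tilt, real gait double-support dynamics,
or sensor dropouts.  Passing the end-to-end checks therefore shows the
pipeline is correctly assembled and that its feature set carries the
designed class structure — not that the printed accuracies would be
reproduced on human recordings.

## Experiments and evaluation

Both experiments split at the **trial** level (70/30 by default): every
segment or window of a trial stays on one side, so within-trial
correlation cannot leak into the held-out estimate.  The gait comparison
runs the three fusion settings on identical generated trials and an
identical split, isolating the feature set.  Reports carry per-class and
overall accuracy, a confusion matrix, the GA's chosen (C, γ) and CV
fitness, a config snapshot, and the seed; identical config + seed gives
bit-identical reports.

Problem sizes used by the default experiments and the acceptance script:
30 trials per gesture (≈90 segments) and 16 trials per gait mode
(≈650 windows), with the GA at population 20 / 15 generations — enough
budget for the two-parameter search to settle while keeping a full run in
the minutes range on one core.  The GA defaults (50/50) remain available
for larger studies.

## Numerical choices and degenerate inputs

* Population (divisor N) variance and SD throughout the feature bank.
* Moving-average output may carry −1e-17-scale negatives from convolution
  rounding on zero stretches; clipped to 0.
* Zero-variance features in the scaler get scale 1 (feature stays 0 after
  centering) instead of dividing by 0.
* An all-zero energy sequence yields threshold 0, a warning and no
  segments.
* Validation errors name the offending quantity (Nyquist violations,
  too-short segments with the minimum length, ragged rows with their line
  number).

## Known limitations

* The pressure branch reduces to a single scalar per window; with five
  classes its ceiling is the three-way ambiguity among walking, waiting
  and falling, which is intentional in the comparison design.
* The trajectory-matrix SVD keeps only σ_max per subband; subband
  spectra with two comparable components are summarised by the larger.
* The GA's fitness is window-level CV on the training trials; a
  trial-grouped CV would be stricter but needs more trials per fold than
  the default sizes provide.
* `falling` is recognised by its impact transient; slow (syncope-like)
  falls without an impact signature are outside the generator's model.
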