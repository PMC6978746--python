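# Methods

## Signal model

Each FSR channel reports force in kilograms at 1 kHz. A gesture repetition
is modelled as a trapezoidal burst: linear rise (default 0.1 s), held
plateau (2.0 s), linear fall (0.1 s), followed by a rest gap (1.5 s); a
trial of R repetitions of G gestures therefore contains exactly R·G
plateaus, each recorded in the ground-truth timeline as a half-open,
0-based sample interval. The measured force is

    f_c(t) = preload + offset_c + scale_c · P[c, g(t)] · e(t) + ε_c(t),

clamped at 0 kg (an FSR cannot indicate negative force), where `P` is the
3×8 plateau matrix (channel × gesture, kg), `e(t)` the trapezoid envelope,
and `ε ~ N(0, noise_sd²)` i.i.d. per sample.

Parameters and defaults:

* `preload = 0.1 kg` — the armband fastening force; rest sits at this level
  on all channels.
* `P` — plateau forces chosen so that each muscle dominates the gestures it
  anatomically drives (flexor carpi ulnaris: flexion/adduction; flexor
  carpi radialis: flexion/abduction; extensor digitorum: extension/fingers
  abduction; clenched fist co-contracts all three, peaking at 1 kg). All
  pairwise plateau-column distances exceed 6× the noise SD, so per-subject
  gesture clusters occupy disjoint regions of mean-force space.
* `noise_sd = 0.02 kg` — 2% of the largest plateau. Large enough that SDs
  are informative features, small enough that the mean-vs-median deviation
  of a held plateau stays within the ~2% the method reports.
* Rise/fall = 0.1 s — brisk posture transitions, consistent with the sharp
  burst edges of the recorded signals. The 40% threshold then retains only
  ~60 ms of ramp on each side of a 2 s plateau, so segment means stay
  within 2% of their medians; markedly slower transients (≳0.15 s) would
  push retained-ramp bias past that bound.
* Inter-subject variability: per-channel multiplicative gain
  `~ lognormal(0, 0.25)` and additive offset `~ U(−0.05, 0.05) kg`, drawn
  once per subject. This emulates armband placement/tightness differences
  and is what degrades pooled-subject and re-donned classification.

The transduction model maps force to digitized voltage,
`V = R_G · V_CC · (G₀ + s·F)` clamped to [0, V_CC] and quantized to 12
bits. The printed design fixes only the affine form, the supply (5 V) and
the gain resistors (850/790/960 Ω); the calibration constants are chosen so
all channels share a 2 V/kg slope (sensitivity ∝ 1/R_G, i.e. equalized
channel gains), a 0.25 V rest baseline, and 2 kg saturation — placing ~1 kg
plateaus mid-range on the ADC. Below saturation the map is exactly affine,
so inversion recovers force within one ADC step divided by the slope;
saturated samples are flagged and not inverted.

## Batch pipeline

Preprocessing subtracts each channel's minimum over a rest reference (the
rest block of a session; for standalone recordings the recording's own
minima, since inter-burst gaps are at rest) and divides all channels by the
single global maximum absolute value, so the preprocessed session peaks at
exactly 1. Segmentation selects the channel with the largest peak-to-peak
amplitude (ties → lowest index) and thresholds it at
`min + 0.40·(max − min)`; maximal supra-threshold runs are the gesture
segments, after bridging sub-threshold dips shorter than 0.1 s and dropping
runs shorter than 0.5 s (robustness additions; the threshold itself is the
method's). Because the threshold is relative, segmentation is invariant
under any joint positive affine transform of the signal, and normalizing
before or after segmenting yields identical segments.

The segmentation channel is chosen per gesture block, matching the
per-class recording protocol. For mixed-sequence sessions (the randomized
second-session test) a single channel cannot recover gestures that are weak
on it — a gesture peaking at 0.1 kg on the selected channel never crosses
40% of a 1 kg peak-to-peak — so those sessions are windowed from the cue
timeline (the video-guided protocol timing) instead. Rest produces no
threshold crossing either; rest instances are fixed-length windows taken
from the rest block's known hold intervals, letting rest participate as a
class.

Features are the per-segment mean and sample (n−1) SD per channel, computed
on normalized signals for classification (kilogram-scaled features are
available by extracting from raw recordings). Segments are ≥500 samples, so
the ddof choice is numerically immaterial but fixed for reproducibility.
The median is deliberately not a feature: on these plateaus it tracks the
mean within ~2%, at extra real-time cost.

## Classifiers and evaluation

LDA/QDA use the standard Gaussian closed forms with frequency priors;
covariances are ridge-regularized by `1e-8·tr(Σ)/d·I` only when the
condition number exceeds 1e10 (the synthetic clusters are tight, so pooled
covariances can be nearly singular). Ties in argmax go to the lowest class
code, a convention applied uniformly (k-NN distance ties, SVM vote ties
after summed-decision-value comparison).

The linear SVM solves each one-vs-one dual by SMO with second-order
working-set selection, KKT tolerance 1e-6. First-order (maximal violating
pair) selection was observed to zigzag on near-duplicate rows of the tight
clusters; the second-order rule converges in tens of iterations on the same
problems and matches a reference QP solution to ~1e-7 relative primal
objective. Default C = 1, matching a standard toolchain default; no
hyperparameter search.

Stratified 10-fold CV shuffles each class with a fixed seed (42) and deals
rows round-robin over folds, falling back (with a warning) to unstratified
folding when a class has fewer rows than folds. The headline accuracy is
the mean of per-fold accuracies; the pooled held-out accuracy is also
reported, and confusion matrices (rows = true, columns = predicted)
accumulate every held-out prediction. Leave-one-out is n singleton folds
and deterministic. The ablation evaluates all 7 non-empty sensor subsets;
the reproducibility test classifies a second session (new variability draw
= re-donned armband) with the first session's model, no retraining.

## What the generator does and does not show

The synthetic cohort reproduces the *structure* of the armband study —
protocol shape, 80×7 databases, non-overlapping per-subject clusters,
pooled-subject and re-donned degradation, real-time windowing — but its
within-subject trial-to-trial variability is only sensor noise plus
threshold jitter. Real repetitions vary in contraction strength, co-
contraction and posture drift, so within-subject CV accuracies here sit at
the top of the range a well-separated real subject can reach (~100% vs
mid-90s); pooled and re-donned accuracies are likewise optimistic in
absolute terms while preserving the qualitative orderings (3 sensors ≥ 2 ≥
1; combined < per-subject mean; second session < first). Passing tests
validate the pipeline's correctness and these orderings, not field
performance. Burst timing is deterministic (no cadence jitter), noise is
Gaussian and white (no drift, motion artifacts or crosstalk), and
saturation is a hard clip.

## Problem sizes

Default study conditions: 10 subjects × (10 repetitions × 8 gestures),
~38 s per gesture block at 1 kHz. The test suite uses these conditions for
the cohort-level checks and smaller sessions (2–5 repetitions) where only
pipeline mechanics are exercised; trend tests (re-donning degradation,
real-time majority labels) average over 20 independent subject seeds.
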