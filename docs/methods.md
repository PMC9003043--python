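# Methods

This note documents the models, conventions and design choices behind
posturekit, in the spirit of a model-description appendix: what each stage
assumes, which parameters matter, and what the synthetic benchmark does and
does not establish.

## Problem setting

A monitored room is observed by one or more depth cameras, each emitting a
30 Hz stream of 17-joint 3-D skeletons. The task is per-frame
classification into five classes — standing (1), sitting (2), lying (3),
dangerous sitting (4, a slumped-in-chair alarm posture), and transition
(5, any movement between two consecutive static postures). Per-frame (not
per-action) output is required because the classifier feeds a downstream
alarm-decision layer that must react to the subject's current state.
Two classifier branches are compared: a static MLP that sees one frame at
a time, and sequence-to-sequence LSTM networks that label every frame of a
60-frame window using its temporal context.

## Coordinate conventions and missing data

Each camera's stream is mapped into a common room-fixed frame by a rigid
transform `p_room = R p + t` with `R` proper orthonormal (validated to
1e-9). The room `z` axis is vertical; frame indexing is 0-based and
timestamps are in seconds.

Temporal holes — stretches where the tracker produced no skeleton — are
filled with *sentinel frames* whose every coordinate is the literal 999.
A gap counts as a hole when consecutive timestamps differ by more than 1.5
frame periods: large enough to tolerate timestamp jitter, small enough
that a regular stream is never padded. A gap of `g` seconds receives
`round(g/period) − 1` sentinels at nominal spacing, which makes the filling
idempotent. Non-sentinel frames that happen to contain the value 999 in a
coordinate trigger a validation warning (the sentinel is a value collision
by construction).

## Features

Seventeen joint angles are computed between adjacent body-segment vectors
(head = Neck→Head, trunk = hip-midpoint→shoulder-midpoint, shoulder =
Neck→Shoulder, arm = Shoulder→Elbow, forearm = Elbow→Wrist, hip =
SpineBase→Hip, thigh = Hip→Knee, leg = Knee→Ankle, foot = Ankle→Foot; the
segment mapping is the minimal one consistent with the angle definitions).
The angle is `arccos` of the clamped cosine, in [0°, 180°]. Four absolute
angles give the signed inclination of the head (A) and trunk (B) segments
out of the horizontal plane, in [−90°, 90°]: pitch is
`atan2(z, |forward component|)` and roll `atan2(z, |right component|)`.

The roll/pitch decomposition uses a *body-attached* horizontal frame: the
right axis is the horizontal projection of the summed hip and shoulder
left-to-right lines and the forward axis completes the triad with the
vertical. A room-fixed sagittal/frontal decomposition would change with
the subject's heading, which is arbitrary in a free-living room and
differs across cameras; the body-attached choice makes all ten candidate
features exactly invariant under rotations about the vertical axis plus
horizontal translations (tested to 1e-9), which is what permits pooling
the four camera views into one database. When the projection degenerates
(body axis vertical), the room `x` axis is used as fallback. Because the
horizontal component enters through its absolute value, the sign of roll
and pitch comes from the vertical component alone; mirroring the skeleton
across the sagittal plane therefore swaps the left/right-paired joint
angles and preserves the magnitudes of the unpaired ones.

The ten candidate classifier features are A_pitch, A_roll, B_pitch,
B_roll, ξ (head–trunk), μ₂ (head–right shoulder), δ₂ (trunk–right hip) —
each divided by 180, giving joint-angle features in [0, 1] and
absolute-angle features in [−0.5, 0.5] — plus the vertical coordinates of
the head, the shoulder midpoint (Z_C7) and the hip midpoint (Z_Hc), each
divided by the subject's height. Sentinel frames propagate: all ten
features of a sentinel frame are 999, and by default they reach the
sequence classifier literally (a `standardize` switch exists for
experimentation but is off, matching the deployment condition in which
dropouts hit the classifier unfiltered).

## Databases

The frame (MLP) database removes every sentinel frame — a static
classifier can learn nothing from an all-999 placeholder. The sequence
(LSTM) database keeps them: each sentinel inherits the class of the last
preceding non-sentinel frame (a leading run with no predecessor takes the
first following label — the only non-destructive completion of the rule),
the stream is cut into contiguous non-overlapping 60-frame windows (2 s at
30 Hz), and only windows consisting entirely of sentinels are discarded.
Windows are non-overlapping because overlap would double-count frames in
the database bookkeeping; trailing remainders shorter than one window are
dropped and counted rather than padded, since padding would need a label
that does not exist. Train/test splits are by subject, never by frame, so
the test subjects are unseen; the split is configuration, not hard-coded.

## Wrapper feature selection

**Exhaustive SVM (static branch).** All 1023 non-empty subsets of the ten
features are scored by fitting an RBF-kernel SVM (scikit-learn defaults:
C = 1, gamma = 'scale') on a stratified 70% of the training frames and
taking the misclassification rate on the held-out 30% as the subset's
loss. One split is drawn per run and shared by all subsets so that scores
are comparable. Ties are broken toward smaller subsets, then lower mask
value, making the result deterministic.

**Steady-state GA (sequence branch).** Chromosomes are 10-bit masks;
population 50, 10 generations, with one all-ones chromosome forced into
the initial population so the full feature set is always evaluated. The
initial population counts as the first generation, so at most
50 × 10 = 500 proposals are scheduled. Operators (standard steady-state
choices, all configurable): binary tournament selection (k = 2), uniform
crossover (p = 0.9), per-gene bit-flip mutation (p = 1/10), empty
offspring repaired by setting one random gene, and an offspring replaces
the current worst individual when it improves on it. Fitness is the
percentage of correctly classified frames (%CC) of a reference network —
LSTM(100) → 30% dropout → LSTM(75) → 30% dropout → dense → softmax —
trained 20 epochs on the chromosome's columns and scored on a held-out
30% of the training sequences. A cache keyed by mask serves re-proposed
chromosomes, so duplicates cost nothing; the duplicate counter reproduces
the distinction between scheduled proposals and distinct evaluated
combinations.

## Classifiers

**MLP.** Three hidden layers of 10 tanh ("sigmoidal tangent") neurons and
a 5-unit softmax output, trained with Adam for at most 1000 epochs with an
internal 30% validation split and early stopping (the training cap is part
of the protocol; the stopping rule is the package's choice since none is
prescribed). A 10-fold stratified cross-validation precedes the final fit
in `train_mlp`. The implementation buys scikit-learn's `MLPClassifier`;
with a fixed `random_state` the fit is deterministic.

**LSTM family.** Implemented in a compact NumPy engine
(`posturekit.nn`): LSTM cells with gate order (input, forget, cell,
output), Glorot-uniform input weights, orthogonal recurrent weights,
forget-gate bias 1; bidirectional layers concatenate a forward and a
time-reversed pass per frame; inverted dropout; a time-distributed dense
head emitting one 5-way softmax per frame; manual backpropagation through
time (verified against numerical gradients to 1e-4 in double precision);
global-norm gradient clipping at 1.0; Adam with learning rate 3e-3
(chosen as a stable default for these layer widths). Parameters are
float32 and all randomness flows from one `numpy.random.Generator`, so a
fixed seed gives a bit-identical trajectory on one machine. Variants:
`LSTM`, `LSTM2FC` (one LSTM then two dense layers), `2LSTM`, `BLSTM`,
`2BLSTM`/`2BLSTM2D` (two bidirectional layers, one dropout after each —
`2D` allows two different rates), `2BLSTM1D` (single dropout after the
second layer); the name-to-layout mapping for the dropout suffixes is an
interpretation and is kept configurable. Hidden widths follow the
convention hidden2 = hidden1 − 25 over the explored grid {75, 100, 125}.
Training uses mini-batches of 32 sequences of 60 frames for 50 epochs; by
default the sequence order is re-permuted every epoch, which changes
mini-batch composition and measurably improves generalization. Per-frame
loss weighting is uniform: the scripted database is approximately
balanced by construction.

## Evaluation protocol

Confusion matrices are reported as raw counts and percent-of-total (cells
summing to 100). Per-class one-vs-rest metrics: sensitivity TP/(TP+FN),
specificity TN/(TN+FP), precision TP/(TP+FP), F-score the harmonic mean of
precision and sensitivity; a ratio with zero denominator is reported as
absent (NaN), never as 0. Repeated runs are summarized by element-wise
mean ± SD matrices and by the distribution of per-run accuracies, and two
configurations are compared with the two-sided Wilcoxon rank-sum test at
α = 0.05. Per-class metrics are computed per run and then aggregated (not
on pooled predictions), matching how run distributions are reported.

## Synthetic benchmark

The generator emulates the acquisition protocol the pipeline targets:
subjects cycle through the four static postures with 10 s holds and 2 s
smooth transitions, at 30 Hz, with heights drawn uniformly from
[1.55, 1.90] m. Each posture has a 17-joint keyframe template in fractions
of height with a small seeded per-subject variation (SD 0.005·height);
transitions interpolate keyframes with a minimum-jerk profile
(10s³ − 15s⁴ + 6s⁵), chosen because it is smooth and velocity-bounded and
gives transition frames genuinely intermediate feature values — the hard
case that motivates the sequence model. Noise: per-coordinate Gaussian
jitter (default SD 0.01 m) and missing-frame bursts with per-frame start
probability 0.005 and geometric length of mean 15 frames, which become
sentinels; these defaults are invented (stated in every manifest) and are
of the order of consumer-depth-camera behavior. The 2 s transition
duration is a typical sit-to-stand time. Multi-camera output renders the
same room-frame movement through each camera's inverse extrinsics.

What the benchmark does *not* emulate: realistic biomechanics and
inter-subject movement style, occlusion-dependent (pose-correlated) noise,
per-joint error spectra of a real depth tracker, or labeling ambiguity at
transition boundaries. Synthetic holds are near-constant in feature space,
so absolute accuracies here are far above what real recordings yield;
passing the benchmark establishes that the pipeline's machinery is
correct (features separate the postures, selectors recover planted
structure, the sequence model exploits temporal context), not that any
particular accuracy transfers to real data.

## Benchmark sizes and reference quantities

The reference benchmarks (in `posturekit.benchmarks`, shared by the test
suite and `scripts/acceptance.py`) use desk-scale sizes chosen so the full
cycle runs in minutes on one CPU:

- *Selector recovery*: 5 classes × 50 frames with two informative columns
  (class-mean separation ≫ within-class SD 0.3) among eight unit-noise
  columns; 10 seeds for the exhaustive SVM. The GA landscape is
  `fitness = 10 − Hamming distance` to a hidden 3-bit target, whose unique
  optimum is verified by brute force before the 10 GA runs.
- *Sequence-vs-static comparison*: the headline run trains 2BLSTM2D
  (125/100, 45% dropout) for 50 epochs on two subjects × four posture
  cycles (≈ 11,400 frames) and tests on one held-out subject; the
  paired-seed comparison repeats a reduced configuration (two cycles,
  50/25 units, 15 epochs, MLP capped at 400 epochs) over ten seeds, each
  seed regenerating its own data so the pairing is over complete
  experiments. The compared quantity is transition-class (5) sensitivity,
  the class where temporal context matters most; the direction of the
  comparison, not its magnitude, is the claim.

## Known limitations

- The NumPy engine is CPU-only and single-threaded beyond BLAS; it is
  sized for the desk-scale benchmarks, not for hundreds of thousands of
  real frames.
- Optimizer and initialization differ from the original MATLAB toolbox
  implementations of this kind of pipeline, so absolute accuracies are not
  transferable across implementations even on identical data.
- The exhaustive wrapper refits 1023 SVMs per run; on large frame tables
  it should be given a subsample (the CLI caps at 20,000 frames by
  default).
- `rank_sum_compare` applies no multiple-testing correction across many
  architecture comparisons; that mirrors the evaluation protocol it
  implements.
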