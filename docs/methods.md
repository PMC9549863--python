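# Methods

This note documents the models, conventions, and design choices behind
`gaitwear`, and what the synthetic cohort does and does not establish.

## Signal model and preprocessing

Raw streams per sensor: tri-axial acceleration (m/s², gravity 9.81),
tri-axial angular rate (deg/s), barometric altitude (m, quantized to the
altimeter's 0.1 m resolution), all at 50 Hz. Units and axis conventions
are an I/O-boundary decision of this package (enforced at read time), not
a property of any particular device.

Four derived series per sensor, all via order-2 Butterworth filters applied
forward–backward (zero phase, no group delay):

| series | filter | rationale |
|---|---|---|
| posture acceleration | low-pass 0.5 Hz | gravity/orientation component |
| activity acceleration | band-pass 0.5–11 Hz | voluntary-movement band |
| filtered gyro | low-pass 11 Hz | de-noised angular rate |
| filtered altitude | 0.5 s moving median, then low-pass 0.5 Hz | de-quantized slow altitude |

The 0.5 / 11 Hz cutoffs are standard choices for human-activity analysis
at 50 Hz (gait fundamentals and harmonics sit well below 11 Hz; postural
drift below 0.5 Hz); they live in one `FilterConfig` block and are
overridable from the pipeline config. Forward–backward filtering uses
odd-reflection padding of about three filter time constants — scipy's
default pad is much too short for sub-Hz cutoffs and visibly bends ramps
at segment edges. The median despiker likewise uses anti-symmetric edge
extension so that stair-bout altitude ramps keep their net change (within
5 cm for ramps up to ~0.3 m/s). The first/last second of any filtered
segment is still treated as an edge region in example-based assertions.

## Windows and labels

128-sample windows, 64-sample hop, half-open 0-based indexing; a trailing
partial window is discarded (the feature contract requires fixed length).
The window label is the per-sample mode; ties break to the label whose
first occurrence in the window is earliest — deterministic and
order-stable. Transition windows record their flanking class pair
(directionless, e.g. sit↔stand) and the flanking class dominant within
the window.

Task label spaces: binary gait detection maps {walking, stairs}→gait and
{lying, sitting, standing}→no-gait; the 5-class task is the identity.
Under the gait task the A-or-B transition rule has two literal
consequences, implemented as stated: stand↔walk windows accept any
prediction (their pair maps to {no-gait, gait}), while lying↔sit and
sit↔stand windows are correct only for "no-gait".

## Features (134 per sensor)

For each tri-axial channel (posture acc, activity acc, gyro): per axis —
mean, population variance, min, max, range, median, IQR, RMS, skewness,
excess kurtosis, spectral energy, spectral entropy, dominant frequency —
plus the three pairwise inter-axis Pearson correlations (42 per channel).
For altitude: mean, variance, min, max, range, least-squares slope, net
change, RMS of first differences (8). Totals 3·42 + 8 = 134 per sensor;
670 for the five-sensor configuration.

Spectral features use a Hann-tapered, unpadded 128-point spectrum; DC is
excluded from energy, entropy, and the dominant-frequency search
(resolution fs/128 ≈ 0.39 Hz). A constant axis yields correlation 0 by
convention, and spectral features 0 when the non-DC power vanishes. The
feature list is defined in one registry (`feature_registry()`), so it can
be amended without touching pipeline code.

Standardization is per subject and per feature with the population (1/n)
standard deviation; zero-variance features map to 0. Statistics are
computed over all of a subject's windows regardless of train/test role:
because normalization never crosses subjects, it cannot leak information
under leave-one-subject-out evaluation. For the unilateral configurations
(C/D) the physical side differs per subject, so feature columns are named
by role (wrist/ankle) to align across subjects.

## Models and evaluation protocol

Grids (fixed, declared order):

* SVM: RBF kernel, class-balanced weights, C ∈ {0.01, 0.1, 1, 10};
* logistic regression: elastic net (saga), intercept, class-balanced,
  C ∈ {0.001, 0.01, 0.1} × l1-ratio ∈ {0.01, 0.1};
* kNN: n ∈ {1, 2, 4, 8, 12, 16, 20, 24, 28, 32} × {uniform, distance}.

Nested LOSO: for each held-out subject, the inner loop runs LOSO over the
remaining subjects for every grid point (fit on inner-train without
transition windows, score on the inner subject with transitions, using
transition-aware balanced accuracy), selects the best mean score (ties to
the first point in grid order), refits on the full outer training set,
and scores the held-out subject. A runtime assertion verifies the
held-out subject contributes no window to any fit. Reports aggregate
fold metrics as unweighted mean ± SD (subjects weighted equally).

Multiclass balanced accuracy is the macro mean of per-class
(sensitivity + specificity)/2; for the binary task this reduces to the
usual (sens + spec)/2. Confusion matrices credit a correctly classified
transition window to the predicted class and an incorrect one to the
dominant flanking class; pooled matrices sum fold counts and
row-normalize to 100 % (empty rows are reported as undefined, not 0).
A class absent from a fold's truth has undefined sensitivity/PPV and is
excluded from that fold's macro mean with a warning.

The "reduced" grid used for quick runs is one representative mid-grid
point per model (SVM C=1; LR C=0.01, l1-ratio=0.1; kNN n=8, uniform).
The grid's extreme first entries were deliberately not used for this:
an RBF SVM at C=0.01 underfits so strongly on clearly separable data
(two-digit accuracy drops) that a single-point grid built from it would
not exercise the pipeline meaningfully.

Score-vs-impairment correlation uses Shapiro–Wilk (α = 0.05) on both
variables to choose Pearson (both normal) or Spearman; p-values are raw
(no multiple-testing correction), as noted in the report output.

## Synthetic cohort

`generate_session` synthesizes five-sensor sessions from an activity
script: static postures are posture-specific gravity directions plus
noise; walking/stairs add cadence-locked sinusoids (fundamental + one
harmonic) on ankle acceleration/gyro, arm swing at the wrists, and a
small chest bounce; stairs add an altitude ramp of 0.17 m per step,
alternating ascent/descent, quantized to 0.1 m after noise; transitions
interpolate gravity orientation over durations near 4.0 / 2.7 / 4.7 s
(lying↔sit / sit↔stand / stand↔walk) and add a movement burst. All limb
amplitudes on the affected side are multiplied by
`affected_attenuation` ∈ [0, 1] (1 = symmetric). Gyro quantities,
including `arm_swing_amp`, are in deg/s.

Two design points matter for realism of the induced difficulty:

* per-bout orientation jitter is largest at the wrists (SD 25° vs 3–4° at
  chest/ankle), because wrist pose within a posture genuinely wanders
  (desk work, eating, gesturing) — this is what makes wrist-only posture
  discrimination hard;
* postural sway is added only at chest/ankle during standing — it is a
  trunk/lower-limb cue.

Together these create the intended difficulty gradient across sensor
setups (all ≥ unilateral ≥ wrists-only) without hand-tuning any
classifier-facing quantity.

The default cohort (14 subjects, ~27 min sessions) draws cadence
(0.6–1.0 strides/s), arm-swing amplitude (18–32 deg/s), attenuation
(0.35–0.70), stair timing, and stair pattern per subject, with clinical
scores (BBS, 10 m walk speed, TUG, FAC) drawn within plausible mobility-
impaired ranges and loosely tied to the attenuation. The activity
schedule tiles a ~9-minute template whose bout chain respects the
adjacency graph (lying↔sitting↔standing↔{walking, stairs}); transition
time is fixed by the chain's counts × mean durations, and the remaining
time is allocated to activity classes proportional to the calibration
shares (lying 4.8 %, sitting 20.2 %, standing 32.8 %, walking 19.5 %,
stairs 6.5 %). Per-bout ±15 % duration jitter is renormalized within
class, so class totals are exact in seconds and the emitted shares land
within ~0.2 points of the targets for default-length sessions. Short
sessions (a few minutes) carry proportionally more transition time, so
their activity shares sit a little lower; the calibration claims apply to
the default session length.

What the simulator does *not* model: real biomechanics (signals are
harmonic bursts, not gait dynamics), free-living confounders (elevators,
vehicles), magnetometer channels, sensor drift or misplacement, and the
full within-class variability of human movement. Passing tests therefore
demonstrate correctness and internal consistency of the pipeline and
that the protocol can recover structure it is designed for — not
clinical-grade performance on real recordings.

## Problem sizes and numerical choices

End-to-end model checks use 14 subjects with 6-minute sessions
(~280 windows/subject, ~3,900 windows at 670 features) and the one-point
reduced grid — sizes chosen so the full suite runs in minutes on one
core while keeping the study-scale subject count for the LOSO structure.
Calibration checks use the full 27-minute default sessions. The
chance-level check fits kNN on per-subject permuted labels and compares
the resulting balanced accuracy against a 200-permutation rescoring null
band around 50 %.

All randomness flows from explicit integer seeds (`numpy` Generator);
the pipeline default seed is 20220926. Reports serialize with sorted
keys so reruns are byte-identical. Stage outputs are cached by a content
hash of the governing config sections plus the seed.

## Known limitations

* The 134-feature list is a fixed, documented convention; other feature
  sets of the same shape would serve equally.
* Inner-loop aggregation is mean-of-fold-scores (subjects equally
  weighted), one of two defensible readings of per-subject aggregation.
* Transition windows' confusion-matrix attribution is a convention
  (predicted class when correct, dominant flanking class otherwise);
  counts are kept per fold so other conventions can be recomputed.
* The simulator's separability is by construction; absolute accuracy on
  synthetic cohorts should not be compared with accuracy on clinical
  data.
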