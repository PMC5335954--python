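# Methods

## Detection model

The detector operates on one 513-sample frame per record, cut around the
critical point — the record-wide maximum of the tri-axial Euclidean norm —
with 192 samples (1.5 s at 128 Hz) of look-back and 320 samples (2.5 s) of
look-ahead. One frame per record is deliberate: the package models episodic
classification of recorded events, not continuous sliding-window
monitoring. Ties for the maximum break to the earliest index, which is
deterministic and stable under record concatenation. Records too short for
the window are, by default, completed by replicating the boundary sample;
the pad counts are kept on the frame so downstream consumers can filter.
The `reject` policy refuses such records instead.

Stage one is a four-threshold triage on the frame extrema v = max Norm_xyz
and w = max Norm_hori. The fall thresholds are the maxima of (v, w) over
training ADL frames, the ADL thresholds the minima over training fall
frames, so by construction no training frame can end up on the wrong side.
Inequalities are strict: a frame sitting exactly on a threshold is deferred
to stage two rather than decided, the conservative choice. When the classes
separate cleanly the "unidentified" band can be empty; nothing assumes
overlap.

Stage two segments the frame into three phases. The impact phase straddles
the critical point: 10 samples before plus 10 after (21 total) when the
frame peak reaches 6 g, or 10 before plus 20 after (31 total) below it.
Equality at 6 g takes the severe branch: 6 g is the full-scale range of the
sensor class this convention models, so a peak there indicates saturation.
The free-fall phase is the 32 samples immediately before the impact phase;
the rest phase runs from the end of the impact phase to the end of the
frame (310 or 300 samples). From the whole frame or any phase, 54
time-domain statistics are extracted over six derived signals (three axes
plus the tri-axial, coronal-plane and horizontal-plane norms): eight
statistics per signal plus six pairwise correlations.

A 3-class linear SVM (one-vs-one, hence 3 binary classifiers) is trained on
the per-phase feature vectors of training fall frames only; rejection of
non-falls is delegated entirely to the temporal-order rule, which accepts
exactly the sequence FreeFall → Impact → Rest (1 of the 27 possible 3-label
sequences). Features are z-scored with training statistics before the
margin classifier because the raw features span wildly different scales
(variances near 0 next to kurtoses in the tens). The margin penalty
defaults to C = 1.0 and is exposed in the configuration. A whole-frame
binary SVM on the same 54 features serves as the baseline that isolates the
contribution of the multiphase model.

## Estimator conventions

Dispersion uses the sample (n−1) estimator; skewness and kurtosis are
standardized third/fourth central moments with population moments and
kurtosis in Pearson (non-excess) form. All four choices are switchable in
`FeatureConfig` since different implementations of these statistics
disagree on bias correction. Correlations on zero-variance input are 0 by
convention (rest phases can be nearly constant), as are moments of constant
signals — classifiers never see NaNs. Segments shorter than 2 samples are
rejected. The coronal-plane norm pairs (ax, ay) by default — with x
vertical, only the horizontal plane (ay, az) is fixed unambiguously by the
norm definitions, so the coronal pair is a configuration option.

## Synthetic data

The generator emulates signal structure, not biomechanics. A fall is 2 s of
pre-fall activity matched to the archetype (standing, gait, a transition),
a free-fall interval whose norm collapses to ≈0.1 g (duration drawn from
0.12–0.8 s, the span reported across the fall-phase literature), a
half-sine impact pulse with an exact configurable peak and sub-second
duration along a direction with 0.35–0.9 horizontal fraction (falls
topple), and 3 s of rest at 1 g static in a lying orientation with a
decaying ring-down. ADLs follow twelve archetypes: periodic gait near 1 g
(walking, stairs), single vertical-dominant transients of 1.4–3 g
(sit/stand transitions), repeated bounces with brief sub-1 g flight dips
(jumping), and lie-downs whose transients carry fall-like horizontal
content. Impact peaks default to an even mix of mild (3.3–5.5 g) and severe
(6.2–8.0 g) bands so both impact-phase branches occur; "lie on the bed
(fast)" reaches 2.5–4.0 g, deliberately straddling the learned threshold
gap so the knowledge stage is genuinely exercised rather than bypassed. All
randomness flows from one seed per record; output is bit-identical under a
fixed seed.

What the generator does not reproduce: sensor drift and calibration error,
subject-specific gait variability, pre-fall reaction movements, soft-tissue
and garment artifacts, and the long heavy tails of real daily-living data.
Passing tests on synthetic data therefore demonstrate that the pipeline
recovers the structure it is built around — they are not a claim about
field performance.

## Evaluation protocol

Stratified k-fold cross-validation (default k = 5) repeated over
independently shuffled rounds (default 5); stratification guarantees both
classes in every training split, which the threshold fit requires. Per
fold, thresholds and the phase classifier are refit on the training portion
only. Metrics are percentages to two decimals; a metric with a zero
denominator is reported as missing and excluded from averages rather than
coerced to zero. Tests and the acceptance script use 5-fold, 1-round runs
on 220 records (110 falls / 110 ADLs) — large enough for stable rates while
keeping a full run in seconds.

## Known limitations

The dominant error mode is the designed one: brisk lie-downs whose
transient peak, horizontal content and post-event stillness mimic a mild
fall. Their pre-impact window holds a rising transient much like the
impact onset that leaks into the free-fall window of genuine mild falls, so
the phase classifier — which never sees ADL examples — sometimes reads it
as FreeFall and the temporal-order rule then accepts the frame. This
mirrors the lie-on-bed weakness reported for detectors of this family on
real recordings; context information (location, bed sensors) rather than
the accelerometer signal is the usual remedy. Thresholds learned as class
extrema are also sensitive to single extreme training frames and are not
personalized per subject. The one-vs-one vote relies on the underlying
library's tie handling; with three classes and linear kernels ties are rare
and were not given a dedicated tie-break rule.
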