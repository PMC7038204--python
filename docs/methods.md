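# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `afdetect`, in the order the pipeline runs.

## Synthetic ECG generator

The generator emulates an ECG bench signal generator: it exists so that
preprocessing, feature extraction and classification can be verified against
exact ground truth (true R positions, RR intervals, P amplitudes, labels)
without external recordings.

Each beat is a sum of Gaussian bumps placed relative to the R peak: P wave
(center −160 ms, σ 25 ms, default 0.15 mV for NSR), Q and S deflections
(∓22 ms, σ 8 ms, −0.10 and −0.15 of the R amplitude), R (σ 10 ms, default
1.0 mV) and T (+260 ms, σ 45 ms, +0.25 of R).  RR intervals are drawn from a
normal distribution with mean 60/heart-rate and standard deviation
`rr_cv · mean`, redrawn below a 0.3 s floor (redrawing rather than clipping
avoids a point mass at the floor).  Defaults: NSR `rr_cv = 0.03` (ordinary
sinus variability), AF `rr_cv = 0.25` (irregularly irregular; the class
invariant requires ≥ 0.15).  AF omits the P wave and adds a 0.05 mV
fibrillatory baseline sinusoid whose frequency performs a bounded random
walk in 4–9 Hz — enough f-wave-like content to exercise P-window estimators
without committing to an atrial model.  The noise class is a white
(≥ 0.3 mV SD) + 50 Hz mains (0.2 mV) + slow baseline-wander (0.4 mV)
mixture with no coherent beats, exercising all three noise features.
Broadband sensor noise (default 0.02 mV SD) is added to every rhythm.
All randomness flows from a single integer seed; identical specifications
produce bit-identical output.

The `verification_preset` (30 s NSR, 80 BPM, 1.0 mV, 250 Hz) mirrors common
bench-verification settings and anchors the acceptance script.

What the generator does **not** emulate: respiration-coupled HRV spectra,
ectopic-beat morphology, electrode-motion artifact bursts, QRS-morphology
variants (bundle-branch block, pre-excitation), or any "Other"-class
arrhythmia.  Passing tests therefore demonstrate correctness of the
pipeline's mechanics and the separability logic, not clinical performance
on real recordings; real "Other" rhythms with irregular RR are known to be
the hard case for RR-based AF detectors.

The benchmark corpus (`make_benchmark`) draws classes at 40/40/20
(NSR/AF/noise) and varies heart rate (55–100 NSR, 60–140 AF), R amplitude
(0.6–1.4 mV), P amplitude (0.1–0.2 mV), RR variability and noise level per
segment, so the classifier cannot key on a single template.

## Preprocessing

* **Band-pass**: zero-phase (forward–backward) Butterworth, 0.5–40 Hz,
  order 3.  These are conventional monitoring-band values: the 0.5 Hz edge
  removes baseline wander without distorting the ST segment badly, and the
  40 Hz edge suppresses mains/muscle noise while preserving P-wave
  amplitude needed by morphology features.  Zero-phase application keeps
  peak timing unshifted; the effective magnitude response is |H(f)|².
* **R-peak detection**: Pan–Tompkins-style energy detector — 5–15 Hz QRS
  band-pass, derivative, squaring, 150 ms moving-window integration,
  adaptive signal/noise running levels with threshold
  `noise + 0.25·(signal − noise)` and a 0.2 s refractory period.  Candidates
  are refined to the extremum of the filtered trace within ±75 ms; if the
  median refined extremum is negative the trace is treated as inverted
  (single-lead patches can yield inverted QRS).  The first and last 0.5 s
  are excluded from the search (filter edge transients).  All thresholds are
  relative, so detection is invariant to uniform amplitude scaling.
* **Beat series**: RR = successive R-index differences / fs; ΔRR =
  successive RR differences.  At least 3 peaks are required; fewer routes
  the segment to the imputation path below.

## Features (31)

Order and names are fixed by `afdetect.features.FEATURE_NAMES`.

**AF group.** `af_evidence` builds the 2-D histogram of consecutive ΔRR
pairs (ΔRR[i−1], ΔRR[i]) with 40 ms bins over ±600 ms (points beyond the
extent are clipped to edge bins so the total count is conserved) and
partitions it into 13 regions: an origin box (|Δ| < 80 ms), four quadrant
zones, and eight axis arms split at 240 ms into inner/outer halves.  The
score is `IrregularityEvidence − OriginCount − 2·PACEvidence`, where
IrregularityEvidence counts occupied bins outside the origin, OriginCount
counts points inside it, and PACEvidence = max(0, N₂₊₄ − N₁₊₃) — the excess
of points in the short–long alternation quadrants over the symmetric ones,
the signature of bigeminy/trigeminy rather than sustained irregularity.
The region layout and the PACEvidence contrast are this package's concrete
instantiation of the classic Lorenz-plot detector family; regular rhythm
scores −OriginCount ≤ 0 and AF scores strongly positive.

`shannon_entropy_drr` uses a fixed 16-bin histogram on [−0.5, 0.5] s
(values clipped into the edge bins), natural logarithm; range [0, ln 16].

`ks_statistic` is the two-sample Kolmogorov–Smirnov statistic between the
recording's ΔRR sample normalized by its median RR (rate normalization) and
a reference AF distribution.  The reference is learned at training time by
pooling the normalized ΔRR of all AF-labeled training recordings and is
serialized with the model bundle; when training data contain no AF, a
seeded synthetic fallback reference (generated by this package's AF
generator and labelled as such in its provenance) is used.

**Morphology group.** The average beat is the per-sample mean of R-aligned
windows [−0.3, +0.5] s (≥ 3 full windows required).  Fiducials: Q = minimum
in [−60, 0] ms; S = minimum in [0, 80] ms; QRS onset/offset = first sample,
scanning outward from Q/S, where |slope| drops below 10% of the maximum
|slope| in the QRS; P = maximum in [−250, −80] ms; T = extremum of larger
magnitude in [+120, +400] ms; isoelectric level = mean of [−90, −70] ms.
Ten kinds: QRS duration (onset→offset), PR (P peak→onset), QT (onset→T peak
+ 80 ms), QS (Q→S), and ST (at offset + 60 ms), P, Q, R, S, T amplitudes
relative to the isoelectric level.  Variant **E** evaluates these on the
average beat.  Variant **O** delineates each beat individually, forms
consensus fiducials as the per-fiducial median offset across beats, then
takes the per-kind median of per-beat values at the consensus offsets.  The
consensus step is the package's robust-delineation choice: on AF, single
beats present fibrillatory crests in the P window at random offsets, and
the median offset plus per-beat median amplitude suppresses them the same
way beat averaging does in variant E, while the two variants remain
distinct estimators (median-of-beats vs mean-waveform).  A variant that
fails delineation entirely is imputed with zeros.

**RR group.** Median RR; the arrhythmia index counts interior beats where,
with m = mean of the surrounding three RR intervals, any of four
knowledge-based conditions fires: RR < 0.85 m followed by RR > 1.15 m
(premature beat plus compensatory pause), RR > 1.5 m (dropped beat),
RR < 0.4 s (ectopic burst), |ΔRR| > 0.3 m (abrupt change).  The remaining
three — mean RR, RMSSD, pNN50 (|ΔRR| > 50 ms fraction) — are conventional
RR statistics added to complete the 31-feature dimensionality and are
flagged `gap_fill` in the metadata.

**Noise group.** `qrs_similarity` is the mean Pearson correlation over all
unordered pairs of [−60, +80] ms QRS windows (zero-variance windows are
dropped).  `signal_quality_index` is the fraction of beats whose isoelectric
window peak-to-peak is below 20% of the R amplitude — the 20% threshold is
this package's choice of "quiet baseline".  `qr_smoothness_index` counts
peaks (endpoints eligible) of the first-difference sequence of the
QRS-onset→R upstroke of the average beat: 1 for a smooth upstroke, more
under high-frequency contamination.

**Imputation.** Every failure path (too few beats, failed delineation,
degenerate windows) substitutes documented defaults — 0 for everything
except `ks_statistic`, which is set to 1 (maximal distance).  Failure modes
are noise-like, so defaults push toward the Noisy class rather than
fabricating physiology; the feature vector always contains 31 finite
values.

## Classifier

The backend is LightGBM.  Hyperparameter defaults: learning rate 0.1,
276 iterations, depth 8 (num_leaves 2⁸), L2 leaf regularization 3, early
stopping after 20 rounds on the validation multiclass MCC, multiclass
log-loss objective.  Ordered-boosting-specific knobs carried in the
configuration (bagging temperature 0.7, random strength 0.2, Newton leaf
estimation) have no LightGBM equivalent; they are warned about once at
train time and recorded under `unsupported_params` in the bundle metadata
so the gap is auditable.  Training is single-threaded and deterministic for
a fixed seed.

Training recipe: (1) fit on all 31 features; (2) stratified 20-fold CV —
stratification rather than plain random folds protects the rare Noisy
class — with per-fold early stopping on validation MCC; (3) rank features
by gain importance, ties broken by manifest order; (4) keep the top 17;
(5) refit on the selection with the iteration count fixed to the median
per-fold best iteration (no early stopping at the final stage).  On a very
separable corpus the median best iteration can be small (the metric
saturates within a few rounds), which is expected behavior of the
early-stopping rule, not underfitting of hard data.  The CV models are
discarded after their best-iteration statistics are collected.

No class reweighting is applied.  The bundle (booster, hyperparameters,
feature manifest, ranking, selection, KS reference, class order, backend
identity) serializes to a directory of text artifacts and round-trips with
bit-identical predictions.

## Metrics

Per-class F1 = 2TP/(2TP+FP+FN); a class with no true and no predicted
members scores 1 (degenerate-denominator convention; this affects only
synthetic fixtures where a class is absent).  The overall F1 averages
Normal, AF and Other only — the Challenge convention; the Noisy F1 is
computed and reported but excluded.  Accuracy is trace/total over all four
classes.  The multiclass MCC uses the covariance form over the confusion
matrix, with degenerate denominators mapped to 0.  Binary AF scores pool
Normal/Other/Noisy as non-AF; an undefined sensitivity (no true positives)
is reported as missing, never as 0.

## Segmentation and splitting

Annotated long records are cut into consecutive non-overlapping windows of
exactly 30 s (trailing partial windows discarded — all features assume a
full 30 s context).  Codes map AFIB→AF, AFL→Other, J→Other, N→Normal; a
window spanning a rhythm change takes the class covering the majority of
its duration (ties prefer a mapped class, then canonical class order), and
windows whose majority is unmapped are dropped.  The majority rule is the
least surprising deterministic choice where the annotation granularity and
the window size disagree; per-class counts are logged so they can be
audited.  Challenge-2017 recordings are used whole.  No resampling is
performed between 250 and 300 Hz sources: every feature is computed in
seconds and millivolts and is sampling-rate-agnostic.  Train/test splitting
is label-stratified (round(fraction · n) per class), deterministic per
seed, disjoint and exhaustive.

## Problem sizes

The end-to-end benchmark trains on 800 synthetic 30 s segments and
evaluates on 200 held out, the scale at which the full recipe (including
20-fold CV) completes in a few minutes on one CPU while estimating the
reported scores with ±2–3% resolution.  Oracle-equivalence checks use
250–1000-point seeded samples; property checks over seeds use 20
replicates.

## Limitations

* The synthetic benchmark contains no "Other" class; the Other-vs-AF
  confusion that dominates errors on real wearable data is untested here.
* Feature importances and the selection plateau are properties of the
  synthetic corpus; the selected top-17 set will differ on real databases.
* The WFDB layer covers format-16 signals and rhythm annotations only —
  enough for AF-database-style corpora, not the full format zoo.
* Delineation assumes a dominant upright (or globally inverted) R wave;
  biphasic QRS morphologies will degrade the morphology group, by design
  routed toward imputation rather than failure.
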