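# Methods

## Problem and model

`p300id` implements a complete analysis chain for discriminating two
groups of subjects — a methamphetamine-use (MA) group and healthy
controls (HC) — from the P300 event-related potential evoked by deviant
(S2) stimuli in a visual oddball task. The chain is: epoch conditioning →
per-channel feature extraction (time, frequency and delta-band wavelet
features) → Fisher-score feature selection → BiLSTM (or SVM)
classification → nested cross-validation with balanced-accuracy metrics.

Because no public recordings exist for this paradigm at this scale, the
package ships a first-class synthetic cohort generator whose defaults
define the study conditions every experiment in the test suite runs
under. All pipeline stages also accept user-supplied epoch tensors in the
same HDF5 layout.

## Synthetic cohorts

An epoch is background noise plus, for post-stimulus time, a P300
template: a Gaussian bump `a·exp(-(t-λ)²/2w²)` with group-specific peak
amplitude `a` and latency `λ`, per-epoch jitter on both, scaled per
channel by a fronto-central gain profile (P300 is largest over midline
fronto-central sites). Defaults:

| parameter | MA | HC | rationale |
|---|---|---|---|
| subjects | 18 | 22 | study scale |
| deviant epochs/subject | 40 | 40 | 5-epoch averaging → 8 samples/subject |
| peak amplitude (µV) | 9 | 6 | clear but non-trivial separation |
| peak latency (ms) | 360 | 330 | secondary latency effect |
| bump sd `w` (ms) | 60 | 60 | spectral energy ≫95 % below 4 Hz |
| amplitude/latency jitter (µV, ms) | 1 / 15 | 1 / 15 | trial-to-trial variability |
| noise | pink, sd 5 µV | same | 1/f background EEG |

62 channels (extended 10–20 montage, 250 Hz, −200…1000 ms epochs). The
amplitude/latency values are working defaults, not biological estimates:
the published paradigm reports neither group's P300 parameters.

By default only the retained addiction-deviant (S2) epochs are
generated, since the analysis uses nothing else. An `include_nontarget`
flag adds frequent standards (S1, noise only — standards elicit no P300)
and neutral deviants (S2-neutral, a common P300 with the control
parameters in both groups) in the paradigm's 70:15:15 proportions; the
preprocessing stage filters them out by stimulus code.

What the generator deliberately does **not** emulate: artifacts (blinks,
drift), inter-channel correlation and volume conduction, per-subject
random effects, uneven epoch retention after artifact rejection, and
non-deviant (S1/neutral) trials. Consequently, passing tests show that
the pipeline recovers the statistical structure it assumes — a delta-band
group difference under S2 — not that it would reach any particular
accuracy on clinical EEG. (In the study this mirrors, preprocessing left
144 MA and 184 HC averaged samples; the clean generator yields 144 and
176, and after seeded majority-class subsampling both designs coincide at
144 + 144 = 288.)

## Preprocessing

Zero-phase 4th-order Butterworth low-pass at 30 Hz (forward–backward, so
latency features carry no filter delay), polyphase resampling to 250 Hz,
baseline correction by subtracting the −200…0 ms mean, selection of
S2-deviant epochs, then averaging of every 5 consecutive epochs within a
subject. Averaging blocks are non-overlapping by default (stride = size):
this gives determinate record counts (`floor((n−5)/5)+1` = 8 per
40-epoch subject) and no shared epochs between averaged samples, hence no
double-counting across CV folds; a sliding mode is available. Class
balancing (seeded subsampling of the majority class after averaging) is
the final step.

## Wavelet features

The P300's spectral content lies in the delta band (0–4 Hz). A five-level
dyadic DWT at 250 Hz puts the deepest approximation band at
250/2⁶ = 3.90625 Hz; those approximation coefficients are the wavelet
features.

The mother wavelet is the quadratic B-spline. Its two-scale relation
fixes the analysis low-pass taps, √2/8·(1, 3, 3, 1); the biorthogonal
dual is a design choice because the spline itself does not determine it.
The shortest dual (one vanishing moment) reconstructs perfectly but is so
poorly frequency-localised that a 2 Hz tone leaves 71 % of its
coefficient energy *outside* the approximation band — useless for a
"delta-band feature". We therefore use the spline dual with 7 vanishing
moments (`rbio3.7` in PyWavelets' naming): the analysis low-pass is still
exactly the B-spline scaling filter (zero-padded), and the energy split
for 2 Hz / 20 Hz tones becomes 0.98 / 0.09. `dual_moments` ∈ {1,3,5,7,9}
is exposed on `build_bspline_bank`.

Boundary handling is half-point symmetric extension. The DWT input is the
full 0–1000 ms post-stimulus epoch (251 samples → 22 approximation
coefficients with the 16-tap dual), and the delta vector is right-zero-
padded or centre-truncated to exactly 23 entries, so the per-channel
feature count (6 time + 2 frequency + 23 wavelet = 31; 62 × 31 = 1922
total) is independent of window length and filter choice.

## Time and frequency features

On the P300 window (default 250–500 ms post-stimulus; configurable —
determined by ERP inspection in practice): MAA = max, MIA = min,
LAT = time of max (earliest on ties), RLM = MAA/LAT, PA = Σ(x+|x|)/2
(raw sample sums, no Δt scaling), DPN = MAA − MIA. The window's power
spectral density is a single-taper (boxcar) periodogram **without** mean
removal: an ERP window is a one-sided bump whose delta-band mass sits at
and near DC, and removing the mean would zero the DC bin and force the
spectral centroid to the first nonzero bin (≈3.97 Hz for a 63-sample
window), destroying the feature's meaning. MF = peak frequency (lowest on
ties); AF = spectral centroid over [0, min(125, fs/2)] Hz — the upper
limit exceeds the 30 Hz filtered content and contributes only near-zero
mass, but is kept as printed in the feature's definition.

## Feature selection

Per-feature Fisher score
`F(i) = [(x̄ᵢ⁺−x̄ᵢ)² + (x̄ᵢ⁻−x̄ᵢ)²] / [s²ᵢ⁺ + s²ᵢ⁻]` with (n−1)-denominator
class variances. Selection keeps features strictly above the mean of the
finite scores, ranked descending. Ties at the mean are dropped (the
conservative reading of "remove below-average features"). A
constant-within-class, different-between-class feature scores +∞: it
sorts first but is excluded from the mean so it cannot inflate the
threshold. Inside cross-validation, selection is always fit on the
training partition only; a one-shot global mode exists behind an explicit
flag for protocol comparison.

## Classification

Each sample is a 62-step sequence (one step per electrode, montage
order) of 31-dimensional feature vectors. The LSTM cell is implemented
directly from the gate equations (forget/input/output gates, candidate
memory; see `classify.py`) with analytic backpropagation through time,
verified against a finite-difference oracle. The BiLSTM runs one cell
forward and one backward and maps the concatenated final hidden states
through a sigmoid readout; decision threshold 0.5. After selection,
dropped features are zero-masked within their channel step, so selection
changes content, never sequence shape.

Training: Adam (lr 1e-2), minibatch 64, at most 80 epochs, early stopping
after 10 epochs without validation balanced-accuracy improvement,
L2 1e-4, uniform ±0.08 init with forget-gate bias +1, all seeded and
deterministic. These defaults were chosen for stable convergence at the
cohort scale this package targets (a few hundred samples); on these data
the model converges within 10–30 epochs, and larger budgets change
nothing but cost. Inputs are z-scored per fold with training-set moments.

The SVM baseline is a soft-margin SVC with sigmoid kernel ("sigmoid
activation" read as the sigmoid kernel; an interpretation, documented).

## Cross-validation and metrics

12 outer folds / 8 inner folds, stratified by class (±1 sample), seeded.
Per outer fold: selection + standardisation fit on the outer-training
set; one classifier trained per inner split; BVA = (Sen+Spe)/2 on the
inner validation subset; the inner model with the best BVA (ties → lowest
inner index) predicts the outer test set, giving BTA; ABTA = mean ± sd of
the 12 BTAs. Sensitivity = TP/(TP+FN)·100 with the MA class positive;
specificity = TN/(TN+FP)·100. Fold-plan invariants (exact partition,
inner folds nested in the outer-training set, stratification) are
asserted on every run.

The default split is at sample level, which lets averaged samples of one
subject appear on both sides of a fold boundary; a `subject_aware` flag
groups each subject's samples into a single fold for the stricter
protocol. Per-electrode ablation repeats the nested CV on each channel's
31 columns (sequence length 1) and reports a ranked table.

## Experiment scales in the test suite

The strong-effect recovery runs at the full default scale (288 samples ×
1922 features, 12×8 folds; measured ABTA 96.5 %). The null-cohort,
effect-size-monotonicity and channel-ablation experiments run on reduced
cohorts (16 channels; 9+11 subjects for the latter two; 6×4 or 4×3
folds) — the properties under test are scale-free, and these sizes keep
the whole suite comfortably reproducible on one CPU. The null-cohort
acceptance band (±6 percentage points around chance) is the binomial
95 % interval for 288 test decisions.

## Known limitations

- The generator's independence assumptions (channels, epochs, subjects)
  make the classification task easier than clinical data; accuracies here
  do not transfer.
- The biorthogonal bank is not an isometry, so coefficient "energy" is an
  approximation-quality diagnostic, not a norm (the orthonormal
  configuration used in tests restores exact energy conservation).
- Single-layer BiLSTM, single hidden size per run; no hyperparameter
  search. The inner CV selects among inner-fold models, not among
  architectures.
- Sample-level folds (the default) overestimate accuracy relative to the
  subject-aware protocol when per-subject structure exists; the synthetic
  generator has none, but real data do.
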