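# Methods

This note documents the models, parameters and numerical choices behind the
package, in the spirit of a methods appendix: what is computed, under which
assumptions, and what the synthetic benchmark does and does not show.

## The analysis pipeline

The pipeline classifies mild cognitive impairment (MCI) against healthy
controls (HC) from EEG microstate dynamics recorded under two paradigms —
eyes-closed rest and a Stroop-like conflict task — optionally fused with the
MoCA cognitive screening score.

**Conditioning.** Signals are band-passed 2–20 Hz (zero-phase Butterworth,
order 4, applied forward–backward), downsampled to 250 Hz (polyphase),
re-referenced to the common average (CAR), and epoched. Epochs whose
absolute amplitude exceeds 100 µV anywhere are dropped (strict inequality;
an epoch peaking exactly at the threshold survives). Augmentation produces
ten analysis segments per subject and paradigm: ten non-overlapping 20-s
epochs from the start of the resting recording, and ten random balanced
blocks of correct-incongruent task trials averaged within block. Every
segment keeps its subject id — the grouped cross-validation depends on it.

**Microstate segmentation.** Global field power (GFP) is the per-sample
standard deviation of potentials across the n = 62 electrodes. Topographies
at strict local GFP maxima (plateaus and endpoints excluded) enter a
polarity-invariant modified k-means with k = 4: maps are assigned to the
template of highest absolute spatial correlation, and each template is
re-estimated as the dominant eigenvector of its cluster's outer-product
sum — so a map and its negation are equivalent throughout. The best of 20
random restarts by global explained variance (GEV) is kept; convergence is
declared when assignments are stable or the GEV improves by less than 1e-6,
with at most 100 iterations per restart; an emptied cluster is re-seeded
from the worst-fitting map; ties between restarts keep the earliest.
Templates are fitted on GFP-peak maps pooled across *all* subjects of both
groups (per paradigm), not per diagnostic group: group-specific templates
would inject the class label into feature extraction. GEV is the
GFP²-weighted mean squared spatial correlation between peak maps and their
assigned templates, evaluated at peaks.

Fitted templates are relabelled to the canonical classes A–D by a globally
optimal bijective matching (Hungarian algorithm on absolute correlation)
against built-in prototype maps: smooth dipolar fields with the canonical
orientations (A left-anterior/right-posterior, B its mirror image, C
anterior–posterior, D fronto-central versus occipito-temporal).

**Backfitting.** Every sample of the continuous (or block-averaged) data is
labelled with the template of highest absolute correlation. No temporal
smoothing or minimum-duration rule is applied, deliberately: pathologically
short states are part of the signal of interest. Ties break to the lowest
class index; zero-variance samples inherit the previous label (class A at
t = 0) and are flagged.

**Features (26 per segment and paradigm).** On the merged label sequence
(maximal runs collapsed, e.g. "AAAAABBBAAB" → "ABAB"): mean duration MD_k
(ms), coverage COV_k (fraction of samples), occurrence OC_k (runs per
second) for each class; the 12 ordered distinct-pair transition
probabilities TP(i→j) = N(i→j)/N(i→), where the denominator counts *outgoing*
transitions so every observed row sums to one; the model GEV of the
segment's own GFP peaks; and the Lempel–Ziv complexity of the merged
sequence (exhaustive left-to-right parsing, raw count, final partial word
included). The identity OC·MD/1000 = COV holds exactly by construction.
States that never occur yield missing MD values and missing TP rows —
recorded as NaN, never as fabricated zeros — and are imputed with
training-fold medians only at the modelling boundary. Names follow the
`{r|t}{A–D}-{MD|COV|OC}`, `{r|t}{i}→{j}`, `{r|t}-GEV`, `{r|t}-LZC`
convention; an ASCII header dialect (`rA.B`) is available for tools that
reject the arrow.

**Screening.** Features are compared between groups on subject-level means
of the ten segments (segments of one subject are not independent; the
segment-level variant is available). Shapiro–Wilk normality in both groups
plus Levene homogeneity (both at α = 0.05) dispatch to the independent
two-sample t-test, otherwise the Mann–Whitney U test; p-values are adjusted
by Benjamini–Hochberg within one paradigm's 26-feature family. Features
with adjusted p < 0.05 are retained.

**Selection and classification.** Retained candidates are ranked by
difference-form mRMR on three-bin discretised features (bins at ±0.5 SD of
the training fold; plug-in mutual information in bits; ties by feature-name
order). For F = 1..10 the top-F prefix is evaluated with an SVM under
stratified subject-grouped 5-fold cross-validation repeated 5 times;
hyperparameters (RBF vs linear kernel, C ∈ {0.01..100}, γ ∈ {1e-3..10},
decade grids) are chosen by an inner grouped 5-fold grid search inside each
training fold. Screening, ranking, imputation, standardisation and
hyperparameter choice are all refitted within training folds by default;
a `paper_mode` switch reproduces whole-data screening (which carries the
known optimistic bias of screening outside the folds). The optimal feature
subset (OFS) is the best-accuracy prefix with at most five features (ties to
the smaller F); the named OFS is recomputed on the full data for
presentation while the reported metrics remain the cross-validated ones.
Sensitivity is the recall of MCI, specificity the recall of HC; the
segment-level metrics are primary and a subject-level majority vote is
reported alongside. The four run configurations (rest, task, fused,
fused + MoCA) share identical fold partitions so their accuracies are
directly comparable. MoCA, when included, enters the candidate pool as one
more column, replicated across a subject's segments and exempt from the
EEG screening families.

Two deliberate simplifications in the inner search, neither of which can
leak test-fold information: (i) it standardises with the outer training
fold's statistics rather than re-fitting the scaler per inner fold, and
(ii) hyperparameters are tuned once per training fold — on the OFS-sized
(five-feature) mRMR prefix — and shared across that fold's F curve, since
the training fold, not the candidate subset, is the protocol's unit of
optimisation. Search fits use a relaxed tolerance (1e-2) and an iteration
cap; they only rank candidates, and the model actually evaluated is always
refitted at full precision.

## The synthetic benchmark

The generator emulates the study conditions end to end: 31 HC + 32 MCI
subjects, a 62-channel spherical-cap montage (Fibonacci layout), one 200-s
resting recording per subject, and a task recording of 300 contiguous 1.2-s
trials (150 congruent, 150 incongruent, stimulus onset 200 ms into each
trial) with an event table; MoCA is drawn per group as rounded Gaussians
(MCI 19.16 ± 1.48, HC 25.48 ± 1.48, clipped to 0–30).

**Temporal model.** Microstate sequences are semi-Markov: run lengths are
gamma distributed (shape 2) with state- and group-specific means, successors
drawn from a zero-diagonal row-stochastic transition matrix, initial state
from the embedded chain's stationary vector. Long-run coverage therefore
follows occupancy_s ∝ π_s·d_s, which the feature stage must recover.
Underlying dwell times sit at the classic microstate timescale (defaults
57–76 ms at rest, 86–172 ms under task): a 2–20 Hz filter has an impulse
response of several tens of milliseconds, so states lasting ~17 ms are
unrecoverable in principle from band-limited data, whereas the short
durations reported by unsmoothed backfitting *emerge* in this model from
noise-induced fragmentation of longer underlying states. The group
contrasts follow the published direction: at rest MCI has longer A and
shorter/rarer D (with fewer transitions into D); under task MCI has more A
and less C. Between-subject heterogeneity is modelled by a log-normal
multiplier on mean durations (CV 0.15) and Dirichlet jitter of transition
rows (concentration 60) — without it, 200-s resting estimates are so
precise that classification saturates at 100 %.

**Rendering.** signal(t) = a(t)·template[label(t)] + noise(t), with
templates built from the canonical dipolar geometry plus a seeded smooth
perturbation (unit-norm, average-referenced, pairwise |corr| < 0.8), and
a(t) = 0.2 + |sin(2π·5t + φ)|² — a positive, waxing-and-waning envelope
whose oscillatory power sits at 10 Hz, mid-band, like bursting alpha. Noise
is spatially and temporally white Gaussian, average-referenced, scaled so
signal RMS / noise RMS equals the requested SNR (default 5). Task trials
are rendered time-locked: each trial of a subject repeats that subject's
evoked label sequence with a common envelope phase, so block averaging
raises SNR as it does for ERPs; congruent trials use an independent control
sequence and are discarded by the epoching stage.

**What the benchmark does not contain**: ocular/muscle artifacts, 1/f
background spectra, volume-conduction forward modelling, bad channels. The
artifact-removal stages of a clinical pipeline (ICA, ASR, channel
interpolation) are represented by a no-op hook. Passing tests on this
benchmark therefore demonstrate the correctness and leakage-safety of the
analysis chain and its recoverability properties — not clinical accuracy on
real EEG, whose noise structure is far richer. Absolute accuracies on the
synthetic cohort are higher than published clinical values (synthetic MoCA
separates groups by design at d ≈ 4); only directional comparisons between
configurations are meaningful.

## Numerical and protocol choices

- Filter: Butterworth order 4 band-pass designed with scipy, applied with
  `sosfiltfilt`; attenuation ≥ 20 dB at 1 Hz and 40 Hz.
- Peak rule: strict local maxima; plateaus never qualify; no minimum peak
  distance.
- Rejection threshold: strict inequality, global max over channels ×
  samples per epoch, applied after CAR.
- k-means determinism: every stochastic step consumes a named generator
  derived from the run seed; identical seeds give bit-identical models.
- Subject-grouped folds: subjects (not segments) are stratified and
  partitioned with scikit-learn's StratifiedKFold over subjects; with
  32/31 subjects each fold holds 12–13 subjects, 6–7 per class.
- Problem sizes in the default acceptance run: 63 subjects × 2 paradigms
  × 10 segments (1 260 segments), GFP peaks subsampled to ≤ 100 per
  segment for clustering (≈ 63 000 resting maps), 600-s sequences for the
  temporal-recovery check, 200 null cohorts for the FDR calibration, and 5
  subject-level label permutations for the chance-level control.
- The permutation control reads accuracy at a fixed F: the OFS maximum
  over F is upward-biased even under the null.

## Known limitations

- The LZC count is reported raw; sequence-length normalisation is left to
  the analyst (segment lengths are constant within a paradigm here).
- The transition-probability denominator counts outgoing transitions, so a
  state that ends a segment contributes its last run to MD/COV/OC but not
  to TP.
- With four classes and 20-s segments at rest, TP estimates per segment are
  based on a few hundred transitions; task blocks (1 s) yield far noisier
  per-segment estimates — by design, mirroring the data regime of the
  emulated study.
- GEV on synthetic filtered data depends on the envelope and SNR choices;
  its absolute level is not comparable to values from clinical recordings.
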