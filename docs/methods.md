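# Methods

`mearaster` implements a raster-plot machine-learning workflow for
multiwell MEA recordings of cultured neuronal networks: spike detection,
network-burst analytics, IMFI-normalized raster imaging, deep-style
image features with per-well vehicle normalization, shallow
pattern-recognition classifiers for seizure-liability and compound
identification, and ROC-based evaluation with a cost-slope operating
point. This note records the model assumptions, the numerical choices,
and what the synthetic benchmark does and does not demonstrate.

## Recording model and spike detection

A plate has 24 wells with 16 extracellular electrodes each. Under
cumulative administration a well contributes an ordered sequence of
10-minute epochs: a vehicle epoch (0.1% DMSO) first, then one epoch per
ascending concentration of a single compound. Each epoch has its own
0-based timeline.

Spikes are detected on raw 20-kHz traces after a 4th-order zero-phase
Butterworth high-pass at 100 Hz. The threshold is ±5.3 σ, where σ is the
baseline noise s.d. during quiescent periods, estimated iteratively:
compute σ over the whole filtered trace, mask ±2 ms around samples
exceeding 4 σ, recompute (two passes). Crossing is strict (|v| > kσ);
an event is a maximal contiguous supra-threshold run timed at its
extreme sample; a 1-ms dead time suppresses double counts. σ is
estimated per electrode.

## Network bursts and the five parameters

Network bursts are detected by a four-step pooled-ISI method: (1) pool
all 16 electrodes' spikes; (2) candidate bursts are maximal runs of
pooled inter-spike intervals ≤ 0.1 s; (3) candidates closer than 0.1 s
merge; (4) candidates with fewer than 50 spikes or fewer than 4
participating electrodes are dropped. All four thresholds are
configurable (`BurstConfig`); the defaults are explicit stand-ins, since
methods differ between facilities. The burst's peak-rate time is the
center of the fullest 10-ms pooled-count bin, earliest bin on ties.

Per epoch the five standard parameters are reported: TS (total spikes),
NoB (burst count), IBI (mean gap from each burst's end to the next
burst's onset; onset-to-onset is a config variant), DoB (mean burst
duration), SiB (mean spikes per burst). IBI needs ≥ 2 bursts and
DoB/SiB ≥ 1; otherwise they are NaN and propagate as missing —
excluded from means and tests with a logged count.

Dose–response tables express each parameter as percent of the same
well's vehicle epoch (vehicle ≡ 100%), averaged over wells with SEM =
sd/√n. Significance versus vehicle uses one-way ANOVA followed by
Dunnett's test (scipy's multivariate-t implementation), gatekept: no
concentration is flagged unless the omnibus ANOVA has p < α. The ANOVA
and Dunnett run on %-of-control values, matching the plotted quantity.

## IMFI windows and raster images

The IMFI (inter-maximum-frequency interval) of a well is the median
spacing between successive network-burst peak-rate times in the vehicle
epoch; wells with fewer than two vehicle bursts are rejected by name.
Every epoch of the well is tiled from t = 0 into
floor(duration / 4·IMFI) non-overlapping windows of width 4 × IMFI; the
trailing partial window is discarded. Windowing by the well's own burst
period normalizes the time axis so that a window holds ~4 burst cycles
regardless of the well's intrinsic rhythm — this is what makes windows
comparable across wells.

A window renders to a 227 × 227 grayscale image: 16 equal horizontal
bands (electrode 0 at top), time linear across columns, each spike a
single black pixel on white (configurable; 1 px keeps within-burst ink
roughly proportional to spike count — larger dots saturate the burst
region and erase density differences). Rendering is deterministic; PNG
export encodes provenance in the filename.

## Image features

The contract is a 4096-dimensional descriptor per window. Two backends:

- **alexnet** — fc7 activations of the pretrained AlexNet (loaded
  lazily; requires torch/torchvision).
- **fixture** (default) — a deterministic, dependency-free extractor:
  the ink-inverted image is downsampled to 64 × 64; its 2-D FFT
  log-amplitude spectrum (2080 values) is concatenated with a 16 × 16
  mean-ink grid (gain 4, putting it on the spectrum's scale) and passed
  through a fixed seeded Gaussian projection to 4096 outputs. The
  amplitude spectrum discards where bursts fall inside the window — the
  translation invariance a convolutional network acquires through
  pooling — while keeping burst rate, width and density linearly
  readable; the grid channel keeps electrode-row structure. A plain
  linear projection of raw pixels was rejected: burst phase is random
  per window, so without the invariance the classes are not linearly
  separable across wells and only kernel methods recover them.

Features are vehicle-normalized per well: each vector minus the
per-dimension mean of that well's vehicle-window vectors (a z-score
variant divides additionally by the vehicle s.d. + 1e-8). Centering
removes the well's initial-state signature (electrode layout, baseline
rate and ink level); after centering the vehicle set has exactly zero
mean, making the operation idempotent and shift-invariant.

## Classifiers and training schemes

The seizure-risk model is a pattern-recognition network
4096 → 9 sigmoid units → 2-class softmax; the drug-ID model is
4096 → 120 → 14. Training is full-batch Adam (float32) on the
cross-entropy with: input standardization on the training partition
(mean/s.d. stored with the model — the conventional pattern-net input
preprocessing, and necessary here because Adam otherwise fits
high-variance noise dimensions before the signal), L2 1e-3 on the
weight matrices, learning rate 0.01 (0.02 for the 120-unit net),
validation loss checked every 5 iterations with early stopping after
20 checks without improvement, best weights restored. Training is
deterministic given the seed (Glorot-uniform init).

Evaluation is always grouped by well. Holdout: test wells contribute no
windows to training; within training wells the windows split 75/25 into
fit/validation. Leave-one-well-out: every well held out in turn, R
replicate models per fold differing only by seed (default R = 5); the
held-out well's window distributions are the element-wise mean over its
replicates. Leakage (a test well's window in training) raises a hard
error.

Window probabilities aggregate to a well risk — default the proportion
of windows with positive probability ≥ 0.5, with mean-probability as the
alternative mode — then to a concentration risk as the mean over wells,
called positive at ≥ 50%.

Risk training labels: vehicle epochs and seizure-free compounds are
negative; positive compounds at designated concentrations (≥ the
generator's half-max by default) are positive; sub-threshold windows
are excluded from training and predicted at evaluation. Drug-ID labels
per the 13-compounds-plus-pooled-negative scheme: the negative class is
the seizure-free compounds (all their epochs); positive-compound
vehicle windows and sub-threshold windows are prediction targets only.
No class weighting or resampling.

SVM baselines go through scikit-learn: a linear SVM on the same 4096-d
features (decision values as ROC scores), a one-class SVM (RBF, ν=0.1,
γ=scale) trained on negative feature vectors (34 time-series parameters
— pooled and per-electrode mean rate and mean ISI, missing ISIs coded
as the epoch duration — or the five burst parameters), and a
leave-one-well-out multi-class linear SVM with one model per well.

## Evaluation

The ROC curve is computed over all distinct score thresholds (no
vertex dropping) with trapezoid AUC. The operating point slides a line
of slope S = [Cost(P|N) − Cost(N|N)] / [Cost(N|P) − Cost(P|P)] · N/P
from (FPR 0, TPR 1) until it touches the curve — implemented as the
vertex maximizing TPR − S·FPR, ties resolved toward the smaller FPR
(conservative against false positives). Default costs are unit
misclassification costs with zero reward, so S = N/P. At the chosen
threshold the report gives accuracy, PPV, sensitivity, specificity and
the F-measure. F defaults to the standard F1 = 2·PPV·Sen/(PPV+Sen); a
`text_literal` variant PPV·Sen/(PPV+Sen) — the harmonic-mean form
sometimes written without the factor 2 — is kept behind a flag because
the two disagree by exactly that factor (0.5 vs 1.0 for a perfect
classifier) and published tables are consistent with standard F1.

## Synthetic data: what it emulates and what it does not

No public recordings exist for this assay, so the generator produces
ground-truth-labeled plates. Baseline (vehicle) activity per well:
network bursts once per period slot (default rate 12/min), onsets
displaced by centered Gamma jitter (s.d. 0.5 s), each burst placing
round(150) spikes over a Beta(2,2) envelope of default duration 1.0 s —
peaked so a pooled-rate maximum exists for the IMFI — across 12 of the
16 electrodes; the participating subset is drawn once per well (the
layout is a property of the well, which is exactly what vehicle
normalization must remove). Background firing is Poisson at
0.3 Hz/electrode. Defaults were chosen once as typical of mature
hiPSC-derived cortical cultures (bursts every few seconds lasting
0.5–2 s over most electrodes, sparse tonic background). Per-well
baseline variability is lognormal (cv 0.1) on burst rate and size.
Times are quantized to the 1e-5-s spike-table grid with collisions
nudged forward, so generation → write → read is lossless.

A drug mechanism is a set of saturating multiplier curves on the
generator parameters: multiplier(c) = M^frac with the Hill occupancy
frac = c^h/(c^h + EC50^h) (default EC50 1 µM, Hill 2), so the
multiplier is 1 at zero, saturates at M, and up- and down-regulation
are symmetric folds (√M either way at the EC50). Effect sizes
small/medium/large map to ×1.2/×2/×3 maximal fold (reciprocal for
downward effects). The library ships 13 positive
mechanisms plus a null negative; signatures were designed to be
pairwise distinct along axes a binary raster image can express — burst
rate, burst duration, electrode participation, background rate, and
ink density in combination. Two physical constraints shaped this
design: raster rows saturate, so within-burst spike count alone is a
weak signature (it is only used jointly with rate or duration changes),
and background beyond ~1 Hz/electrode floods the pooled train and
merges bursts, so background multipliers use the standard fold. The
kainate-like `ts_down` collapses firing on all axes (spikes, background
and burst rate down), mirroring how a glutamatergic excitotoxic
response silences network bursts.

What passing the end-to-end tests shows: the full pipeline — detection,
IMFI windowing, rendering, feature extraction, vehicle normalization,
grouped training and aggregation — recovers known mechanism-specific,
concentration-dependent effects from held-out wells at realistic
within- and between-well variability. What it does not show: performance
on real recordings, where bursts have richer internal structure,
electrodes are heterogeneous, effects are not clean Hill curves, and
the fixture extractor is not AlexNet. The headline numbers of the
original assay are not reproducible without its (non-deposited)
recordings.

## Problem sizes in the test suite

The default suite runs on 1 CPU in well under half an hour, so the
end-to-end checks use scaled-down but otherwise identical conditions:
the risk task uses 6 positive mechanisms plus the negative compound at
5 wells each (3 training, 2 held-out — the assay's n = 3–4 wells per
condition motivates the count) with full 600-s epochs and a by-well
holdout; the drug-ID task uses all 14 classes × 3 wells with 240-s
epochs, leave-one-well-out, and R = 2 replicate models per fold (the
library default remains R = 5). Effect size "large", concentration
grid {0.3, 1, 3} µM around the EC50 of 1 µM.

## Known limitations

- The four burst-detection thresholds are conventions, not fitted to
  any reference dataset; absolute NoB/DoB values shift with them.
- The fixture extractor is a designed stand-in for a pretrained deep
  backbone: adequate for the synthetic benchmark's geometry, but not a
  claim about AlexNet's representational power.
- IMFI is defined as the median peak-to-peak spacing; alternative
  readings (onset-to-onset, mean) change window widths by a few
  percent.
- Dunnett gatekeeping on the omnibus ANOVA is a choice; reporting
  ungated adjusted p-values alongside would also be defensible.
- The one-class and multi-class SVM baselines use fixed, conventional
  hyperparameters; no search is performed.
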