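# Methods

## Problem and pipeline

High-frequency oscillations (HFOs) — brief 80–500 Hz events in intracranial
EEG — are biomarkers of epileptogenic tissue. `hfopipe` implements a
two-step, feature-based machine-learning procedure over fixed-window
segmentation of multichannel iEEG:

1. **Detection** (binary): every non-overlapping segment of a band-filtered
   recording is described by twelve energy features and classified as HFO vs
   background.
2. **Classification** (three-class): segments detected (or annotated) as HFO
   are assigned to ripples (R, 80–250 Hz), fast ripples (FR, 250–500 Hz) or
   fast-ripples-on-ripples (FRonR).

Both steps compare five classifier families — LDA, l2 logistic regression,
linear SVM, KNN and random forest — under a common protocol, and a
rank-based statistics layer (Friedman test with Nemenyi or
Holm/Bergmann–Hommel post-hocs) compares window lengths and algorithms
across subjects. Analysis is within-subject throughout: every subject gets
their own models and metrics, and the cross-subject statistics operate on
the subjects × conditions metric matrix.

## Features

Each recording is band-passed into three bands (ripple 80–250 Hz,
fast-ripple 250–500 Hz, broad 80–500 Hz) and cut into non-overlapping
windows of 10, 50 or 100 ms. Per band and segment, four features:

| feature | definition |
|---|---|
| line length | (1/(N−1)) Σ \|x[n+1] − x[n]\| |
| short-time energy | (1/N) Σ x[n]² |
| RMS | √(short-time energy) |
| Teager energy | (1/(N−2)) Σ (x[n]² − x[n−1]·x[n+1]) |

All four are window-length-normalized means (the cited source definitions
differ on sums vs means) so values are comparable across the 10/50/100 ms
conditions; this is a per-condition constant rescaling and does not change
any classifier's decisions once features are standardized. Features are
z-scored with training-partition statistics inside every fit (a
`StandardScaler` leads each model pipeline), which KNN and SVM require for
sensible distance/margin behavior.

**Filter.** Zero-phase FIR (Kaiser design, ~65 dB single-pass attenuation
over a 20 Hz transition, applied forward-backward), cut-offs pushed half a
transition width outside the nominal band so the band edges sit in the flat
pass band. Measured on the zero-phase output, pass-band ripple is < 1 dB
and attenuation ≥ 40 dB at the band edges ± 20 Hz. Zero phase matters:
a causal filter's group delay would shift event energy relative to the
annotation-based labels.

**Labeling.** Annotations are half-open `[start, end)` intervals in seconds.
A segment takes the class of the event with maximal temporal overlap
fraction (overlap / window length) when that fraction is ≥ 0.5, else
`noHFO`; exact ties break by precedence FRonR > FR > R (the rarer, more
specific class wins).

## Step-1 protocol

Per subject and window length:

1. **Balancing.** All HFO segments (R ∪ FR ∪ FRonR) are kept; an equal
   number of background segments is drawn uniformly without replacement.
2. **Tuning.** A stratified 30% holdout is grid-searched by mean AUC under
   internal 3-fold CV. Grids: LDA none; LR/SVM penalty or cost over 13
   log-spaced points 10⁻³…10³; KNN k = 1…20; RF {100, 200} trees ×
   depth {5, 10, 20} × min-split {2, 5, 10} × min-leaf {1, 2, 4}.
   Ties resolve toward the simpler model (heavier regularization, larger k,
   smaller/shallower forest): candidates are enumerated simplest-first and
   only a strictly better score displaces the incumbent.
3. **Evaluation.** Stratified 5-fold CV on the remaining 70%; per fold AUC
   (from continuous scores), sensitivity and specificity (at the model's
   native decision rule, i.e. 0.5 posterior for probabilistic models). One
   tuned setting is reused across folds, matching the explicit 30%/70%
   separation of the protocol.

A learning-curve helper re-trains each family on growing stratified subsets
under 10-fold CV, recording train/validation AUC and wall-clock fit time
(reported, never asserted — timing is machine-dependent). The deployment
entry point (`detect`) applies a trained model to a recording and merges
consecutive positive segments into scored intervals.

## Step-2 protocol and ADASYN

Step 2 operates on the HFO rows of the 10 ms table (ground-truth segments,
as the protocol evaluates it; a cascade on step-1 positives is available at
the CLI). Ripples dominate (~90%), so minority classes are oversampled with
ADASYN: with minority count m_s and majority count m_l, G = round((m_l −
m_s)·β) synthetics are generated; each minority point x_i receives g_i ∝
Δ_i, its count of non-minority members among K = 5 nearest neighbors
(Euclidean on z-scored features), so generation concentrates near class
boundaries; each synthetic is x_i + λ(x_z − x_i), λ ~ U(0,1), x_z among
x_i's K nearest minority neighbors. If all Δ_i = 0 the allocation is
uniform. The binary algorithm is extended to three classes one-vs-rest per
minority class, with the majority count as target.

**Leak control.** ADASYN is fitted and applied inside each training fold
only; synthetic rows carry a flag and never reach an evaluation fold.
Oversampling before splitting would place synthetic near-copies of
evaluation points into training and inflate metrics; that ordering is
available behind `oversample_before_split=True` for demonstration only.
Metrics are one-vs-rest sensitivity and specificity per class from
stratified 3-fold CV after a 30% tuning holdout (tuning score:
macro-averaged one-vs-rest AUC).

## Rank-based comparison

The Friedman test uses per-subject average ranks with the standard tie
correction (metric ties happen with rounded AUCs); χ² reference with k−1
df. Post-hocs: Nemenyi critical difference CD = q_α(k)·√(k(k+1)/(6N)) with
q from the studentized-range distribution at infinite df (cached table
fallback), used for window-length comparisons; pairwise z-tests with Holm
(via statsmodels) or Bergmann–Hommel correction for algorithm comparisons.
Bergmann–Hommel enumerates exhaustive hypothesis sets — one per partition
of the conditions into equal-groups — and is implemented by enumeration,
feasible for k ≤ 6 (the relevant case is k = 5 algorithms); it rejects a
superset of Holm's rejections at the same α. The "significance graph"
connects conditions that are *not* significantly different.

## Synthetic data generator

The generator emulates the statistical structure of the interictal sleep
iEEG the pipeline assumes, so every stage is testable without data
downloads. Defaults are the emulated study's conditions:

| parameter | default | rationale |
|---|---|---|
| sampling rate | 2000 Hz | the analysis rate of the emulated recordings |
| duration | 300 s | five minutes of interictal recording per subject |
| channels | 4 | small differential-montage subset |
| background | 1/f¹, RMS 1.0 | canonical EEG spectral shape; units arbitrary |
| spikes | 1/min/channel | interictal sharp transients (biphasic, 20–70 ms, 4× RMS) as false-HFO confounds |
| HFO rate | 6/min/channel | keeps 10 ms segment prevalence ≈ 1% (well under 10%) |
| class mix | 0.90 / 0.05 / 0.05 | ripples ≈ 90% of events; FR/FRonR split unreported, set equal |
| R duration | truncated normal, mean 96.2 ms, sd 45.5, bounds [30, 300] ms | published ripple duration statistics |
| FR duration | truncated normal, mean 40.6 ms, sd 26.7, bounds [10, 150] ms | published fast-ripple statistics; 10 ms minimum duration |
| event SNR | 3.0 | peak in-band amplitude / in-band background RMS |

Durations are drawn from truncated normals whose *truncated* moments match
the published mean/sd (the parent parameters are solved numerically);
naively truncating a normal located at the published mean would inflate the
sample mean by ~6 ms because the bounds are asymmetric.

Events are Hann-windowed sinusoids with a per-event frequency drawn from
the class band, kept ~2/T Hz away from the band edges so short events do
not leak out of band. FRonR is rendered as one composite event: a ripple
tone plus a fast-ripple tone over the same support (the fast component's
support is contained in the ripple's), with each component's peak amplitude
calibrated against its own band's background RMS. Onsets follow a
homogeneous Poisson process per channel; overlapping draws are rejected and
redrawn; all events lie strictly inside the record. Everything is a pure
function of (config, seed): identical seeds give bit-identical output.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: physiologically detailed HFO morphology (chirps,
asymmetric envelopes, harmonics), artifact channels, ictal activity,
non-stationary background, inter-subject variability of spectra, or the
upstream automated marking that produced the emulated dataset's ground
truth. Events here are exactly where the annotations say, which real
markings are not.

### A known, deliberate property of the event model

With a Hann envelope and the ≥ 50%-overlap labeling rule, segments near
event edges are labeled HFO while carrying almost no oscillatory energy
(~39% of HFO-labeled 10 ms segments lie where the envelope is below a third
of its peak). At the default event SNR of 3 this caps achievable
segment-level detection AUC near 0.8 — segments at the envelope peak
separate from background at AUC ≈ 0.96, edge segments are at chance. This
is a property of tapered events at moderate SNR, not an implementation
artifact, and it mirrors how real HFO detection is hard at high temporal
resolution; the high-SNR tests (event recall ≥ 95% at SNR 50) show the
injection and recovery machinery itself is sound.

## Numerical choices and degenerate inputs

- Feature definitions require N ≥ 2 (line length) or N ≥ 3 (Teager);
  shorter windows raise a degenerate-window error. The 10 ms window needs
  ≥ 3 samples, i.e. fs ≥ 300 Hz.
- Trailing partial windows are dropped; a window longer than the signal
  yields an empty segment list, not an error.
- Overlap-fraction ties in labeling use a 1e-12 tolerance before the
  precedence rule applies.
- Grid-search tie-breaks are exact score equality on the simplest-first
  enumeration; with continuous features exact ties essentially occur only
  when candidates are equivalent (e.g. separable data).
- ADASYN requires m_s ≥ 2 and K < m_s; inside CV folds the K is clamped to
  m_s − 1 for very small training partitions rather than aborting the fold.
- All randomness flows from integer seeds through `numpy.random.Generator`;
  per-stage seeds are derived from the master seed with `SeedSequence`, so
  the full pipeline is bit-reproducible. Fit times are the only
  non-deterministic outputs and live in their own table.

## Scaled-down problem sizes

The acceptance suite exercises the full protocol at sizes chosen to keep a
complete run cheap on one CPU: one default 5-minute subject (≈ 120 000
10 ms segments, ≈ 1 200 HFO segments) for the recovery checks, and a
three-subject cohort of 2-minute recordings (the four fast classifier
families; the random-forest grid is exercised at full size in the recovery
checks) for the end-to-end reproducibility run with learning-curve sizes
140/280/420. The default
learning-curve sizes (720/1440/2520/3240) exceed what a 5-minute synthetic
subject's balanced table provides; `run_full` skips infeasible sizes with a
logged notice. The full-size protocol is the same code path.

## Known limitations

- Step-2 minority classes are scarce at default prevalence (a 5-minute
  subject yields only tens of FR/FRonR segments), so per-class metrics have
  high fold-to-fold variance; pooling more channels or longer records is
  the remedy.
- The EDF path is read-only (plus a multi-rate rejection probe); recordings
  are written to the `.npy` + JSON sidecar container.
- Cross-subject transfer, probability calibration, nonlinear SVM kernels
  and cost-sensitive thresholds are out of scope.
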