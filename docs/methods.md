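# Methods

This note records the models, parameter choices and numerical conventions
behind `eegfd`, and what the synthetic validation does and does not
establish about real EEG.

## Signal model and ground truth

The synthetic cohort treats each EEG channel as a Gaussian fractal
process parameterized by a Hurst exponent H ∈ (0, 1). Stationary
fractional Gaussian noise is sampled exactly by circulant embedding
(Davies–Harte): the autocovariance
γ(k) = ½(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H}) is embedded in a
2(N−1)-periodic circulant whose FFT eigenvalues are non-negative for fGn,
so two FFTs give an exact draw. The channel signal is the *cumulative
sum* of these increments — a sampled fractional-Brownian-motion path —
because it is the motion's graph, not the stationary increments, whose
fractal dimension is analytically 2 − H. (The Higuchi estimator applied
to raw fGn gives values near 2 for every H, since its curve lengths then
scale as k^{-2}·sqrt(1 − ρ(k)); the integrated series recovers 2 − H to
within ±0.01 at N = 2500, which is the ground-truth channel all
recovery tests use.)

Group structure: all groups share H = 0.70 on unaffected channels;
channels 4, 5, 6 and 15 (F3, Fz, F4, Pz) carry group-specific H in
0.10 steps — addict 0.85, first 0.75, second 0.65, normal 0.55 — so
active addiction has the lowest planted complexity (FD 1.15) and healthy
controls the highest (1.45). The 0.10 step is large enough for
desk-scale statistical power at 20 subjects per group yet small enough
that classification is not trivial. Subject counts default to the study
composition (19/24/23/20); two eyes-closed recordings per subject are
independent draws sharing the subject's Hurst profile (within-subject
dependence is not modelled). Eyes-open recordings are not simulated.

**Channel scaling.** Channels are scaled to equal per-sample *increment*
SD (default 1 µV), not equal path SD. Under common average referencing
each channel absorbs a 1/19 admixture of every other channel; with equal
path amplitudes the small-scale increments of rough (low-H) channels are
an order of magnitude larger than those of smooth channels, and that
cross-talk dominates the smooth channels' curve lengths and destroys the
planted ordering. Equal increment scaling keeps the admixture a uniform
≈5% variance perturbation at every lag, and the full cleaning chain then
recovers the planted group ordering on the affected channels while null
channels stay flat.

**Artifacts.** Injected contamination mirrors what the cleaning chain
removes: a 50 Hz sinusoid (10 µV, random phase per channel), slow
sinusoidal drift (30 µV at 0.1 Hz), and Poisson-timed ~50 ms Gaussian
transients (0.05/s, 800 µV). These are caricatures — real mains noise is
nonstationary, drift is aperiodic, and muscle/ocular artifacts have
structure that only ICA-class methods can address — so passing tests
demonstrate that the deterministic chain removes *these* nuisances, not
that it cleans arbitrary clinical EEG.

## Preprocessing

Fixed order: baseline removal (per-channel mean subtraction) → 1–70 Hz
band-pass → 50 Hz notch → common average reference → bad-channel repair
→ amplitude-threshold window rejection. All stages are pure functions;
composite output is checked finite.

* **Band-pass**: windowed-sinc (Hamming) linear-phase FIR, cutoffs
  mid-transition (0.75 Hz and 75 Hz), tap count from the Hamming
  transition-width rule for the 0.5 Hz lower transition (1651 taps at
  250 Hz), applied forward–backward (zero phase). Forward–backward
  application doubles attenuation in dB: ≥100 dB at 0.5 Hz and 80 Hz,
  passband ripple well under 1 dB.
* **Notch**: second-order IIR notch (zero on the unit circle at 50 Hz),
  quality factor 15, forward–backward; ≥30 dB at 50 Hz with under 1 dB
  loss at ±5 Hz.
* **Bad channels**: flagged when peak-to-peak < 0.1 µV (flat) or any
  |sample| > 500 µV; repaired as the unweighted mean of non-bad 10–20
  neighbours (hard-coded geometric adjacency). More than 50% bad
  channels, or a bad channel with no good neighbour, is unrecoverable.
* **Rejection**: consecutive non-overlapping 1 s windows; a window is
  dropped if any channel exceeds ±200 µV. All-windows-rejected is
  unrecoverable.
* **ICA** component removal is deliberately out of scope: it is not
  deterministic across implementations and is delegated to external
  tools; the pipeline accepts already-ICA-cleaned data.

Filtfilt padding is capped at one sample less than the record, so short
records (≥ a few hundred samples) remain filterable with edge effects
confined to the record ends.

## HFD estimation

`k_max = 8` by default (stable for 250 Hz segments of ≥1000 samples;
exposed in `HFDConfig` together with an optional fit range). The
regression is ordinary least squares of ln ⟨L(k)⟩ on ln (1/k), no
weights, no clipping. The estimator is exactly affine-invariant and is
computed on the broadband cleaned signal — no band decomposition.
Subjects contribute exactly two eyes-closed recordings; with more, the
first two in manifest order are used; with fewer, the subject is
excluded with a warning.

## Fuzzy partition membership

The partition generator is a single CART tree (Gini impurity, minimum
leaf 2, unlimited depth, deterministic); cells are its leaves, keeping
the sum-to-one fuzzy-partition semantics. Crisp membership is the
one-hot leaf indicator. Graded membership softens each split with a
logistic σ(±(x_f − t)/b_f); a leaf's degree is the product along its
root-to-leaf path, so degrees are in [0, 1] and sum to one by
construction, and shrinking the bandwidth recovers the crisp assignment.
Default bandwidth is 0.25 × the per-feature interquartile range of the
training fold (SD fallback where the IQR is zero). In cross-validation
the partition is always fitted on the training folds only; fitting on
all data is possible through the library but is leakage and is not the
default anywhere.

## Attribute evaluators

All four return a full ranking with deterministic lower-index
tie-breaks, applied to the raw 38 HFD attributes:

* **correlation** — class-frequency-weighted mean |Pearson r| against
  one-vs-rest class indicators (constant attributes score 0);
* **chi-squared** — equal-frequency discretization (10 bins, reduced
  with a warning when n is small) then the χ² statistic of the
  bin×class table;
* **significance** — mean of the two Theil uncertainty coefficients
  U(attribute|class) and U(class|attribute) on the same table; this
  realizes "two-way probabilistic association" with a documented closed
  form (1 for a class-determining attribute, 0 for a constant one);
* **PCA loadings** — eigendecomposition of the attribute correlation
  matrix; score_j = Σ_c λ_c |v_c[j]| over the leading components
  (default: smallest set explaining 95% of variance). Zero-variance
  attributes are excluded and rank last. Being unsupervised, this
  evaluator rewards attributes that share dominant variance directions —
  it finds the planted effect because the affected-channel features are
  mutually correlated, not because it sees labels.

## Classification

Eleven schemes for four groups: all-groups, four one-vs-rest, six
pairwise (1 + g + C(g,2) in general). Stratified k-fold (default 10)
with pooled out-of-fold predictions; folds are reduced with a warning
when the smallest class is smaller than k. Any fitted transform
(partition membership, standardization) is fitted per training fold.

Model defaults follow the conventions of the WEKA tools the analysis
mirrors: MLP with one hidden layer of ⌈(p + classes)/2⌉ logistic units,
backpropagation (SGD, learning rate 0.3, momentum 0.2, 500 epochs,
minibatches of 32 to approximate online updating, standardized inputs);
SVM with RBF kernel at default scale, one-vs-one multi-class, and
probability calibration for score-based areas. ROC/PRC areas come from
pooled out-of-fold one-vs-rest probability scores and are approximate
for the SVM (Platt-style calibration). Report tables round half-up to
2 decimals. All model runs are reported; a "best by weighted F" summary
states its selection rule in the manifest.

## Group statistics

Normality screening is the Kolmogorov–Smirnov test with Lilliefors
correction (parameters estimated from the sample; the plain KS variant
is available and flagged). Per-attribute one-way ANOVA across the four
groups reports uncorrected p-values — each attribute treated as its own
family — alongside a Bonferroni column over the 38 tests for the
conservative reading. Post hoc comparisons use Tukey's HSD (studentized
range) over all six group pairs. Significant attributes map to channels
via channel = ⌈j/2⌉ with duplicates collapsed per channel.

## Determinism and problem sizes

A single run seed fans out to named substreams (stage → subject →
repetition) via `SeedSequence` spawn keys, so adding a stage or subject
never perturbs other streams, and identical configs reproduce every CSV
bit-for-bit. Derived integer seeds stay below 2³¹.

Validation problem sizes are chosen for desk-scale runs: fractal-
dimension recovery uses N = 2500 samples (10 s at 250 Hz) with 50
replicates; the synthetic study analog uses 20 subjects per group, 20
replicate cohorts for ANOVA detection/false-positive rates (artifact-free
cohorts, since the detection question concerns the estimator and test,
not the cleaning chain), and one artifact-contaminated cohort through
the full cleaning chain for the classification margin.

## Known limitations

* The generator's channels are statistically independent; real EEG has
  strong inter-channel correlation (volume conduction), which changes
  how common average referencing behaves. Passing tests validate the
  pipeline mechanics and the estimator, not clinical performance.
* The 70 Hz low-pass slightly compresses high fractal dimensions at the
  smallest delays (k = 1, 2), a bias shared across groups that preserves
  ordering but shifts absolute values.
* fGn/fBm is a single-exponent model; real EEG complexity is
  band-dependent and nonstationary.
* ROC/PRC areas depend on probability calibration details and are the
  only outputs not reproducible bit-identically across BLAS builds
  (they reproduce to ~1e-9).
* The psychological-questionnaire analyses of the original study design
  are out of scope; only the EEG arm is implemented.
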