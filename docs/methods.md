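# Methods

This note documents the models and procedures implemented in `eegimpact`,
the defaults and why they are what they are, and the limits of what the
synthetic validation establishes.

## 1. The synthetic cohort

### Study design emulated

36 subjects (configurable), alternately assigned to a *kicking* group
(exercise bout before the baseline session) and a *non-kicking* group;
three sessions per subject (pre-impact, 1 h post, 24 h post); 8 blocks of
2.5 min per session in the fixed cycle sitting-open, sitting-closed,
standing-open, standing-closed (twice); 32-channel 10-10 montage at
512 Hz, microvolt units.

### Signal model

Each channel is the sum of

1. **Broadband background** — stationary Gaussian noise synthesized in the
   frequency domain with one-sided PSD `A / max(f, f₀)^β`
   (A = 15 µV²/Hz at 1 Hz, β = 1, floor f₀ = 0.5 Hz). Random-phase
   synthesis makes the target spectrum exact in expectation.
2. **Narrow-band oscillator sources** — four shared sinusoidal sources
   with Gaussian scalp topographies: bilateral occipito-parietal alpha
   (10 µV² at the peak channel, frequency drawn per block from 9–11 Hz)
   and bilateral central beta (2 µV², 16–19 Hz), random phase per block.
   Shared sub-Gaussian sources emulate volume-conducted rhythms and are
   what makes ICA decomposition of the data well-posed; a purely Gaussian
   background has no identifiable components.
3. **Artifacts** at Poisson-placed, manifest-recorded times: blinks
   (12/min, ~120 µV raised-cosine of 300 ms, frontal-polar topography),
   horizontal saccades (4/min, ±60 µV step-plateau-step, antisymmetric
   lateral-frontal topography), and jump transients (mean 1/block, one
   channel, 50–200 ms, 25× that channel's background SD — comfortably
   beyond the 15-SD rejection rule).

Band-power *effects* are multiplicative factors on the PSD within a band ×
scalp region: per-lag impact effects, an eyes-closed alpha boost (×2), an
exercise after-effect applied to any session recorded within ~1 h of a
bout (kicking group: baseline and 1 h-post sessions; non-kicking group:
1 h-post only — this asymmetry is what lets the subgroup analysis separate
exercise from impact), and per-subject, per-band log-normal offsets
(σ = 0.2) for between-subject variability.

The paper reports no effect sizes, so the injected factors are free
parameters of the stated scenarios, not estimates of the real phenomenon:
the "late effect" scenario uses occipital alpha ×1.5 and frontal theta
×1.3 at 24 h (and nothing at 1 h); the "disjoint" scenario adds a
different 1 h signature (central β₁ ×1.5, temporal δ ×1.4); the exercise
after-effect is γ ×1.3, β₂ ×1.2 everywhere.

**Ground truth.** `expected_band_power` returns the analytic mean Welch
band power per channel. It pushes the target PSD through the exact Welch
measurement operator (circular convolution with the Hann taper's power
kernel): for a steep 1/f spectrum, taper smoothing shifts low-band means
by 10–17%, so a naive band-mean of the target PSD would *not* be what the
features converge to.

**Seeding.** One master seed; every block is seeded by its
(subject, lag, block) coordinates via `numpy.random.SeedSequence` spawn
keys, and subject offsets by (subject) alone — realizations are
independent of generation order and byte-reproducible.

## 2. Preprocessing

Fixed order: band-pass → average reference → ocular ICA → jump rejection,
each step logged in the block's provenance.

* **Band-pass 0.1–50 Hz**: zero-phase linear-phase FIR, Hamming-windowed,
  cascade of a high-pass with 0.1 Hz transition width (~33 s kernel) and a
  low-pass with 10 Hz transition; applied by centered convolution on a
  reflection-padded signal. ≥ 20 dB attenuation one octave beyond each
  edge; a 10 Hz tone passes within 5% RMS.
* **Average reference**: instantaneous channel mean subtracted; errors on
  single-channel input.
* **Ocular ICA**: FastICA in a PCA-reduced space of 8 components (up to 4
  seed restarts). The full channel rank is deliberately not used: the
  background is near-Gaussian, so a full-rank decomposition chases
  unidentifiable directions and rarely converges, while the ocular and
  oscillator sources — the genuinely non-Gaussian, high-variance ones —
  live in the top PCA subspace. Components whose mixing-column topography
  has absolute Pearson correlation ≥ 0.80 with either canonical eye
  template (frontal monopolar = vertical/blink; antisymmetric
  lateral-frontal = horizontal saccade) are removed, strongest first, at
  most 4. Removal subtracts only the matched components' contribution
  from the signal, leaving everything outside the ICA subspace bit-intact.
  If no restart converges the block passes through unmodified and is
  flagged. The templates are geometric reconstructions; a real deployment
  would calibrate them from EOG. Blocks shorter than ~60 s give unstable
  unmixing (estimation error bleeds background into the removed
  components).
* **Jump rejection**: per channel, the peak-to-trough amplitude of every
  0.5 s window (stride 1 sample, computed with monotonic min/max filters);
  windows exceeding mean + 15 SD of the series are flagged, flagged spans
  padded by 0.5 s each side, union over channels returned as a sample
  mask. The mean/SD population **pools all channels' window series** by
  default. The per-channel variant (available as `pooled=False`) is
  self-masking: a single-channel artifact covering fraction *f* of that
  channel's windows inflates its own threshold by ≈ 15·√f·amplitude, so
  for f > (1/15)² ≈ 0.44% — e.g. any ≥ 75 ms spike in a 2.5 min block —
  the artifact can never be flagged no matter how large it is. Pooling
  over 32 channels divides *f* by 32 and restores detectability.
  Excluded samples are masked, never deleted.

## 3. Band-power features

Welch PSD with NFFT = 512 (1 s windows at 512 Hz), 0.5 s overlap, Hann
taper, one-sided density scaling (µV²/Hz), **no per-window detrending**
(drift is already removed by the 0.1 Hz high-pass, and constant-detrending
each window would bias the delta band low relative to the generator's
stated spectrum). Any window containing a masked sample is skipped whole —
no concatenation across gaps, which would add splice-discontinuity
leakage. Band power is the mean PSD over bins whose centers fall in the
half-open band interval [low, high), so adjacent bands sharing a printed
edge never double-count a bin. A block with no clean window yields
missing (NaN) features, flagged per condition. Session features average
the per-condition blocks (unweighted); the table for one contrast has one
baseline and one post-impact row per subject and 768 feature columns.

## 4. Classifier and search

`HistGradientBoostingClassifier` stands in for XGBoost (not available
here): histogram split finding, 100 iterations, log-loss. Mapping of the
searched hyperparameters: max_depth ↔ max_depth (int 2–8), λ ↔
`l2_regularization` (log-uniform 1e-15–100), column fraction ↔
`max_features` (0.2–1.0), learning rate (log-uniform 0.01–1.0), number of
F-score-selected features (int, 10–width). α-regularization (log-uniform
1e-15–1), row subsampling (0.1–1.0) and min-split-loss = 1 have no sklearn
equivalent; they are still sampled and recorded so the search distribution
matches the stated one, but are not applied. Two backend constants are
set for subject-scale data: `min_samples_leaf=2` (the sklearn default of
20 makes splitting impossible on ~19-row training folds — every model
degenerates to the constant classifier) and `max_bins=64` (lossless below
64 training rows, ~30% faster).

Feature selection is one-way ANOVA F (`f_classif`), computed strictly on
training rows, top-k with index tie-break, constant features scored 0.

Grouped CV shuffles subjects by seed and deals them round-robin into k = 5
folds; each subject contributes one row per class, so folds are
automatically class-balanced under true labels. Fold scores are balanced
accuracy, degrading to the present class's recall if a shuffled-label fold
is single-class. A poisoning test verifies no leakage: overwriting
held-out rows leaves selected features and model outputs bit-identical.

The TPE search is a compact self-written Tree-Parzen estimator (no
sequential-optimization package is available): 10 uniform startup trials,
then candidates drawn from a per-dimension Parzen mixture over the top-25%
configurations and ranked by the good/bad density ratio, 24 candidates per
step, all in bounded unit coordinates (log-transformed where the range
spans decades). A `strategy="random"` fallback uses identical
distributions. Trial *i* is seeded from (search seed, *i*); results record
the strategy, trial log and arg-max.

## 5. Randomization inference

`randomization_test` runs the full search n_seeds times with true labels
and n_seeds times with labels freshly permuted before each search (fresh
search seeds too — the paper is silent on seed reuse), then compares the
score samples with a two-tailed Welch t-test (statistic and
Welch–Satterthwaite df verified against the closed form to 1e-12).
Degenerate zero-variance comparisons are reported as diagnostics, not
numbers. No multiplicity correction is applied across reported
comparisons, matching the original analysis.

**Shuffling unit.** Default is a uniform permutation of all rows (the
natural reading of "shuffling the target labels"). The within-subject
variant — each subject's baseline/post pair swapped with probability 1/2 —
is available via `shuffle_mode="within_subject"`, and matters more than a
sensitivity analysis at small cohort sizes: true labels are perfectly
subject-paired, and with p features and m subjects about p·2^(1−m)
features are by chance sign-consistent across every subject's pre/post
difference. Selection inside CV finds them, so paired-null tables carry a
"lucky-feature ceiling" that uniformly shuffled tables (which break the
pairing) cannot reach. At the full 36-subject scale this is negligible
(expected count ≈ 1e-8), but at the reduced validation scale of 12
subjects it is ≈ 0.4 per cohort and measurably inflates the uniform-shuffle
test's type-I rate (4/20 rejections at α = 0.05 in piloting, p-values
clustering at 0.02–0.04). The type-I acceptance check therefore uses
within-subject shuffling — the exchangeable unit of this paired design —
while power and dissociation checks keep the uniform default. The same
arithmetic dictates subgroup sizes: at 6 subjects/group (~24 lucky
features) true-label CV saturates near 0.8 on null contrasts, so the
subgroup validation uses 12 subjects per group.

**Transfer.** For each training lag and seed: full search → grouped CV
with retained fold artifacts; each fold's model classifies (a) its own
held-out post-impact rows (same-lag sensitivity) and (b) the *other* lag's
post-impact rows restricted to the same held-out subjects — the only
leak-free protocol when identical subjects appear at both lags. Shuffled
baselines run the same protocol but are always *evaluated* against the
true post-impact rows, keeping "sensitivity" interpretable as detection of
genuinely post-impact sessions. Only positive rows are comparable across
lags (the baselines are shared), hence sensitivity rather than balanced
accuracy.

## 6. Pipeline and I/O

`RunConfig` → `run_pipeline` composes simulate/ingest → preprocess →
featurize → classify → infer, streaming one session at a time (a full
36-subject cohort at 2.5 min blocks is ~19 GB and is never materialized).
A single master seed derives all stage seeds through a CRC-stable
SeedSequence construction; outputs embed the config SHA-256 digest and
package version, and a saved config re-runs byte-identically. EDF
round-tripping uses a minimal built-in 16-bit codec (plain EDF, µV);
cohorts can be exported as EDF + JSON manifest and re-ingested.

## 7. What a green suite establishes — and what it does not

The synthetic world is stationary Gaussian-plus-oscillators with
multiplicative band effects, stereotyped artifacts, and i.i.d.
between-subject variation. It validates the machinery: filters meet their
specs against closed-form oracles, the rejection rule matches brute-force
recomputation exactly, Welch matches scipy to 1e-6 and Parseval to 5%,
effects injected at known factors are recovered, the randomization test
has power for strong late effects, controls type-I error at the
exchangeable-unit null, and reproduces the published lag-transfer and
exercise-confound dissociations in pattern. It does *not* calibrate
real-world effect sizes, non-stationarity, heavy-tailed artifacts,
electrode drift, or physiological coupling between bands — and green tests
say nothing about whether real sub-concussive impacts are detectable at
any particular accuracy. The published headline numbers were computed on
undeposited human data and are deliberately not reproduced.

## 8. Known limitations

* The ocular templates and topographies are geometric idealizations.
* FastICA in 8 components can miss ocular variance if more than ~6 strong
  non-ocular sources compete; the removal cap (4) and threshold (0.80) are
  conservative defaults.
* The 15-SD rule, even pooled, cannot flag artifacts that occupy a large
  fraction of a short block (threshold inflation is intrinsic to
  moment-based thresholds; robust location/scale would behave better but
  is not what the procedure specifies).
* With ≤ 20 training rows the boosted trees are heavily
  regularization-dominated; hyperparameter search surfaces are flat and
  near-degenerate, which is faithful to the original design but means
  search results at this scale are mostly noise around the selection bias
  the randomization test corrects for.
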