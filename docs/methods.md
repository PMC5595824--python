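# Methods

This note documents the models and procedures implemented in `cssynergy`,
the parameter choices that matter, what the synthetic benchmark does and
does not emulate, and the numerical decisions taken where the design was
genuinely open.

## 1. Signal model and synergy factorization

Epoched multichannel signals are pooled into a matrix `B` of shape
`M × T` (channels × concatenated trial timepoints) after anti-alias
filtering and decimation to 50 Hz and restriction to the 0–1 s
post-onset analysis window (start-inclusive, end-exclusive; 50 samples
per trial).  The factorization approximates

    B ≈ W C,   W = W_PCA · W_ICA,   C = C_ICA

where `W_PCA` (M × N) holds the top-N orthonormal principal directions of
the row-centred `B`, and temporal ICA (FastICA, tanh/logcosh contrast,
symmetric decorrelation, tolerance 1e-6, at most 1000 iterations) rotates
the retained subspace so the N component time courses are as
statistically independent as possible.  Held-out data are projected as
`C_dec = W_ICA⁻¹ W_PCAᵀ (B − mean)`, which coincides with applying the
Moore–Penrose pseudoinverse of `W` to the centred data because `W_PCA`
has orthonormal columns.

Decisions taken where the formulation is open:

- **Centring.** Channels are centred by the *training* mean, which is
  stored in the model and reused when projecting held-out trials,
  keeping train/test treatment symmetric.
- **Scale and sign conventions.** ICA is scale-, sign- and
  permutation-ambiguous.  We normalize the columns of `W_ICA` to unit
  norm and move all scale into `C`; since `W_PCA` is orthonormal this
  also makes every composed synergy column of `W` unit-norm, directly
  comparable to the generator's unit-norm planted patterns.  Components
  are ordered by descending activation variance, and each activation's
  sign is flipped so its largest-magnitude value is positive.  These
  conventions affect presentation only, never the reconstruction.
- **Fit window.** The factorization is fitted on the same 0–1 s, 50 Hz
  window used for decoding rather than the full −1…2 s epoch; both
  stages then see identical preprocessing.
- **Non-convergence.** If FastICA does not reach tolerance the result is
  still returned, flagged `converged_=False` with a warning.  On noisy
  data with many near-Gaussian components this is common and benign: the
  basis still spans the PCA subspace exactly, so reconstructions and
  explained variance are unaffected; only the axis orientation within
  the subspace is approximate.
- **Synergy count `N`.** Default `min(channels, 32)` in the pipeline
  (32 = the desk-scale sensor count, a proxy for the rank of the sensor
  data from which channel signals derive); per-kind defaults are the
  sensor count for EEG synergy and `min(sensors, channels)` for CS
  synergy.  Configurable everywhere.

A structural identity worth stating: because `W_ICA` is invertible, the
N-component PCAICA reconstruction of any input equals its plain
N-component PCA reconstruction to machine precision.  ICA redistributes
the basis within the subspace; it cannot change the subspace.

## 2. Sparse Bayesian decoder (ARD logistic regression)

Each of the 8 classes gets a binary one-versus-rest logistic regression
with an independent zero-mean Gaussian prior of precision `α_i` per
weight (automatic relevance determination) and a Laplace approximation of
the posterior.  Features are z-scored by training statistics before
fitting (ARD decisions are scale-sensitive; constant features get unit
scale); the bias is never penalized or pruned.  A test trial receives the
class whose decoder reports the highest probability, ties broken to the
lowest class index.

Two optimizers are provided:

- `solver="sequential"` (default): fast marginal-likelihood ARD.
  Starting from an empty model, the single action (add a feature,
  re-estimate its precision, or delete it) that most increases the
  Laplace-approximate evidence is applied, and the posterior mode is
  re-found by Newton iteration after every change.  Sparsity/quality
  factors are computed for all features per sweep via the Woodbury form
  of the marginal covariance, costing O(n·d·|active|) per sweep.  This
  optimizer remains stable when features vastly outnumber trials and
  when informative features form strongly correlated temporal blocks —
  the regime of this pipeline (d ≈ 1600–3000 features, n ≈ 150 trials,
  smooth activations sampled at 50 Hz).  In that regime a parallel
  update-and-prune schedule is degenerate: it either stalls without
  pruning (each member of a correlated block looks individually
  redundant given the rest) or deletes entire blocks at once, including
  strongly discriminative features.
- `solver="prune"`: the classical iterate-and-prune schedule — Newton to
  the mode for fixed `α`, then a parallel MacKay effective-degrees
  update `α_i ← (1 − α_i S_ii)/ŵ_i²` (or an EM update,
  `update_rule="em"`), pruning features whose precision exceeds
  `alpha_prune` (default 1e8).  Retained for small, weakly correlated
  problems and for its clean reductions; when active features outnumber
  trials the Newton direction and covariance diagonal are computed in
  the n × n dual space via the Woodbury identity.

With `ard=False` the precisions stay fixed at `alpha_init` and the fit
reduces exactly to ridge-penalized logistic regression; the test suite
verifies this against an independent convex optimizer to 1e-6.

"Selected features" are those present in the final model (nonzero
weight); the per-class selected sets, mapped through the
(component, timepoint) feature map, feed the feature analysis.

## 3. Cross-validation and labelings

Half of the trials of each (target × angle) condition form the
*estimation* set (used only to fit the synergy basis); the other half
form the *decoding* set.  Decoding uses leave-one-trial-out
cross-validation over the decoding set: each fold holds out exactly one
trial per condition (16 test trials per fold under the default
mixed-angle reading; a `fold_unit="class"` switch gives the 8-per-fold
reading), trains the one-versus-rest decoder on the rest, and records
accuracy, predictions and selected features.  The synergy basis is
fitted once per split, not per fold, mirroring the separation of
estimation and decoding halves; test trials of a fold never enter
decoder training.  Fold membership depends only on the split seed, so
all four signal kinds (EEG, EEG synergy, CS, CS synergy) are evaluated
on identical test-trial sets and paired fold statistics are valid.
Non-convergent decoder fits are retained and flagged rather than
dropped, to avoid biasing mean accuracy.

The two labelings share one source of truth: the extrinsic class is the
target id regardless of elbow angle; the intrinsic (finger-movement)
class equals the target at elbow 0° and the target cyclically shifted by
+2 steps of the 45° grid at 90° (so target 8 at 90° maps to movement
class 2, and target 2 at 90° to class 4, the movement opposite class 8).
The shift direction is configurable should a different target numbering
be assumed.

## 4. Statistics

Paired comparisons of per-fold accuracies use sign-flip permutation
tests: the statistic is the mean fold-wise difference, the null is
generated by independent random sign flips, and
`p = (exceedances + 1)/n_perm` capped at 1 — so an observed statistic
beating all 10,000 permutations yields exactly 1.00e-04.  Tests against
the 12.5% chance level shuffle true labels within each fold and rescore.
Sidedness defaults: two-sided for signal-type comparisons, one-sided
(greater) versus chance.  The exchange unit is the CV fold; the paired
test is validated against exhaustive sign-pattern enumeration at small n,
and its type-I error is checked by simulation.  Multiple comparisons use
Benjamini–Hochberg step-up FDR with cumulative-minimum adjusted q-values
(delegated to statsmodels; verified against a brute-force reference).

## 5. Feature and dominant-area analysis

Feature-selection counts accumulate per (class, feature) over folds whose
accuracy exceeds 40% — above three times the 8-class chance level — and
the top-10 features by total count (ties broken by earlier time, then
lower index) are annotated with a brain area: the synergy's dominant ROI
for synergy features, the channel's own ROI for CS features.  A synergy's
*dominant area* is the ROI whose channels carry the highest mean
**absolute** weight; the absolute value is forced by ICA's sign
ambiguity (a sign-sensitive mean would be convention-dependent), and a
raw-mean option is provided.  Unassigned channels are excluded; an ROI
with no channels is excluded from the argmax with a warning; ties break
to the first ROI in canonical order.

## 6. The synthetic benchmark: what it emulates, and what it does not

The generator plants `N_true` synergies over a 60-channel space divided
into contiguous blocks for the six ROIs (hand knob, M1, PMd, PMv, SMA,
preSMA).  Each synergy has a unit-norm spatial pattern supported on one
ROI or on 2–3 distant ROIs (half and half by default), a unit-peak
Gaussian temporal bump, and a per-trial amplitude
`a = b + κ·cos(θ − φ) + ε` (truncated at zero) whose direction angle θ
follows the trial's intrinsic movement id or its extrinsic target,
according to the synergy's tuning frame.  Signals are
`W_true · C + noise` at 500 Hz over −1…+2 s epochs, with per-channel
Gaussian noise calibrated so signal-power/noise-power equals the
requested `snr`; channels outside every planted ROI carry noise at the
median signal power.  A spatially smoothed random matrix `L` with
unit-norm rows maps channels to sensors; sensor noise is white with RMS
equal to `sensor_noise` times the mixed-signal RMS; the inverse filter is
`G = Lᵀ(LLᵀ + λI)⁻¹`.

Default study conditions (chosen once, for realism, and held fixed):
20 epochs per condition at desk scale (1280-trial paper scale remains a
config choice), `snr = 10` for channel signals, `sensor_noise = 1.0`
(0 dB single-trial sensor SNR — still generous for scalp EEG, where
task-related activity typically sits at or below the background),
`λ = 1e-2`, tuning depth `κ = 0.8` on baseline 1.0 with amplitude noise
0.1, bump peaks jittered ±50 ms around the EMG-onset (200 ms) and
cursor-onset (400 ms) landmarks with widths 80–150 ms.

Two limitations matter when reading benchmark results:

- **Identifiability of the planted synergies.** With nonnegative
  amplitudes and temporally overlapping bumps, the planted activations
  are mutually *correlated* (they share the baseline co-activation), so
  temporal ICA's independence assumption is violated and no algorithm
  can fully recover the planted columns; under the defaults the matched
  mean |cosine| is ≈ 0.7.  Recovery tests therefore use a configuration
  that satisfies the independence precondition — narrow (30–50 ms),
  well-separated bumps and amplitude variation dominating the baseline —
  under which recovery reaches ≈ 0.96–0.97 and dominant-area assignment
  of planted single-ROI synergies is essentially perfect.  Passing those
  tests demonstrates correctness of the factorization under its model
  assumptions, not that real cortical synergies are exactly recoverable.
- **The linear mixing stand-in flattens the signal-type hierarchy.** In
  this benchmark the sensor signals are a 32-channel linear image of the
  full low-rank planted signal, and the estimated channel signals are in
  turn a deterministic linear transform of the sensors — no
  representation carries more *information* than raw sensors, and with
  only 32 sensors the raw-sensor decoder has no dimensionality handicap.
  Consequently raw-EEG decoding is strong here and the ordering expected
  from full EEG source-imaging analyses (CS synergy decisively above
  EEG) does not emerge: the measured desk-scale table is eeg 0.88/0.66,
  eeg_synergy 0.66/0.58, cs 0.56/0.40, cs_synergy 0.62/0.64 (int/ext).
  The mechanisms that favour estimated sources in such analyses — on the
  order of a hundred noisy sensors, an anatomically informed
  hierarchical-Bayes inverse, cortical ROI restriction — are exactly the
  components this benchmark replaces with the stand-in.  Synthetic
  results here validate the pipeline's machinery (all signal kinds
  decode far above chance; shuffled labels fall to chance; folds are
  paired), not a claim that synergy features dominate on real EEG.

## 7. Numerical details and degenerate inputs

- Decimation uses a zero-phase FIR anti-aliasing filter; constant
  channels are preserved exactly; an identity path skips filtering when
  the target rate equals the data rate.
- `PCAICA.fit` refuses `N` above the numerical rank of the training
  matrix; `explained_variance` raises on zero-variance input.
- The logistic sigmoid and log-likelihood are evaluated in numerically
  stable forms; Newton steps use step-halving and never decrease the
  penalized log-likelihood; Hessian solves switch to the dual (Woodbury)
  form when active features outnumber trials.
- Permutation p-values are bounded in `[1/n_perm, 1]` by construction;
  tie comparisons use a 1e-12 tolerance.
- All stochastic stages take explicit seeds; `RunConfig.with_global_seed`
  derives the five stage seeds (simulation, mixing, split, ICA,
  permutation) from one integer via `numpy.random.SeedSequence`.

## 8. Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` run the full pipeline at desk
scale — 60 channels, 32 sensors, 8 planted synergies, 20 epochs per
condition (320 trials; 10 decoding folds) — and the statistical
calibrations at 200 null simulations with 1,000 permutations; the
factorization oracles use M=40 channels, N=8 sources, T=2000 pooled
samples.  Paper-scale runs (80 epochs per condition, 128 synergies) are
a configuration choice and complete in proportionally longer time.
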