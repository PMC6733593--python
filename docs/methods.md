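# Methods

This note documents the models, estimators and defaults implemented in
`dualdecode`, the assumptions behind them, and the choices made where the
design was genuinely open.

## 1. Synthetic-EEG model

One simulated "subject" is a tensor of `n_trials x 64 channels x 565
samples` (512 Hz, −300…800 ms relative to stimulus onset, sample instants
at exact multiples of 1000/512 ms).

**ERP kernel.** Attentional selection of a target is modelled as half a
cycle of a sine wave: `a·sin(π(t − t_on)/(t_off − t_on))` inside
`[t_on, t_off]`, zero outside. Defaults: amplitude `a = 1 µV`, window
200–600 ms. The kernel is zero at onset/offset with a single interior
maximum at the window midpoint.

**Spatial pattern.** Eight posterior channels carry signal; the remaining
56 carry noise only, so the decoder's 64-dimensional feature space matches
a real recording. For the horizontal dimension the kernel is added
positively on the hemisphere contralateral to the target (PO8, P8, PO4, O2
for a left target) and negatively ipsilaterally (PO7, P7, PO3, O1); a right
target flips both signs. The vertical dimension uses an *orthogonal* split
of the same eight channels (lateral {PO7, P7, PO8, P8} vs. medial-occipital
{PO3, O1, PO4, O2}), intersecting each horizontal half in exactly two
channels, so the two ±1 channel templates are orthogonal vectors: each
dimension can be decoded without interference from the other. PO7/PO8 are
genuine 10–20 labels so the classical N2pc electrode pair resolves on
synthetic data.

**Correlation modes.** Whether the ERP is present on a trial is the
simulation's ground truth about seriality:

| mode | presence pattern | phi(H, V) |
|---|---|---|
| `positive` | both present on exactly half the trials, both absent on the rest | +1 |
| `negative` | exactly one present per trial (half/half) | −1 |
| `null` | independent Bernoulli(½) per dimension | 0 in expectation |

Position labels (left/right, top/bottom) are counterbalanced jointly
(n/4 per cell) and are independent of presence, so ERP-absent trials carry
chance-level information about their label by construction.

**Noise and SNR.** SNR is defined as peak ERP amplitude over *maximum*
noise amplitude. A hard maximum is only well defined for bounded noise, so
the default is i.i.d. uniform noise on `[−a/SNR, +a/SNR]` per
trial/channel/sample; the bound is bit-exact and attained to ~1e−4 relative
at study scale (≈18 M draws). Gaussian noise (σ = bound/3, so ±3σ matches
the bound) is available via `noise="gaussian"`. For noise-only data
(`amplitude = 0`) the bound is set explicitly through `noise_amplitude`.
Noise is white in time and space; no 1/f spectrum, spatial covariance or
head-model mixing is simulated — conclusions about the *pipeline* transfer
to real data, conclusions about absolute SNR thresholds do so only
approximately.

**Reproducibility.** One master seed; per-subject and per-stage child seeds
are drawn from `numpy.random.SeedSequence.generate_state` (kept below
2³¹). Identical configs regenerate tensors bit-exactly.

**Behavioural metadata** (RT ~ N(700, 120²) ms clipped at 250, 97% correct,
blocks of 64, random two-color target assignment) exist so the screening
rules have realistic input; they are not part of the neural ground truth.

## 2. Epoch screening

Rules run once, in a fixed order, and each rejected trial keeps the reason
of the *first* rule that fired: response → EOG → EMG.

- **Baseline**: per trial and channel, subtract the mean over −100…0 ms.
- **Response**: reject incorrect trials; RT < 200 ms (anticipations); RT
  above block mean + 3 SD, with the block statistics computed in a single
  pass over that block's trials surviving the first two rules (no
  iteration).
- **EOG steps**: a 100-ms window advanced in 50-ms steps across 0–500 ms;
  flag when |mean(second half) − mean(first half)| ≥ 30 µV. The split-half
  difference makes the detector exactly invariant to constant offsets.
- **EMG**: 110–140 Hz band-pass (4th-order Butterworth, zero-phase), mean
  squared amplitude per trial, z-scored across trials; cutoff
  `max(3, 3·SD(z))`. With plain z-scores SD(z) = 1 and the rule is a 3-SD
  cutoff; the second term widens it for heavy-tailed trial distributions
  instead of triggering mass rejection. Both constants are exposed.
- **Blink components**: decomposition-based cleaning of real recordings is
  out of scope here; the stage is a pass-through with a user hook.

## 3. Time-resolved decoding

For each time sample, a binary LDA is trained on the 64-channel voltage
vector under 10-fold cross-validation (trials shuffled once, folds of
near-equal size, every trial tested exactly once).

**Solver.** Pooled-covariance LDA with equal priors. Per class, the
covariance is the Ledoit–Wolf shrunk estimate computed on standardized
features and rescaled (numerically equivalent to scikit-learn's
`LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")`, which the
test suite verifies); the two class covariances are averaged and
`w = Σ⁻¹(μ₊ − μ₋)`, `b = −w·(μ₊ + μ₋)/2`. Shrinkage is essential at 64
channels vs. ~460 training trials. The solver is vectorized over
timepoints (batched Gram matrices and batched solves), which is what makes
full-epoch decoding of hundreds of samples tractable; a fixed shrinkage
value in [0, 1] may be supplied instead of `"auto"`.

**Balancing.** *Within-class*: inside each class of the decoded dimension,
trials are randomly undersampled until both levels of the orthogonal
dimension are equally frequent; removed trials leave the analysis entirely
(applied before fold assignment — it depends only on labels, so no test
information leaks). *Between-class*: on training folds only, the minority
class is oversampled to parity with synthetic trials
`x_a + u·(x_b − x_a)`, `u ~ U[0,1)`, where `x_b` is one of the five nearest
minority neighbours of `x_a` (whole-trial feature vectors); a singleton
minority falls back to duplication with a warning. Test folds are never
touched.

**Outputs.** AUC per timepoint (Mann–Whitney form, ties ½), averaged over
folds; per-trial confidence = signed distance `w·x + b` from the decision
boundary of the fold in which the trial was *test* data (positive ⇒
first-listed class: left, top); fold-averaged weights; activation maps
`Σ_train·w` (forward-model transformation), interpretable as source
topographies where raw weights are not.

`TimeResolvedDecoder` follows the scikit-learn estimator protocol
(`get_params`/`set_params`/`clone`); because it is a cross-validated
read-out, fitting and scoring happen in one `fit` pass and results are
exposed as fitted attributes (`auc_`, `confidence_`, …).

## 4. Group statistics

**Cluster permutation.** Pointwise one-sample t (vs. 0.5 for AUC, 0 for
differences and correlations) or paired t via the per-subject difference.
Cluster-forming threshold: the two-sided critical t at α = 0.05; clusters
are maximal contiguous same-sign supra-threshold runs (positive and
negative excursions clustered separately, the standard for signed
statistics — observed cluster extents match MNE's implementation exactly);
mass = summed |t|. The null distribution of the maximum mass comes from
per-subject sign flips (equivalent to condition swaps in paired mode);
p = (1 + #{perm ≥ obs})/(n_perm + 1), so p ≥ 1/(n_perm + 1) and the test
can never report p = 0. Sign flips leave per-subject squares unchanged, so
the permuted t statistics are computed from permuted means and fixed sums
of squares — one matrix product per test. Measured family-wise error on
pure-noise cohorts: 0.056 at nominal 0.05 (500 replicates; inside the
binomial 95% CI).

**Jackknife fractional-peak onsets.** For each leave-one-out group average:
smooth with a 3-point moving average (edges replicate the boundary
sample), find the peak in the 150–700 ms search window, and take the first
in-window sample at or above `chance + 0.5·(peak − chance)`. The 50%
criterion is referenced to the *elevation above chance* (0.5 for AUC, 0
for difference waves): a raw-value criterion would be met at the first
sample for any series that starts at chance. Ties at the crossing: first
at-or-above sample wins. A series that never exceeds chance yields NaN
with a warning; a peak at the window edge warns but returns. Condition
contrasts use `t_c = t_naive/(n − 1)` on the paired leave-one-out
differences (df = n − 1), compensating the artificially reduced variance
of overlapping subsamples; the identity `t_c·(n − 1) = t_naive` is asserted
in the tests.

**Switch/repeat split.** Trials partition by whether the target color
equals the previous trial's within the same block; first trials of blocks
are excluded.

## 5. Confidence-dependency diagnostic

Per subject and timepoint, Spearman ρ across trials between the two
decoders' confidence scores, computed on the intersection of the trials
each decoder retained. Confidence is by default *correctness-referenced* —
multiplied by +1/−1 so that positive always means "confident toward the
trial's true class" — making left/right and top/bottom trials
commensurable; without this, the raw signed distances of two independent
class codings would decorrelate by construction. `orient="raw"` preserves
the plain signed convention. The rank correlation is invariant under any
strictly monotone transform of either input (property-tested).

Group inference applies the cluster permutation test to the per-subject
ρ(t) series against 0. Additional summaries per subject: ρ at each
dimension's peak-AUC timepoint, and the Spearman correlation between the
two AUC *time courses* in 150–700 ms.

**SNR sensitivity sweep.** For each (mode, SNR) cell a fresh cohort is
simulated and fully analysed; `detected` records whether a significant
cluster with the injected sign overlaps the ERP window (for the null mode:
any significant cluster, i.e. the diagnostic's false-alarm rate). On the
reduced grid used in the test suite (3 modes × SNR ∈ {4, 0.5, 0.05}, 8
subjects × 128 trials) the injected sign is recovered at SNR 4 and lost at
the lowest SNR, reproducing the qualitative sensitivity curve; the full
17-level grid is available as `PAPER_SNR_GRID`.

## 6. N2pc analysis

Contra-minus-ipsi difference waves at PO7/PO8: for left-target trials
`PO8 − PO7`, for right-target trials `PO7 − PO8`, averaged over trials
(collapsing vertical position). In the noise-free limit the wave equals
exactly twice the injected kernel on ERP-present trials (asserted to
1e−12). Amplitude and onset latency reuse the jackknife machinery with
chance level 0, restricted to the 200–350 ms component window; `polarity`
selects the searched deflection sign (−1 for the recorded N2pc negativity,
+1 for the positive-contralateral synthetic convention).

## 7. Problem sizes and numerical choices

- Defaults follow the simulated study: 512 trials, 64 channels, 10 folds,
  5000 permutations for final inference. The test suite and bundled
  examples run a reduced profile (128 trials, 8 subjects, 500–1000
  permutations, decoding restricted to 100–700 ms) chosen so the full
  suite completes in minutes while every qualitative result (chance
  calibration, sign recovery, FWER calibration) is preserved.
- Uniform noise bound, fold partition and presence counts are exact
  (integer/bit-level assertions); statistical acceptance bands use
  Monte-Carlo tolerances stated in each test.
- Degenerate inputs fail loudly: single-class AUC, empty balancing cells,
  fewer trials than folds, < 3 subjects for jackknife, sub-Nyquist EMG
  bands all raise with specific messages.

## 8. Known limitations

- White bounded noise and a fixed binary spatial pattern understate the
  difficulty of real EEG decoding; absolute AUC values at a given nominal
  SNR are optimistic relative to recordings.
- The simulator models selection as all-or-none ERP presence; graded
  selection strength (partial amplitudes) is not modelled.
- Temporal-generalization matrices, channel-space clustering and
  Bayes-factor statistics are out of scope.
- ICA-based blink removal is a hook, not an implementation.
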