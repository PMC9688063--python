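# Methods

This note records the models, conventions and numerical choices behind
`eegms`, and what its synthetic benchmarks do and do not demonstrate.

## Synthetic cohort generator

The generator (`eegms.simulate`) emulates two groups of resting-state
eyes-closed recordings (19-channel 10/20 montage, 250 Hz, 15 min by
default) whose microstate dynamics are calibrated, per group and state,
to published healthy-control vs. schizophrenia statistics: occurrence
weights proportional to the groups' occurrence rates (HC ≈ 3.7–4.3 Hz
per state; the SZ-like group's state C down at 2.34 Hz), mean dwell
times of 56–80 ms (state D prolonged to 79.8 ms in the SZ-like group),
and GFP scales of 4.6–5.6 µV (slightly higher in the SZ-like group).
The SZ-like group gets a larger additive-noise SD (0.8 vs 0.5 µV), which
lowers its microstate map correlations for all states — emulating the
reported MsMC reductions.

**State sequence.** A semi-Markov process over runs: run lengths are
gamma distributed (shape 8, i.e. CV ≈ 0.35, the order of published
dwell-time spreads) around the state's mean duration; run states follow
a no-self-transition Markov chain. The naive chain that renormalizes the
occurrence weights after excluding the current state over-represents rare
states (≈ +15% for the SZ-like state C), so the transition weights are
solved (closed form per state, fixed-point on the normalizer) such that
the chain's *stationary* run frequencies equal the configured weights.
The implied occurrence rate is then $w_s / \sum_j w_j \mu_j$.

**Forward model.** `signal(t) = √N · gfp_scale[s(t)] · a(t) ·
template[s(t)] + noise`, with `a(t) = sin(2π·16 Hz·t)`. Two coupled
choices matter here:

* the carrier is a signed in-band sinusoid (GFP envelope = rectified
  sinusoid, peaks every 31.25 ms). A rectified carrier concentrates its
  power at DC and at twice the envelope frequency; at the analysis band
  of 2–20 Hz that spectrum is almost entirely removed by the band-pass
  filter and the surviving boundary ringing produces mixture
  topographies (an equal A+B mixture is collinear with the C map),
  which measurably corrupts template and occurrence recovery. The
  signed carrier passes the filter essentially unchanged; polarity is
  irrelevant to every downstream step.
* dwell times are quantized to whole envelope half-cycles, so every
  state switch falls on a carrier zero-crossing (field amplitude 0 — no
  high-amplitude mixture frames) and every dwell contains at least one
  GFP peak by construction. Quantization uses stochastic rounding, so
  configured mean durations are preserved.

Gaussian channel noise is re-referenced (zero channel mean) before
addition, preserving the average-reference invariant of the clean
signal. Two nuisance processes make the cohort realistic rather than
trivially separable: a slow log-normal amplitude drift (unit mean,
CV 0.4, AR(1) time constant 5 s — vigilance-like; without it the mean
GFP feature is deterministic per epoch and becomes implausibly
discriminative) and per-subject log-normal jitter (CV 0.15) of each
state's mean duration and occurrence weight (between-subject
heterogeneity; this is what makes leave-one-subject-out a genuinely
harder protocol). Ground truth stores each subject's *jittered*
parameters, so parameter-recovery checks compare against what each
subject was actually generated with.

**Ground-truth templates.** Deterministic functions of electrode
position realizing the canonical gradients — A: x + 0.7y (right-frontal
/ left-posterior), B: −x + 0.7y, C: y (midline anterior–posterior), D: a
frontal-midline Gaussian bump with the C direction projected out. All
maps are average-referenced and unit-norm; pairwise |r| ≤ 0.59 on the
default montage.

**What the generator does not emulate:** volume conduction / realistic
forward head modeling, EMG/EOG artifacts, 1/f background spectra,
line noise, non-stationary switching statistics. Passing recovery tests
therefore demonstrates correctness of the analysis chain, not expected
performance on real recordings — in particular, real MsMC values (~0.6)
are far below the synthetic ones (~0.98), because real topographic
variability is much larger than the additive noise modeled here.

## Preprocessing

4th-order Butterworth band-pass 2–20 Hz applied forward-backward
(zero phase, `sosfiltfilt`); common-average reference; nonoverlapping
5-s epochs (trailing remainder dropped); epoch rejection by one pooled
scalar variance per epoch (all channels × samples), thresholded once at
mean + 3 SD of the within-subject distribution — no iterative
re-thresholding, and per subject rather than pooled because amplitude
scales differ between subjects.

## Microstate segmentation

GFP follows the spatial-RMS definition; peaks are interior samples with
`g[i−1] < g[i] ≥ g[i+1]` (first sample of a plateau gets the credit).
Spatial similarity is always polarity-invariant (absolute Pearson
correlation across channels of average-referenced maps), the standard
convention for spontaneous EEG.

Modified K-means: assignment by maximal squared correlation; update =
principal eigenvector of the outer-product sum of the member maps taken
*unnormalized*, i.e. GFP²-weighted. Under exactly this weighting both
half-steps monotonically increase GEV, so the GEV-based convergence
criterion (relative change < 10⁻⁶) and the best-of-20-restarts selection
are coherent, and the global optimum is a fixed point — which is what
makes the brute-force equivalence test on enumerable instances
meaningful. Empty clusters are re-seeded from the worst-explained peak.
Template signs are fixed deterministically (strongest channel positive).

Clustering substrate: GFP-peak maps pooled across *all* subjects of both
groups, yielding one shared template set — classification requires a
common feature space. Per-group template sets are additionally computed
for topography reporting only. GEV is computed on peaks only. Canonical
A–D labeling maximizes the summed absolute correlation to the four
canonical maps over all 24 permutations (lexicographic tie-break).
Backfitting labels each peak, and every other sample inherits its
nearest peak's label (midpoint boundary; the earlier peak keeps the
midpoint sample). No temporal smoothing or small-segment rejection is
applied.

## Features

Computed per retained 5-s epoch (the classification sample unit);
subject-level means are provided for group-table reporting. Runs
truncated by epoch edges count as runs. A state absent from an epoch
contributes 0 to its features and raises a flag in a JSON sidecar —
never NaN — keeping the table dense for classifiers. For any partition
labeling, Σ coverage = 100% and occurrence × duration / 10 = coverage
hold exactly; both are enforced by tests.

## Statistics and ranking

Univariate comparisons use the pooled-variance (Student) two-sample
t-test, t > 0 when the first (HC) group's mean is higher; the Bonferroni
family size defaults to the number of features tested and is
configurable. Chi-square ranking discretizes each feature into 10
equal-frequency bins (duplicate edges merged, so constant features score
0) and computes the Pearson chi-square (no continuity correction) of the
bin × class table; importance is −log₁₀ p (capped at 300 to stay
finite), with ties broken by statistic then name for determinism.
Equal-frequency binning makes the ranking invariant to strictly monotone
feature transforms.

Shapley explanations use the interventional value function — coalition
value = mean model score over background rows with query values
substituted on the coalition — with exact enumeration up to 12 features
(beyond that, seeded permutation sampling). Local accuracy (contributions
sum to the score's deviation from the background mean) is exact by
construction and tested to 1e-6.

## Classifier selection

Nine learner families with bounded domains (log-scaled where natural):
svm (linear/RBF/poly-2,3; C, γ ∈ 10^±3), knn (k 1–50), tree (min leaf
1–64), ensemble (random forest, 50–400 trees), linear (logistic, ridge
C), naive Bayes (Gaussian, variance smoothing 10⁻¹²–10⁻³ — scikit-learn
offers no kernel naive Bayes), net (1 hidden layer, 4–64 units, weight
decay), discriminant (LDA with shrinkage / QDA with regularization),
kernel (random Fourier features + logistic). All are wrapped with
standardization; SVMs are iteration-capped (10⁵) so pathological
hyperparameter corners return a bad objective instead of hanging.

The objective is stratified 5-fold CV misclassification on the training
split, with fixed fold seeds so configurations are compared on identical
splits. One random-forest surrogate (50 trees) is fit per learner family
on that family's evaluated points; mean and spread are taken across
trees. Candidates are drawn uniformly per family plus multi-scale local
perturbations of the family's best configuration, and scored by
closed-form expected improvement against the incumbent. Because a
bagged-tree surrogate never predicts below its lowest training target,
pure EI systematically under-exploits smooth objectives; a quarter of
the steps therefore greedily evaluate the lowest predicted mean. With
this acquisition the optimizer beats seed-matched random search on a
deterministic 1-D test objective in 10/10 seeds by 1–2 orders of
magnitude. After the budget (default 50 evaluations) the incumbent — the
lowest objective value observed — is refit on the full training split.

Protocols: subject-dependent = stratified 80/20 epoch-level split
(epochs of one subject may appear on both sides, matching the reference
design for small cohorts); leave-one-subject-out = one subject per group
held out per fold (folds = smaller group size, subjects paired in sorted
order), each fold running its own optimization (default budget 12) so no
information about held-out subjects leaks into model selection. The
positive class for sensitivity is the SZ-like group. AUC uses continuous
decision scores (predicted probability where available, signed decision
values otherwise). Incremental feature curves evaluate the top-k ranked
features for k = 1..k_max; k_max defaults to 19 with the exclusion
configurable.

## Problem sizes

The shipped benchmarks run the full pipeline at reduced recording
lengths, chosen so results are stable while the suite stays fast on one
CPU: parameter/template recovery uses 4 subjects per group × 60 s with
noise at 10% of the GFP scale; the calibrated classification cohort uses
14 + 14 subjects × 60 s (≈ 334 retained epochs), optimizer budget 24
(subject-dependent) and 8 per leave-one-subject-out fold. At these sizes
the pipeline recovers templates at |r| ≥ 0.99, per-state occurrence and
duration within a few percent, and top-6-feature accuracies around
85–95% with LOSO within a few points — the same qualitative picture as
longer recordings, with sampling noise dominating the residual spread.

## Known limitations

* The EDF reader (via `mne`) is provided but exercised only manually; no
  EDF writer is bundled, so recordings round-trip through CSV + JSON.
* The semi-Markov generator draws run states independently of run
  lengths; real microstate syntax (transition asymmetries) is not
  modeled, so transition-probability features would be meaningless here
  and are deliberately not implemented.
* Chi-square ranking p-values at extreme separations saturate at the
  float floor; the cap at −log₁₀ p = 300 preserves order only up to that
  point (ties then resolved by the statistic).
* The optimizer's surrogate treats categorical hyperparameters as
  integer codes; with the small per-family dimensionalities used here
  that is adequate, but it would not scale to rich conditional spaces.
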