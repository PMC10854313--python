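# Methods

This note documents the models, conventions, and design choices behind
`stresspop`, in the spirit of a methods appendix. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Synthetic cohorts

The generator emulates a head-fixed two-spout sucrose/water choice task
with chronic-social-defeat-stress (CSDS) groups and paired BLA/vCA1
recordings. Group sizes default to 15 control, 12 susceptible and 33
resilient mice (the 45-CSDS + 15-control design). Each mouse gets:

- **Behavioral metrics.** Sucrose preference ~ clipped Normal (control
  and resilient 0.75 ± 0.08, susceptible 0.45 ± 0.10); social
  interaction ratio ~ Normal clipped at 0 (1.1–1.2 vs. 0.5). These
  effect sizes are package choices — the real group differences are not
  quantified anywhere we can copy them — and are exposed on `GroupSpec`.
- **Choice sequence.** First-order Markov over (water, sucrose) with a
  group-specific row-stochastic matrix; the first choice comes from the
  stationary distribution (the first trial is discarded by all
  history-conditioned analyses anyway). Defaults: control
  P(W→S)=0.7/P(S→S)=0.8, resilient 0.8/0.85 (strong, history-dependent
  sucrose seeking), susceptible 0.5/0.55 (weakly structured choices).
- **Trials.** Rewards every 9 s (8 s inter-trial interval plus
  anticipation), so the ±4 s half-open analysis windows abut but never
  overlap, by construction.
- **Spiking.** A sticky Markov chain (self-transition 0.9 at the 1 s
  state resolution) over K group-specific hidden states; emission rates
  per neuron/state ~ Uniform(2, 20) spikes/s; counts are Poisson in
  50 ms sub-bins and spike times uniform within sub-bins. Control and
  resilient specs use K = 3 states, the susceptible spec K = 5 with
  25% of states reserved as *intention-only* states.
- **Intention-state planting.** On ~90% of switch trials the chain is
  overridden into a dedicated intention state for 3 of the 4 pre-reward
  1 s bins — exactly the ≥ 3-bin occupancy that the downstream ablation
  rule tests. Planted trial indices are recorded in the ground truth.
- **Reward modulation.** 40% of neurons gain ×2.5 (preferred reward) or
  ×1.2 (non-preferred) during the first post-reward second, half
  preferring sucrose and half water. This plants both reward modulation
  and a post-reward reward-choice code.
- **Interregional coupling.** Both regions' rates are multiplied by a
  log-normal gain exp(σ·g − σ²/2), σ = 0.5, where g mixes a per-region
  and a shared AR(1) signal with weight √|ρ|; ρ is the `GroupSpec`
  coupling knob (sign applied to the second region). The gain lives on
  a 50 ms grid with ~0.25 s correlation time: fast enough to create
  measurable within-1 s-window correlation at 10 ms binning (a gain
  constant within each window would be invisible to the windowed
  Pearson statistic), slow relative to the bins. The knob maps
  monotonically onto the measured correlation; the mapping is not
  calibrated to specific r values.
- **Licks.** Inhomogeneous Poisson: 0.5 Hz baseline in the 4 s before
  reward, a 3 s consummatory burst after (control 6/3 Hz for
  sucrose/water, resilient 7/2.5, susceptible 4/3.5). Anticipatory
  licking carries no group signal by default, so DI_pre is
  uninformative while DI_post separates groups.

All randomness descends from a single seed through
`numpy.random.SeedSequence.spawn`; cohort generation is a pure function
of (specs, seed), and the writer emits byte-identical TSV/JSON for
identical inputs.

**What the generator does not emulate:** refractory periods, spike
waveforms, bursting, non-Poisson count dispersion, behavioral drift
within sessions, and any continuous-time state dynamics. Passing
recovery tests therefore show that the pipeline recovers planted
structure of this statistical form, not that the real recordings contain
such structure.

## Behavioral analyses

- K-means phenotyping z-scores the two metrics first (they live on
  different scales; the choice is ours), uses 50 restarts, evaluates
  k = 2…min(10, n−1) by mean silhouette (Euclidean), and breaks ties
  toward smaller k. The cluster with the lowest mean sucrose preference
  is labeled susceptible; with k > 2 every other cluster is labeled
  resilient.
- DI = (S − W)/(S + W); undefined (NaN) when both rates are zero.
- Transition probabilities are row-normalized within each source choice;
  a source choice that never occurs leaves its row missing and flagged.
- Chance-removed proportions subtract P(X)·P(Y) with P the marginal
  choice frequency over all trials.
- Lick rasters use 20 ms bins, rate traces 100 ms bins, both half-open
  over ±4 s.

## Single-neuron statistics

Rank-sum tests use the mid-rank/normal-approximation convention with tie
correction (`scipy.stats.mannwhitneyu`, asymptotic, two-sided);
FDR control is Benjamini–Hochberg across all tested neurons; neurons
with < 10 trials per class are excluded rather than tested. The auROC
is computed by an explicit threshold sweep (trapezoid over the TPR/FPR
curve), which for count data equals the rank statistic U/(n₁n₂) with
ties counted ½ — the test suite checks this equivalence against a
brute-force pairwise oracle to 1e-12. Selectivity is two-sided:
|auROC − 0.5| must exceed 2 sd of |shuffled − 0.5|, with the shuffle sd
computed per time bin (10 shuffles by default, configurable upward);
both preference directions count as selective.

## Pseudo-population decoding

Trials are balanced over the four previous/current reward-history types;
per scheme each binary class combines equal numbers of its two
constituent types (current: {WW,SW} vs {SS,WS}; previous: {WW,WS} vs
{SW,SS}; intention: {SS,WW} vs {SW,WS}), with the common count set by
the rarest type across the selected neurons. Pseudo-trials sample each
neuron's trials independently within a history type; each neuron's draws
come from an RNG stream keyed to the neuron's identity, which makes the
assembly invariant to neuron ordering. The SVM is linear with C = 1.0
and features are z-scored on the training fold only, so accuracies are
invariant to global rate scaling. The 80/20 split is stratified by
constituent history type (the alternative — unstratified — is not
exposed; stratification keeps the class balance exact in both folds).
The two-level scheme (cell draws × trial draws, paper defaults 10 × 10,
60-neuron subsamples) reports the distribution over cell draws of the
mean over trial draws. Chance bands are 0.5 ± 2 sd of label-shuffle
accuracies, shuffled within the balanced set.

## Poisson hidden Markov models

Counts in bin t given state j are independent Poisson with means from
column j of the emission matrix; states follow a first-order chain with
transition matrix T and initial distribution A. Fitting is Baum–Welch
EM (hmmlearn's Poisson HMM as the EM core) with our initialization:
emission rates from k-means on count vectors plus Uniform(0, 0.5)
jitter, sticky transitions (diagonal 0.9), uniform initial
distribution. Five restarts per candidate K (best log-likelihood wins),
at most 100 iterations, and AIC = 2·n_params − 2·logL with
n_params = K·N + K·(K−1) + (K−1) selects the order. The desk-scale
default K range is 2–15 (configurable to the full 2–50). For
trial-concatenated fits each trial is an independent sequence, i.e. the
chain resets to the initial distribution at every trial start (the
alternative — carrying the chain across the inter-trial gap — would
assert state persistence through unmodeled time). Degenerate all-zero
inputs fit with a warning flag rather than an error.

## State clustering and intention-selective states

States are points in neuron-activity space (their emission-rate
vectors); pairwise Pearson correlation ρ gives the distance D = 1 − ρ,
and complete ("farthest-point") linkage builds the hierarchy. A
zero-variance activity vector has undefined correlations; we define its
ρ as 0 with a warning. D can exceed 1 when ρ < 0; merge heights are
reported as computed and thresholds are only probed in [0, 1]
(anti-correlated states simply never merge in that range). The cluster
count / proportion-retained curve is evaluated at thresholds 0.1–0.5
(the five group-decoder features); it is nonincreasing in the threshold
by construction.

Intention selectivity uses the Shannon entropy of a state's (or merged
cluster's) pre-reward occurrences over the two intention classes,
natural log, 0·ln 0 ≡ 0. H = 0 — exact exclusivity — defines an
intention-selective state. The analysis threshold is the one (of
0.1–0.4) yielding the most such states, ties to the smallest; if none
exists anywhere the report is empty, not an error.

### Ablation decoding

Trials containing intention-selective states in ≥ 3 of the 4 pre-reward
1 s bins are flagged. The switch/stay decoder runs on posterior-smoothed
activity Y_t = Σ_j γ_t(j)·μ_j, with modes: all trials; flagged trials
removed; an equal number of random trials removed; or only flagged
trials kept. Because the generator plants intention states in one class
only, "keep" restricts each class *that has flagged trials* to those
trials and leaves the other class intact — otherwise the binary problem
would lose a class. Per CV iteration the real trials of each class are
split 80/20 and pseudo-trials (per-neuron resampling within class) are
built separately from the two splits, so no real trial informs both
training and testing; with few real trials the alternative (one shared
pseudo-trial pool) lets the decoder memorize trial-specific noise and
inflates accuracy. Defaults follow the 100-train/20-test, 100-CV,
100-shuffle scheme; tests scale n_cv down to 30.

## Population geometry

Each neuron is z-scored over the analysis window; zero-variance neurons
are excluded before subsampling. Each of the (default 1000) subsamples
of 5 neurons contributes the cumulative explained-variance curve and the
participation ratio PR = (Σλ)²/Σλ² of its 5×5 covariance (unbiased T−1
normalizer; PR is scale-invariant either way). The pre-task analysis
window is minutes 2–8 of the pre-task epoch, 1 s bins (360 bins at full
scale). Population-vector correlation over time excludes zero-variance
bins and averages the upper triangle of the bin-by-bin correlation
matrix.

## Subject-identity decoding

The Mahalanobis-like binary decoder scales the Euclidean distance to
each training-group centroid by the **variance** (not sd — as specified;
a `use_std` flag exposes the sd variant for sensitivity analysis) of
that group's training points projected on the test-to-centroid unit
vector. A test point at a centroid has distance 0; zero projected
variance falls back to the pooled variance over both training groups
(keeps the distance finite without favoring either group); exact ties
break uniformly at random. Cross-validation balances groups by
subsampling to the smaller size and holds out one mouse per iteration
(default 1000 iterations); a `holdout_fraction` option supports a
20%-test variant for larger samples. For neural features the
spike-count mean/sd columns are min-max scaled on training mice only,
the test mouse clipped to [0, 1] (scaling on all mice would leak the
test mouse into the preprocessing). Behavioral features (DI_pre,
DI_post, sucrose preference, SI ratio; F = 4) are used raw; neural
features are the first three cumulative-variance values, the five
proportion-of-clusters thresholds, and spike-count mean/sd (F = 10).

MDS is classical (Torgerson): double-center the squared Euclidean
distance matrix and eigendecompose; per-group variance normalization is
applied first when group labels are given. Orientation is
unconstrained.

## Interregional correlation

Region-mean rates at 10 ms bins, Pearson r per 1 s window (100 samples),
windows tiling the ±4 s trial. Zero-variance windows are skipped and
counted. The per-mouse summary averages windows within trials and then
across trials of a type (the reverse order is exposed as an option;
the two differ only when windows are dropped), and
Δ = corr_sucrose − corr_water.

## Problem sizes used in the test suite

The packaged tests run the full pipeline at reduced scale — cohorts of
1–9 mice, 6–12 neurons per region, 50–80 trials, 60–120 s pre-task
epochs, HMM K ranges of 2–8, decoding with 2–3 cell/trial draws and
20–100 shuffles, 20-run recovery sweeps — sizes chosen so each analysis
retains enough data for its statistical guarantees while the whole
suite stays quick. Full-scale defaults (60 mice, K up to 50, 1000
subsamples/CVs) remain the package defaults for real use.

## Known limitations

- AIC tends to select more states than planted when the data contain
  unmodeled rate modulation (the slow gain, reward gains); this is
  expected model-mismatch behavior, and order recovery is guaranteed
  only for data generated exactly from a Poisson HMM with
  well-separated states.
- The strict H = 0 criterion is sensitive to single misassigned bins;
  with few neurons (< ~10) Viterbi misassignments can hide planted
  intention states.
- The Mahalanobis decoder's variance scaling is unstable for very small
  training groups (< ~8 mice after balancing); this is a property of
  the specified statistic, not of the implementation.
- Shuffle chance bands use one accuracy per shuffle, so they are wide
  when test sets are small; they mirror the specified procedure rather
  than a minimum-variance chance estimate.
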