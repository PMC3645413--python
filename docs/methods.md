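# Methods

## The approach

tscompass treats a time-series analysis *method* as an **operation**: a pure
function that reduces a univariate, uniformly sampled series **x** to a
single real number. Applying a library of operations F_j to a collection of
series x_i yields the data matrix D_ij = F_j(x_i). Rows (series) are then
empirical fingerprints of dynamics, and columns (operations) are empirical
fingerprints of methods, and both can be organized, clustered, reduced and
selected by their behaviour on data rather than by the literature they come
from.

The package implements the full loop: a catalogue of ~96 registered
operations across nine families (distribution, correlation, spectral,
stationarity, information, scaling, model fit, symbolic, and
perturbation/simulation-based "novel" operations), matrix assembly with
special-value handling, outlier-robust normalization, mask-aware distances,
PAM k-medoids and complete-linkage clustering, reduced operation sets
scored by residual variance, nearest-neighbour networks, PCA structuring,
and statistically controlled supervised selection (threshold-classifier
cross-validation, forward selection with a Fisher discriminant, pooled
permutation FDR).

## Operation contract and special values

An operation either returns a finite real or a `SpecialValue` with a reason
(`nan`, `inf`, `error`, `inapplicable`, `constant_input`, `too_short`).
Exceptions raised on data-dependent failures are caught and mapped to
`error`; special values become masked matrix cells and are never coerced to
numbers. Columns with a masked fraction not strictly below 20% are dropped
before analysis (the boundary is read strictly: a column exactly at the
threshold goes).

Constancy is detected with an exact range test (`ptp(x) == 0`) rather than
`sd == 0`: floating-point pairwise summation gives a constant array an sd
of order 1e-16, which would silently defeat every `sd == 0` guard.

Series are stored raw. Operations that need normalized input (e.g. the
AR(3) fit, GP segments) z-score internally; distribution-family operations
see original units. Each operation carries an honest `scale_sensitive`
flag: every operation flagged insensitive is checked by the test suite to
agree to 1e-9 between x and 3x + 7.

## Key definitions and conventions

- **ApEn(m, r)** includes self-matches; **SampEn(m, r)** excludes them and
  uses the N − m templates that have an (m+1)-length extension for both
  template lengths. r is a fraction of the *sample* sd; template distance
  is Chebyshev. Both are verified against O(N²) brute-force counting
  oracles to 1e-12.
- **Autocorrelation** uses the biased (1/N) normalization, which keeps
  |ρ| ≤ 1 and the ACF positive semi-definite. Consequence: an exactly
  periodic series has ρ(period) = (N − lag)/N, not 1.
- **Lempel–Ziv** complexity: LZ76 exhaustive-history phrase count of the
  median-binarized sequence, normalized by N/log2(N).
- **Auto-mutual information**: plug-in estimate with equiprobable *rank*
  binning (exactly equal counts when N divides by the bin count); a tie
  straddling a bin boundary marks the binning degenerate.
- **DFA**: profile = cumulative sum of the mean-removed series; ~20 window
  sizes log-spaced on [10, N/4]; least-squares linear detrend per
  non-overlapping window; exponent = slope of ln F(n) vs ln n. For a
  spectrum S(f) ∝ f^−α the expected exponent is (α + 1)/2.
- **Spectral slope**: least-squares fit of log-periodogram vs log-frequency
  over the central frequency decade, excluding DC and the top 10% of
  frequencies. The multiplicative periodogram noise adds a constant offset
  in log space, so the slope needs no smoothing to be unbiased.
- **Symbolic words**: increments are tercile-coded (A/B/C) by rank, making
  letters a-priori equiprobable; word probabilities count overlapping
  windows.
- **Outlier-adjusted AC ratio**: lag-3 autocorrelation before/after
  deleting the ⌈0.1N⌉ points of largest |x − mean| and closing the gaps.
- **Inertial particle**: a damped unit mass pulled toward the signal,
  v_{t+1} = γ v_t + κ(x_t − p_t), p_{t+1} = p_t + v_{t+1}, with κ = 0.1,
  γ = 0.9, p_0 = x_0, v_0 = 0; summaries (residual sd, residual lag-1
  autocorrelation, mean speed) are taken after an N/10 burn-in. The
  dynamics and defaults are this package's concretization of the idea of
  probing a series through a simulated follower.
- **GP length scale**: non-overlapping z-scored segments of 50 samples;
  exact marginal likelihood of a squared-exponential kernel maximized over
  a fixed grid (30 log-spaced length scales on [0.1, 50] samples, 12
  log-spaced noise-to-signal ratios, signal variance profiled
  analytically). Grid search keeps the feature deterministic. Among
  numerically tied grid points the smallest length scale wins (sub-sample
  length scales produce identical kernels, and an exact argmax would
  otherwise flip on rounding noise). Note that on pure noise the exact
  marginal likelihood still picks a large length scale in roughly half the
  50-sample segments — chance low-frequency structure is worth up to ~0.7
  nats — so the white-noise output sits in the lower part of the grid
  rather than pinned at its bottom; the tested properties are the ones
  that are stable (noise below the grid midpoint, smooth input strictly
  above noise).

## Normalization

Each column is mapped through the outlier-robust sigmoid
1/(1 + exp(−(x − med)/(1.35·IQR))) (1.349·IQR equals one sd for a normal
distribution) and then linearly rescaled so the observed values span
[0, 1]. The transform is exactly invariant under positive affine maps of a
column, monotone, and bounded against arbitrarily large outliers (a single
extreme value moves other entries only through its bounded effect on
median/IQR and the rescale extremes). Zero-IQR columns fall back to rank
scaling (all-equal columns map to 0.5); fallbacks are logged.

## Distances, clustering, reduced sets

Series are compared by mask-aware Euclidean distance on normalized rows,
rescaled by P/|S| for the shared unmasked column set S so that pairs with
different coverage stay comparable; pairs sharing fewer than half the
columns are flagged unreliable. Operations are compared by 1 − |r|
(sign-blind: redundancy is about predictability, not direction; the signed
r matrix is retained for display) or by 1 − NMI with equiprobable binning
for nonlinear redundancy.

k-medoids is PAM (greedy BUILD + steepest-descent SWAP with vectorized
swap deltas), best of 20 seeded restarts; it matches exhaustive search on
every random instance with n ≤ 8, k ≤ 3 in the test sweep. Near-constant
operations whose correlation to everything is undefined are excluded
greedily (most undefined pairs first) before clustering. A reduced set's
quality is the residual variance 1 − R², where R correlates the pairwise
series distances computed from the reduced columns with those from all
columns.

## Supervised selection

The single-feature classifier is an optimal-threshold stump: the threshold
scans midpoints of consecutive distinct training values (plus one
candidate beyond each end); accuracy ties break toward the widest margin,
then the smallest threshold. Scores are means over 10 repeats of
stratified 10-fold cross-validation (fold assignment is a pure function of
seed and labels; the fold count is clamped, with a log message, when a
class is smaller than the fold count). Multi-class tasks are one-vs-rest
with macro-averaged error — a deliberate consequence is that a "middle"
class is not isolable by one threshold, so its one-vs-rest error is
bounded away from zero.

Forward selection greedily adds the feature minimizing the joint CV error;
a single feature uses the stump (so a one-feature selection reproduces the
single-operation ranking exactly), two or more use a Fisher linear
discriminant (scikit-learn's LDA). Masked cells are mean-filled for the
joint model, and the selection path error is non-increasing by
construction of the stopping rule (stop when improvement ≤ tol).

Permutation control pools null scores across all operations and
permutations: p = (1 + #{null strictly better})/(1 + n_perm·n_ops),
followed by Benjamini–Hochberg q-values. Null classification scores use a
single CV round per permutation; the observed scores (10 repeats) are less
variable than the null draws, which makes the procedure mildly
conservative under the global null — the test suite confirms the measured
false-positive fraction stays at or below the nominal 5%.

## Synthetic generators and what they do / do not cover

All generators are pure functions of their parameters and seed. The
library covers: four one-parameter iterative maps (logistic, sine, cubic
x → Ax(1 − x²), asymmetric logistic x → Ax(1 − x)²); a stochastic sine map
x → A sin x + η with occasional uniform kicks (A = 2.2 places two
symmetric attracting sets, so rare kicks produce noisy switching);
Euler–Maruyama SDE paths (geometric Brownian motion dX = aX dt + bX dW and
an affine form); white/AR(1)/noisy-sine noise; and self-affine series with
S(f) ∝ f^−α by Fourier filtering (any α) or random midpoint displacement
(α ∈ (1, 3), H = (α − 1)/2).

The benchmark collections fix the study conditions used by the tests and
the reproduction script: 50 + 50 white-noise vs noisy-sine series of 1000
samples for classification; 40 Fourier-filtered series of 5000 samples
with α uniform on [−1, 3] for regression; and a 48-series mixed collection
(noise, AR(1), sinusoids, chaotic maps, GBM, self-affine; 1000 samples)
for redundancy analysis. These sizes keep the full pipeline at
desk scale; they exercise every algorithm end to end but are far smaller
than a real interdisciplinary corpus, so passing tests demonstrate
correctness and qualitative behaviour (which operation families win which
task, how redundancy collapses), not the numerical constants one would
obtain from thousands of real recordings. Real data also bring artefacts
none of the generators emulate: missing samples, trends and
nonstationarity beyond simple drift, measurement quantization, and heavy
non-Gaussian tails.

## Numerical choices and degenerate inputs

- Tie-breaks are deterministic everywhere: lexicographic ids for neighbour
  ordering and medoid reporting, stable sorts for outlier removal and rank
  binning, smallest-threshold/widest-margin for the stump, smallest grid
  point for tied GP likelihoods.
- PCA fills masked cells with the column's unmasked mean (fraction logged)
  and fixes each component's sign by making its largest-magnitude loading
  positive.
- HDF5 outputs are written with `track_times=False` so repeated runs are
  byte-identical; the CLI fans a single `--seed` out to per-component
  seeds by stable hashing, and `tscompass rerun` reproduces any run from
  its emitted `config.json` bit-exactly.
- Constant inputs, too-short inputs, degenerate binnings and zero-variance
  denominators all produce typed special values rather than exceptions.

## Known limitations

- The catalogue is a representative library (~96 operations), not an
  exhaustive one; families such as surrogate-data tests, GARCH/state-space
  fits, correlation dimension, Lyapunov exponents and
  series-to-network transforms are intentionally out of scope.
- The GP length-scale feature is a grid-searched summary, not a tuned
  model fit; its resolution is the 30-point grid.
- Only univariate, uniformly sampled series are supported; no imputation
  of masked cells beyond the documented mean-fill for PCA/LDA.
- The permutation null pools across operations; per-operation nulls would
  be more exact for heterogeneous score distributions but need far more
  permutations for usable tail resolution.
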