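# Methods

`fasdiet` implements a complete fatty-acid-signature (FA) diet-inference
pipeline for a generalist semi-aquatic predator (the nearctic river otter)
and its candidate prey — fishes, molluscs, frogs and crayfish — together
with a synthetic-study generator that reproduces the statistical structure
of the published group-level data, so that every stage can be validated
against known ground truth.

## Compositional signatures

An FA signature is a composition: the vector of proportional masses of each
FA bin, non-negative and summing to one (closure). Signatures are stored as
fractions; all I/O and reports use percent by mass, the convention of
GC-FID FA tables. The packaged reference table contains nine group columns
(otter tail and footpad adipose, crayfish, frog, mollusc, and four fish
orders) with mean ± sd for 29 identified FA bins. Identified bins sum to
89.0–98.5% per column; the remainder (31 unidentified chromatographic bins
in the original 60-bin scheme) is pooled into a single `other` bin at load
time so each column is a closed composition. The `other` bin has no
reported dispersion; its sd is assigned as its mean times the median
coefficient of variation of the column's positive identified bins — a
modeling choice, recorded in the fixture metadata.

**Zero replacement.** Log-ratio distances require strictly positive parts.
Zeros are replaced by flooring at `eps = 1e-5` and re-closing; `eps` is two
orders of magnitude below the 0.1% resolution of the printed tables, so the
replacement is far below measurement resolution while keeping all log terms
finite.

**Predominant-FA statistic.** The share of total FA contributed by the four
predominant acids (16:0, 16:1, 18:0, 18:1) is computed as the sample-size-
weighted grand mean of the within-group sums of group means — algebraically
the all-samples mean when groups partition the samples. On the packaged
table with n = (46, 19, 14, 12, 37, 6, 15, 43, 26) it evaluates to 55.98%.

## Peak binning by restarted 1-D k-means

GC retention times drift between runs, so unidentified peaks must be binned
across samples before their areas can be treated as variables. Peaks
matched to standards are pinned to their labels; the remaining retention
times are pooled over all samples and clustered into K = 60 bins by Lloyd's
k-means on the retention-time axis. Initial centroids are drawn uniformly
on the observed retention-time range; the procedure is restarted (default
1000 times) and the run maximizing variance explained, SS_between/SS_total,
is kept. Numerical choices:

- assignment uses the sorted-centroid interval structure of 1-D k-means;
  midpoint ties go to the lower-retention-time centroid (determinism);
- a cluster that loses all members is re-seeded at the point farthest from
  its nearest centroid, keeping K fixed — this repair is what makes random
  uniform initialization effective at K = 60 (in our separated-bin test
  regime ~90% of single restarts already reach a near-optimal partition);
- if all values coincide, SS_total = 0 and variance explained is defined as
  1 (the clustering is vacuous, not failed);
- one master seed spawns independent per-restart streams
  (`numpy.random.SeedSequence.spawn`), so the first n restarts coincide for
  any two calls sharing a seed and best-of-n variance explained is
  non-decreasing in n.

The exactness oracle used in tests is exhaustive enumeration over
contiguous partitions (the optimal 1-D k-means partition is contiguous in
sorted order).

## Ordination and group tests

Each FA bin's proportion is one variable. PCA defaults to the correlation
matrix (variables centred and scaled, n−1 denominator), matching the
default of the common reference implementations — the choice between
scaled and unscaled proportions is an assumption, and covariance PCA is
available by flag. Constant bins are dropped with a notice before scaling.
Component signs are fixed so the largest-|loading| FA loads positively.
Because closure makes compositional data rank-deficient, the last
eigenvalue is numerically zero; correlations of FA with such null score
columns are noise and are reported as 0.

Group structure on each of the first 5 components (higher components are
not tested by default) is assessed by one-way ANOVA with Tukey's Honest
Significant Differences for all pairwise comparisons, using the
Tukey–Kramer statistic q = |m_a − m_b| / sqrt(MSW/2 · (1/n_a + 1/n_b)) and
the studentized-range distribution from scipy, whose survival function
agrees with the two-group pooled-t closed form to ~1e-13. Adjusted
p-values are floored at 1e-16 (tail accuracy). Singleton groups are
allowed; they contribute no residual degrees of freedom.

## QFASA diet estimation

The predator signature y is modelled as a convex mixture ŷ(p) = closure(p ·
(c ⊙ M)) of prey-taxon mean signatures M, with per-FA calibration
coefficients c for predator metabolism (identity by default — predator FA
metabolism is unknown for this system, and the basis accepts a
user-supplied vector). The diet estimate minimizes the symmetrized
Kullback-Leibler distance

    d(y, ŷ) = Σ_k (y_k − ŷ_k) · ln(y_k / ŷ_k)

over the simplex. The distance is non-negative, symmetric, zero only at
equality, and up-weights discrepancies in rare FA, which carry most of the
taxon-specific signal. A one-sided KL option exists for sensitivity
analysis. The prey basis is built at the taxon-group level (four groups) by
default; only tail-deposit predator samples enter estimation (the footpad
deposit is cold-adapted and a biased diet indicator).

**Optimization.** With identity calibration the mixture is linear in p and
the objective is convex on the simplex (its Hessian in ŷ is diag(1/ŷ +
y/ŷ²) ≻ 0), so any converged point is the global minimum. The solver is
SLSQP with the analytic gradient, bounds [0, 1], the equality constraint
Σp = 1, and objective tolerance 1e-12, started from the barycenter plus 10
Dirichlet(1) random restarts (restarts guard the non-convex calibrated
case). Tests verify the optimum against dense simplex grid searches (step
1e-3 and 1e-4).

**Bootstrap.** Uncertainty is assessed by resampling predators with
replacement and prey individuals with replacement within each taxon
(either alone, by flag), rebuilding the taxon-mean basis per replicate,
and fitting; reported proportions are the replicate mean, the SE the
replicate standard deviation (default 500 replicates).

**Fitting the mean signature, not individuals.** Within each bootstrap
replicate the default fits the mean signature of the resampled predators
(`fit="mean"`); fitting every predator individually and averaging the
diets (`fit="individual"`) is available. The default was chosen after a
bias decomposition on synthetic studies at realistic noise (predator
per-FA sd matched to the observed otter-tail column): the per-individual
KL fit is a nonlinear function of the noisy signature, and averaging the
fits inflates rare diet components — a true 3.0% crayfish share was
recovered at ~9% (per-taxon mean absolute error up to 0.07), while the
mean-signature fit recovered all taxa within 0.003. Averaging first
removes the individual-level noise before the nonlinearity. The cost is
that between-individual diet heterogeneity is averaged away; for a
population-level diet composition, which is what the bootstrap reports,
the mean-signature fit is the lower-bias estimator.

## Synthetic-study generator

The generator defines the conditions under which the pipeline is validated.

**Individuals.** Per-taxon signatures are drawn from a logistic-normal
scheme: each bin with positive mean and sd gets an independent lognormal
draw, and the active bins are closed to 100 minus the constant-bin total.
Closure distorts moments, so the underlying lognormal parameters are
calibrated by a fixed-point iteration (four rounds against a 40,000-draw
fixed-seed Monte Carlo sample, cached per taxon) until the post-closure
means and sds match the printed targets. Simulated group means land within
3·sd/√n of the targets; sds of well-conditioned bins (CV ≤ 1) within 15%
(bins with CV > 3, e.g. mollusc 10:0 at 0.4 ± 1.47, are heavy-tailed and
their sample sd is intrinsically noisy). Bins with zero sd — and bins with
printed mean 0.0, whose true mean is below the 0.05 rounding resolution —
are held constant at the printed mean rather than simulated; downstream
zero replacement handles them where positivity is required.

**Predators.** Each predator resamples every prey taxon with replacement
at its observed size, mixes the resampled taxon means at the true diet
vector, multiplies each bin by mean-preserving lognormal noise
exp(σ_k Z − σ_k²/2) and re-closes. σ_k is CV-matched at the mixture mean to
a percent-scale sd template (the otter-tail column by default, CV capped at
3), times a global `noise_scale`; `noise_scale=0` yields exact mixtures.
Simulated predator per-bin sds reproduce the otter-tail sds within
0.87–1.24×. The default true diet for reference-scale studies is (fish 0.377,
mollusc 0.320, frog 0.273, crayfish 0.030).

**Peak tables.** K true retention-time centers a fixed spacing apart; each
sample gets one peak per center with Gaussian jitter and Dirichlet-random
areas, with the true center index returned as truth. Jitter sd =
spacing/50 is the well-separated regime; jitter ≈ spacing produces heavy
overlap where recovery must degrade.

**What the generator does not emulate.** Real signatures have correlated
bins (shared metabolic pathways), seasonal and geographic drift,
species-level heterogeneity within taxon groups beyond the four fish
orders, and predator FA metabolism (calibration ≠ 1). Passing recovery
tests therefore demonstrate correctness of the estimator under the model's
own assumptions — mixtures plus independent-per-bin logistic-normal noise —
not robustness to metabolic distortion, which no analysis can supply
without calibration data.

## Problem sizes and reproducibility

Reference-scale synthetic studies use 46 predators and prey at the reference
sample sizes (crayfish 14, frog 12, mollusc 37, fish 90), 500 bootstrap
replicates; recovery properties are evaluated over 20 replicate studies,
ordination separation over 100 replicates, and peak-binning recovery over
5 seeds at 10 samples × 60 bins with 1000 restarts. All randomness flows
from a single master seed through `SeedSequence` spawning; identical
(config, seed) reproduce outputs bit-for-bit.

The fixture metadata records one internal inconsistency of the source
tables: the per-species fish counts sum to 90 across 15 species, while the
figure caption mentions 14 fish species totalling 56. The packaged table
uses the per-species counts.

## Known limitations

- Calibration coefficients default to identity; estimated diets are
  therefore proportional-representation estimates, not
  metabolism-corrected ones, and should be read as upper/lower bounds in
  the sense discussed above.
- The `other` bin aggregates 31 unidentified FA; its dispersion is a
  modeling choice and taxon separation driven by unidentified FA is not
  represented.
- The printed explained-variance percentages of the original ordinations
  (14.9%, 12.9%, …) depend on the undeposited per-individual data and are
  intentionally not reproduction targets; the ordination is validated by
  its separation properties instead.
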