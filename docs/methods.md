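# Methods

`localpls` implements a family of calibration strategies for predicting
scalar phenotypes (milk technological traits: rennet coagulation time RCT,
curd-firming time k20, curd firmness a30/a60, casein micelle size CMS, pH)
from mid-infrared absorbance spectra, together with the data editing,
benchmarking and simulation machinery needed to compare them.  This note
records the model, the conventions fixed where the design was open, and the
known limits of what the synthetic experiments show.

## The calibration strategies

All three strategies predict each sample ("predictand") out-of-sample: the
model that predicts a sample never sees that sample's trait value.

**Global PLSR.**  For each predictand, a single-response PLS regression is
fitted on all remaining samples; the number of latent factors (1..20 by
default) is chosen by leave-one-out cross-validation within those samples,
ties broken toward fewer factors.  This is the benchmark every local
strategy must beat.

**LOCAL (fixed neighbours).**  Candidates are ranked by the Pearson
correlation between the predictand's absorbance vector and theirs; the top
k (k in {25, 50, 100}) form the training set and a fixed factor count
(5, 10 or 20) is used without cross-validation — the classical
Shenk–Westerhaus design, with the neighbour count chosen a priori and
shared by all predictands.

**Local changepoint.**  The similarity geometry is the space of the first
4 principal components of the (optionally per-wavelength standardised)
absorbance matrix.  Because PC scores are uncorrelated, the Mahalanobis
distance between two samples reduces to the eigenvalue-weighted Euclidean
distance of their scores.  For a predictand, the distances to all
candidates are sorted in increasing order and PELT is run on that vector as
a change-in-mean problem: the first changepoint selecting at least 20
neighbours (so the inner factor cross-validation has material to work with)
sets the neighbour count.  The factor count is then chosen by leave-one-out
cross-validation within the neighbour set, capped at
`min(20, n_neighbours - 2)`.  When no changepoint at or beyond the minimum
exists, the selection falls back to *all* candidates — a flat distance
profile means no local structure, and the global benchmark is the natural
default (logged, and recorded as rule `"all"`).

## Changepoint conventions

The mean-change cost of a segment is its sum of squares about the segment
mean divided by a common noise variance `sigma2`.  Penalty constants are
`beta = 2 log n` for SIC (one mean plus one location parameter per
changepoint) and `beta = 3 log n` plus an additive `log(segment length)`
cost term per segment for MBIC (after Zhang & Siegmund).  `sigma2` defaults
to the first-difference estimator `Var(diff(y))/2`, which is robust to mean
shifts and makes the segmentation invariant to the overall scale of the
distances (the raw Mahalanobis distances differ in scale across
standardisation settings); `fixed_one` (the common known-variance
convention) and a global MLE are also provided.  The segment cost is
non-decreasing under extension for both penalties, so PELT's pruning is
lossless; the tests verify exact agreement with an unpruned O(n^2) dynamic
programme across penalties and variance modes.  Dynamic-programme ties are
broken toward the smaller changepoint index, and the minimum segment length
is 2 so segment means stay well-defined with the MBIC log-length term.
AMOC (at most one change) uses the same penalty in a likelihood-ratio
comparison against the no-change model; it is provided for completeness but
PELT is the default detector.

## PLS conventions

The regression core is single-response PLS in its kernel form: all
quantities are computed from the centred cross-products `X'X` and `X'y`,
with only the cross-covariance deflated per component.  This is
algebraically identical to orthogonal-scores NIPALS (verified against an
independent implementation to machine precision) and makes leave-one-out
exact and cheap: removing a sample is a rank-one downdate of the moments,
so all folds run as one batched recursion.  Predictors are centred but
never scaled inside the regression — standardisation, where requested,
belongs to the neighbour-selection geometry only.  With as many factors as
the rank of the centred predictors, the fit equals the least-squares
solution; requesting more factors than the rank is an error.  The global
benchmark additionally exploits that the inner-CV fit excluding samples
{i, j} serves predictand j at fold i and predictand i at fold j, halving
the quadratic fit count.

## Data editing

The editing pipeline runs in a fixed order: (1) animal de-duplication —
for each animal with several records, keep the record with the greatest
Mahalanobis distance from the centre of the dataset-wide PC space
(standardised, 4 components by default), maximising retained variability;
(2) removal of high-noise wavenumber windows (1580–1710 and 2990–3690
cm^-1 as closed intervals, plus everything above 3822 cm^-1), leaving the
informative bands; (3) transmittance→absorbance, `A = log10(1/T)`, when
the input is transmittance; (4) single-pass per-trait outlier removal
(>3 SD from the trait mean, moments computed once on pre-filter values)
followed by restriction to samples with complete traits.  Whether the
de-duplication PC space should be standardised is not determined by any
constraint we know of; standardised is the default and a flag exposes the
alternative.  The pipeline is idempotent on its own output.

## Synthetic data

The generator follows the Beer–Lambert premise that makes PLSR sensible in
the first place: latent component concentrations (log-normal, `sigma_log =
0.3`) mix linearly through smooth absorbance profiles (sums of 3 Gaussian
peaks per component, plus a broad base response), with a smooth quadratic
per-sample baseline and i.i.d. spectral noise (SD 0.002 absorbance).
Traits are linear (optionally cluster-specific, optionally quadratic)
functions of the concentrations plus noise, affinely rescaled to realistic
trait moments (e.g. RCT mean 17.24 min, SD 6.61 min; pH mean 6.66, SD
0.09).  Default noise-to-signal ratios per trait are chosen so attainable
prediction correlations span the weak-to-strong range typical of these
traits (CMS hardest, pH easiest).

Ground-truth knobs for testing the editing pipeline: a configured fraction
of samples is duplicated under shared animal ids (concentrations perturbed
by ~5%), and a configured fraction of trait values is replaced by outliers
at 4.5–5.5 target SDs.  When outliers are injected, natural standardised
trait values are clipped at ±2.8 SD before rescaling — measured
technological traits are range-bounded, and this makes the ">3 SD" rule
identify exactly the injected set.  Injected outliers and duplicates are
drawn from disjoint sample sets so both ground truths stay identifiable.

**Cluster regimes.**  `cluster_separation` shifts cluster concentration
means additively, measured in within-cluster concentration SDs (additive
shifts keep every cluster's covariance identical; log-mean shifts would
confound separation with scale).  `heterogeneous_config()` builds the
canonical two-cluster condition in which locality genuinely helps: one
trait's loading row is sign-flipped in the second cluster, and the
offsets place both clusters on that trait's zero iso-surface, separated
along a direction orthogonal to the loading row.  Cluster trait means and
within-cluster covariances then match exactly, so a pooled linear
calibration provably carries no information about the within-cluster
spectra–trait relationship, while same-cluster neighbours see a clean
linear signal.  This is the sharpest linear-model analogue of the
heterogeneous (multi-material) datasets where local calibration is
reported to shine.

**Planted neighbour fixture.**  A tight core (spread 0.05% of the
separation) at the centre of a diffuse background annulus (radii jittered
20%, truncated at half the separation) in a latent 4-space, mapped through
rank-4 smooth profiles.  The core spread is far below the detector's
resolution — the difference-based `sigma2` is set by the core/background
gap itself, and the least-variance principal component shrinks core
differences least — so "the other core members" is a well-defined ideal
neighbour set.  The broad base response in the profiles matters here:
per-wavelength standardisation amplifies any signal-free wavelength to
unit variance, and without a base response that amplified noise would
masquerade as within-core structure.

One property of the Mahalanobis-on-PCs geometry is worth stating plainly:
whitening caps the between-cluster gap of two balanced clusters at about 2
units (the separation direction's eigenvalue absorbs the separation) while
normalising within-cluster spread to ~1 per component.  Perfectly pure
neighbour sets are therefore unattainable for balanced clusters —
selections pick up a few percent cross-cluster neighbours regardless of
the nominal separation — whereas a small tight core inside a dominant
background (the planted fixture) separates cleanly.  Benchmarks on the
clustered regime rely on the RMSEV comparison, not on perfect purity.

## Evaluation

RMSEV is the root mean square error over the leave-one-out predictions and
r the Pearson correlation between true and predicted values; residual
tables are emitted for diagnostic plots.  "Edge" subsets are the samples
with the greatest Mahalanobis distance from the centre of the global
standardised 4-component PC space — always that space, regardless of the
setting being evaluated — at 5% and 10% fractions; subset sizes round half
away from zero (5% of 348 → 17).  The default benchmark grid is 14
settings per trait: 1 global + 9 LOCAL (k × factors) + 4 changepoint
(penalty × standardisation).  Everything is deterministic given the
dataset and configuration.

## Problem sizes

The benchmark-style tests and the acceptance script run at 40–100
wavelengths rather than the 531 of a full instrument grid, with 250–300
samples, 10 seeds for the qualitative comparisons and 100 seeds for
neighbour recovery.  The wavelength count only scales the linear algebra
— all selection geometry is 4-dimensional after projection — and 40+
channels already leave the rank-8 latent structure heavily
over-determined, so these sizes preserve every property being measured
while keeping a full run in minutes on one core.

## Limitations

* The synthetic spectra are linear mixtures with Gaussian peaks; real
  mid-infrared instruments add water-absorption physics, detector noise
  signatures and wavelength-dependent error that the generator does not
  emulate.  Passing benchmarks show the *relative* behaviour of the
  strategies under the model's own assumptions, not instrument-level
  accuracy.
* The changepoint penalty constants are a documented convention; published
  applications rarely print theirs, and different constants shift neighbour
  counts (MBIC is gentler than SIC at equal `log n` multiples only because
  of the log-length term).
* Leave-one-out factor selection inside leave-one-out validation is
  O(n^2) fits per trait even with moment downdating; for datasets beyond a
  few thousand samples k-fold inner validation would be the practical
  choice.
* With `pc_fit_scope="full_dataset"` (the default, matching the single
  global PC geometry) the predictand's spectrum — never its trait value —
  participates in the PC fit; `exclude_predictand` refits the space per
  predictand for strictly leakage-free geometry at extra cost.
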