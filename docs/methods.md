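# Methods

## Model

`hybridgp` predicts a quantitative trait (grain yield, kg/ha) for
recombinant inbred lines (RILs) of a nested association mapping (NAM)
population from two information sources: genome-wide SNP markers and
daily canopy-coverage values derived from field images.

The base model is single-kernel GBLUP,

    y_i = mu + u_i + e_i,     u ~ N(0, G sigma_u^2),  e ~ N(0, I sigma_e^2),

where G is an n x n similarity ("relationship") matrix among lines.  Two
base kernels are built from column-standardized feature matrices
(centering to 0, scaling to unit sample variance with the n-1 divisor —
the convention every derived test value in this package uses; the
divisor is configurable):

    G_X = X X' / p   (X: n x p standardized minor-allele counts)
    G_C = C C' / q   (C: n x q standardized daily canopy values, q = 42)

and blended element-wise into the hybrid matrix

    G_F = (1 - w) G_X + w G_C,   0 <= w <= 1,

a convex combination of PSD matrices, hence PSD.  w = 0 is marker-only
GBLUP; w = 1 is canopy-only ("phenomic") prediction.  The default weight
grid is the 11 values {0, 0.1, ..., 1}.

## Canopy expansion

Canopy coverage is observed weekly (6 time points, 2-8 weeks after
planting) as the proportion of plot area covered, in [0, 1].  Each
line's trajectory is modeled as a logistic growth curve via the logit
link with fixed asymptotes 0 and 1:

    logit(coverage(t)) = a + b t,

fitted by ordinary least squares on the logit scale after clipping
observations into [eps, 1-eps] with eps = 1e-3 (the link diverges at the
boundaries).  A two-parameter form is used deliberately: coverage is a
proportion with natural asymptotes, and six observations cannot support
estimating asymptotes as free parameters stably.  The fitted curve is
evaluated on the daily grid t = 14, ..., 55 (42 values, configurable),
matching the 6-weeks-of-7-days expansion.  Noise-free logistic data are
recovered to 1e-8, and the OLS slope is unbiased under logit-scale noise
(both are tested).

## Variance components and prediction

REML estimation profiles the restricted likelihood over the variance
ratio delta = sigma_e^2 / sigma_u^2 after one spectral decomposition
G = U D U'.  In the rotated basis the model is heteroscedastic-diagonal,
so the generalized-least-squares mean and the profiled sigma_u^2 are
closed-form at each delta and every candidate ratio costs O(n).  The
scalar optimizer (bounded Brent) searches log delta in [-10, 10]; an
optimum pinned at either bound is flagged (`at_boundary`).  A constant
response short-circuits to mu = y, sigma_u^2 = 0 (sigma_e^2 is floored
at 1e-12 to keep downstream ratios defined).  A diagonal jitter of
1e-8 x mean(diag K) is added inside linear solves only — never to stored
kernels.

Held-out lines are predicted from kernel cross-covariances,

    y_hat = mu + K_ts (K_tt + delta I)^(-1) (y_t - mu 1),

which equals the Henderson mixed-model-equation solution; tests verify
this against an independent dense MME oracle.  When sigma_u^2 is
estimated at (numerically) zero, predictions fall back to mu.

Leave-one-observation-out (LOO) CV has two modes:

* `fixed_vc` (default): variance components and mu are estimated once on
  the cluster, then each line's held-out prediction uses the exact LOO
  identity for kernel-ridge smoothers, `pred_i = y_i - alpha_i /
  (A^-1)_ii` with `A = K + delta I`, `alpha = A^(-1)(y - mu)` — one
  matrix inversion for all n folds, identical (to 1e-8, tested) to
  deleting each line and re-solving with those components fixed.
* `refit_vc`: the literal definition; a full REML refit per fold.  Used
  by the oracle tests and practical for small clusters.

For populations in the low hundreds the two modes give nearly identical
predictions; `fixed_vc` makes the 99-strategy grid run in seconds.

## Cross-validation design

Lines are clustered on the Euclidean distance over the column-wise
concatenation of the standardized marker and canopy blocks.  No block
rescaling is applied by default, so with p >> q markers dominate the
distance; that mirrors clustering on "the combined information" as
plainly described, and the feature matrix is exposed so callers can
reweight blocks if desired.

* **CLARA** (sampling k-medoids): `n_samples = 5` subsamples of size
  `40 + 2k` (the classic defaults); PAM (greedy BUILD + steepest SWAP,
  ties to the lowest index) finds k medoids on each subsample; all lines
  are assigned to the nearest medoid; the medoid set minimizing the
  total distance of all lines wins.  Bit-reproducible given its seed.
  PAM/CLARA are implemented in-package and verified against exhaustive
  k-medoids enumeration on small instances.
* **HL (Ward)**: agglomerative clustering with the Ward
  minimum-variance criterion (scipy's `linkage`/`fcluster`),
  deterministic.

For each clustering (method, k in {2,3,4,5}) — computed once and reused
across all weights — LOO prediction runs independently inside each
cluster and the per-cluster predictions are concatenated into a single
vector covering every line.  A cluster with fewer than 3 lines raises an
error rather than being silently merged; the CV design is not meaningful
there.  The unclustered scheme (whole population as one cluster) adds 11
more strategies, for 99 = 11 x (1 + 2 x 4) in the default grid.

## Evaluation

* **Predictive ability**: Pearson correlation between the full observed
  and predicted vectors.
* **Classification grid**: lines binned at the empirical 20/50/80
  percentiles (linear-interpolation quantiles) of the observed and the
  predicted values separately; a value tied exactly with a cut goes to
  the lower group.  Cell (h, g) is the share of lines in predicted-group
  g whose observed value lands in observed-group h, so each non-empty
  column sums to 1; an empty predicted group yields a NaN column and is
  flagged.  A keyword flips the conditioning to observed groups for
  sensitivity checks.

## Synthetic populations

The generator emulates the NAM design at desk scale: one common inbred
parent crossed to `n_families` diverse inbred parents; each RIL inherits
contiguous 10-marker blocks from one parent or the other (a deliberate
simplification of meiosis that still yields LD and family structure)
with residual heterozygosity 1/16 per locus (F5).  Defaults: 5 families
x 40 lines, 300 markers with allele frequencies drawn from
U(0.1, 0.5), re-polarized to minor-allele counts.

Genetic values are sums of i.i.d. normal effects on standardized codes,
rescaled so their realized variance is exactly `h2_marker` (default 0.5)
of the unit phenotypic budget; yield is `3000 + 600 x (g + e)` kg/ha.
Canopy signal enters through the growth slope only (genetic variation in
vigor): the slope's standardized deviation correlates with the
standardized genetic value with coefficient `canopy_link`, plus
logit-scale observation noise (sd 0.2).  The default `canopy_link = 0.4`
was chosen so the simulated regime reproduces the qualitative structure
of real marker + canopy panels — canopy-only predictive ability roughly
half of marker-only, with the hybrid at or above the marker-only model —
rather than a canopy channel as informative as the genome, which field
imaging is not.

What the generator does **not** emulate: real linkage maps and
recombination interference, allele-frequency spectra of any particular
panel, selection during line development, spatial field trends, or
environment-by-genotype interaction.  Passing tests therefore establish
internal correctness and the qualitative information ordering, not
expected predictive abilities on any real panel.

## Problem sizes and numerical choices

Test and acceptance runs use populations of 100-300 lines with 100-300
markers — large enough for stable REML and clustering, small enough to
iterate quickly.  Heritability-recovery checks build the marker kernel
from all polymorphic markers (no MAF filter), because filtering discards
causal low-frequency variants and attenuates the estimate — as it does
with real data; the pipeline itself applies the MAF >= 0.05 filter
(strict-less-than removal, so MAF = 0.05 is retained), with missing
calls imputed to the column mode beforehand.

Degenerate inputs: constant feature columns are rejected at
standardization (QC removes them first in the pipeline); constant
responses collapse to the boundary fit; a test line with an all-zero
kernel row is predicted at mu.

## Known limitations

* The two-parameter growth curve cannot represent canopy decline late in
  the season; the daily window (14-55) ends before senescence matters.
* `fixed_vc` LOO is not the literal re-fit definition; the exact mode
  exists but costs n REML fits per strategy.
* CLARA's PAM uses steepest-descent SWAP, which is the classic local
  search; it is not guaranteed to find the global medoid optimum on
  adversarial data (tests use well-separated or exhaustively-verifiable
  instances).
* With p >> q the combined-feature distance is marker-dominated; cluster
  structure from canopy alone will not drive the partition unless blocks
  are reweighted by the caller.
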