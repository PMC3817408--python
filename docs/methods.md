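# Methods

This note records the models, estimators and numerical choices behind
`promscale`, and what the synthetic-data tests do and do not establish.

## Promoter activity from growth curves

A well's reporter fluorescence F(t) accumulates at rate P·OD(t) when the
promoter produces reporter at a constant rate P per OD unit per second.
Activity is therefore estimated by the integral form

    P = (F(t2) − F(t1)) / ∫_{t1}^{t2} OD dt ,

trapezoidal quadrature on the measurement grid with linearly interpolated
fluorescence and exponentially interpolated OD at the fractional window
boundaries.  This equals the window average of (dF/dt)/OD exactly for
constant P and is far less noise-sensitive than pointwise derivative
ratios.  Before quadrature each curve is background-corrected (media OD
offset and per-channel fluorescence offset from blank wells;
autofluorescence as a through-origin regression slope of promoter-less
control fluorescence on OD) and de-spiked with a Hampel filter (rolling
median, window 7, 3 MAD-sigmas; both configurable).

The activity window is placed at maximal growth: the rolling 5-point
regression slope of ln OD (restricted to points above an OD floor,
default 0.01) locates the time of maximal d(ln OD)/dt; in yeast mode the
window is the surrounding interval spanning exactly two OD doublings (so
OD(t2)/OD(t1) = 4, located by interpolating the monotone envelope of
ln OD, and shifted into the measured range when the maximum sits at an
edge); in ecoli mode it is the 3-hour interval centered on that time,
clipped to the run and to after any compound-addition time.  The culture
doubling time is ln 2 over the least-squares slope of ln OD inside the
window.

Detection: with ≥ 30 promoter-less control wells per condition, the yeast
threshold is the 95th percentile of a normal fit to their activities
(μ + 1.645 σ); the ecoli threshold is μ + 3 σ.  Replicate means below
threshold are floored at it (yeast) or set to zero (ecoli) and flagged —
two distinct conventions kept as distinct modes.  Cells with a single
replicate take their SD from the error model.

## Error model

Replicate relative error is summarized as a binned CV curve: promoter ×
condition cells with ≥ 2 replicates contribute (mean, SD/mean) points,
binned on a log-activity grid (default 10 bins, bins with < 5 points
merged rightward), per-bin CV = mean of member CVs.  Lookups interpolate
linearly in log-activity and clamp at the edges.  Log-activity is the
interpolation coordinate because activities span orders of magnitude;
mean-of-CVs (rather than pooled SD over pooled mean) weights every
promoter equally within a bin.

## Scale lines

The global factor S[A,B] is the slope of the origin-anchored robust line
y = a·x over promoter pairs above detection in both conditions
(floored values would bias the ray downward and are excluded from the
fit).  The estimator is IRLS with Tukey bisquare weights (tuning 4.685)
on the residuals y − a·x, with the residual scale fixed at 1.4826 ×
median |residual| of the median-ratio fit.  Because the fixed-scale
bisquare objective can be multimodal on small samples, the iteration is
multistarted from the deciles of the observed ratios y/x and the
converged slope with the lowest objective is kept; tests verify agreement
with a brute-force grid search over the same objective.

Variance explained projects every point orthogonally onto the ray and
returns 1 − Var(d)/Var(v), with both variances pooled over all scalar
components (x- and y-components together, mean-centered).  Pooling per
component (rather than per point norm) was an open choice; it makes the
2-D construction identical to the clustering criterion below.  The
permutation test shuffles the y-condition across promoters, recomputes
the variance explained by the *original* ray, and reports the add-one
estimator p = (1 + #{VE_perm ≥ VE_obs})/(n_perm + 1), so p is never zero;
calibration measured over 200 independent null datasets is 4.5–5%
rejection at α = 0.05.

Classifiers.  Method A (applicable to everything above detection in at
least one condition, floored values participating at the floor): global
iff |y − a·x| < 3 s_y or |x − y/a| < 3 s_x with s from the error model —
the two one-coordinate 3-SD tests OR-ed, which only loosens the ≤ 0.27%
per-test false-specific rate.  Method B (promoters above 0.1 in both
conditions, where the CV is a flat ~0.05): global iff the activity is
within 30% of the ray's prediction; others are excluded, not forced into
a class.

## Proportional clustering

Spherical k-means under d(x,y) = 1 − cos∠(x,y): assignment to the
nearest center (ties to the lowest index), center update to the
normalized mean of the members' unit vectors, iteration to an assignment
fixed point, best of 100 seeded restarts (centers initialized at K
distinct random profiles; an emptied cluster is re-seeded at the point
farthest from all centers).  Clusters are relabeled by descending size so
cluster 0 is always the dominant global group.  K is the largest value in
2..12 whose best model keeps every pair of centers ≥ 0.05 apart in cosine
distance (else 1).  Promoters below detection everywhere are excluded;
row normalization is not applied since the metric already ignores scale.

Per-cluster scaling factors between the reference and each condition are
ray fits over the cluster's members with inverse-variance weights
1/(x²(cv_x² + cv_y²)) from the error model: unweighted, the brightest
member dominates the slope; with plain equal-leverage weights the
noisiest low-activity members bias the ratio upward by ≈ cv².
Detection-floored cells are dropped per pair; clusters with < 10 usable
members fall back to the median ratio and are flagged low-n.  Stability
between two clusterings is the fraction of shared promoters keeping their
identity after maximal-overlap bipartite matching of cluster labels.

## Prediction from few promoters

Over m measured conditions each cluster is (approximately) a ray, so a
new condition adds one unknown per cluster.  Representatives measured in
the new condition identify it: for cluster t, the extension e_t is the
no-intercept least-squares slope of the representatives' new-condition
values on their projection coefficients x·c_t; promoter p in cluster t is
predicted as (x_p·c_t)·e_t, floored at the condition's detection level.
A cluster without a representative inherits the global cluster's
extension (flagged).  The nearest selection scheme takes ⌊n/K⌋ promoters
per cluster plus one extra to each of the largest clusters, choosing
within a cluster by smallest cosine distance to the center.

The greedy scheme forward-selects the rows minimizing the total squared
residual of reconstructing the whole matrix as linear combinations of the
selected rows, and predicts with the matching estimator: per-promoter
least-squares coefficients on the representatives' training profiles
applied to their measured new-condition values.  This linear-sum pairing
is used because it is exactly what the greedy criterion optimizes, and
because with fewer representatives than clusters the extension route
necessarily leaves clusters unrepresented; it is well-posed when
representatives are fewer than training conditions.

Leave-one-condition-out evaluation re-selects K on the remaining
conditions, refits, predicts the held-out column and reports r² between
predicted and measured plus the fraction of promoters whose relative
error is within 3 × their CV.

## Factor models

Growth-rate model: Ŝ[A,B] = τA/τB — unregulated promoters preserve
activity per doubling time, hence concentration.  Passive resource
allocation: total promoter activity × doubling time is a fixed resource
partitioned between the specific (G_spe) and global (G_glo) responses;
with f_glo[X] the G_glo share of the summed activity in condition X,
Ŝ[A,B] = (τA/τB)·(f_glo[B]/f_glo[A]).  This follows algebraically from
the conservation law plus proportionality of G_glo and reduces to the
growth-rate model when f_glo ≡ 1; it is exact to machine precision on
data generated under its own law (a tested identity).  Pairwise
predictions are defined through the per-condition vector
(Ŝ[A,B] = Ŝ[ref,B]/Ŝ[ref,A]), which makes reciprocity and transitivity
exact by construction.  Model scores report per-condition relative
deviations |Ŝ−S|/S (reference excluded), mean ± SD, and a
boundary-inclusive within-15% count.  The f_glo sums run over measured
promoters only — a known bias source when the library is incomplete.

## Synthetic data: what it emulates and what it does not

The generator plants the structure the pipeline is built to recover.
Baselines are log-normal (ln-SD 1.5, median 1 — roughly three decades of
activity at ±2σ); cluster memberships are multinomial with a dominant
global cluster (default fractions 0.77/0.05/0.05/0.05/0.04/0.04);
condition-specific multipliers r_t[c] (global cluster ≡ 1) define five
programs — respiration-like, osmotic-stress, galactose-utilization,
heat-shock and repressed-on-poor-carbon — whose directions keep pairwise
cosine separation ≥ 0.12 on the full six-condition panel and remain
separated in every leave-one-condition-out projection, so both K
selection and held-out prediction are well-posed.  Global factors are
solved self-consistently from the conservation law (so τ_c·Σ_g P[g,c] is
constant by construction) and normalized to the reference.  Default
doubling times are 90–220 min, the range of budding-yeast plate cultures
across rich and poor media.

Wells use logistic OD growth (od0 = 0.005, carrying capacity 1.4 — small
enough od0/K that the two-doubling window sits in the near-exponential
phase and the doubling-time bias stays under 2%), media background 0.04
OD, autofluorescence 20 fluorescence units per OD, readings every 20 min
for 20 h.  Replicate variability enters as one multiplicative
mean-preserving log-normal factor per well with CV from the planted
curve (0.36 at activity 0.003 falling log-linearly to a constant 0.05
above 0.1 — the natural scale for a relative-error model), plus small
per-increment jitter (CV 0.01), OD read noise (SD 0.002) and fluorescence
read noise (SD 2).  Each condition gets 36 promoter-less control wells
(so ≥ 30 survive QC) and 6 media blanks; an optional fraction of wells is
planted with flat OD for QC testing.

Not emulated: single-cell variability, plasmid copy-number dynamics,
diauxic shifts, reporter maturation delays, position effects, or any
dynamic environment change.  Passing tests therefore establish that the
estimators recover the planted generative structure at realistic noise —
they do not establish that real cultures obey proportional scaling; on
real data the model-deviation scores and permutation tests are the
relevant checks.

## Numerical conventions and degenerate inputs

Time is seconds internally; configs accept minutes at the boundary.
Variances use the population convention (ddof 0) wherever pooled over
components, and the sample convention (ddof 1) for replicate SDs and
deviation summaries.  IRLS tolerance 1e-8, ≤ 100 iterations; k-means ≤
300 iterations per restart.  Ties in k-means assignment and in
representative selection break toward the lowest index; equal-objective
restarts keep the first.  Saturated-from-start or sub-two-doubling OD
series raise a no-growth error naming the well; QC never hard-fails, it
flags (no-growth, gaps, constitutive-channel robust |z| > 3) and leaves
exclusion to downstream stages; re-running QC is idempotent.  All
randomness flows through seeded `numpy.random.default_rng`; identical
seeds give bit-identical truth, curves and artifacts.

## Problem sizes

The bundled study runs at 500 promoters × 6 conditions × 3 replicates
(plus controls and blanks, ~9,700 wells), 1000-permutation tests, 100
k-means restarts, and 200 null datasets for permutation calibration —
sizes chosen so a full end-to-end run completes in about a minute on one
CPU while keeping every estimator in its intended regime.

## Known limitations

The selected K can exceed the planted cluster count on some seeds:
strongly repressed promoters whose activities hit the detection floor in
several conditions form a genuine extra direction in the floored matrix,
and the separation rule (correctly) keeps it.  The greedy selector is
O(n·picks) QR decompositions and is meant for hundreds, not tens of
thousands, of promoters.  Method A's 3-SD rule inherits whatever bias the
error model has at the extremes of the binned range (clamped
extrapolation).  The resource-allocation model's f_glo is computed over
the measured library only.
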