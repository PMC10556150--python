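# Methods

`dfnckit` implements a dynamic functional network connectivity (dFNC)
analysis for resting-state component time courses: sliding-window
regularized-inverse-covariance connectivity, k-means brain-state
clustering under the city-block metric, temporal state metrics, group
inference, bootstrap mediation, and a centroid-regression SVM
classifier. A synthetic cohort generator supplies data with the
statistical structure the analysis assumes, so every stage is testable
without fMRI recordings. This note documents the models, the defaults
and why they were chosen, the numerical decisions, and what the
synthetic experiments do and do not demonstrate.

## Data model

The unit of analysis is one subject's time x component matrix: 23
independent-component time courses sampled at TR = 2 s for 230
timepoints, partitioned into three cognitive-control networks — default
mode (DMN, 7 components), central executive (CEN, 9), salience (SN, 7).
Connectivity is always expressed over the 253 unordered component
pairs, ordered row-major over the upper triangle with components sorted
DMN, then CEN, then SN.

## Post-processing

Component time courses are cleaned per column in a fixed order:

1. **Detrend** — least-squares polynomial removal, order 1 by default
   (orders 0–2 supported).
2. **Despike** — robust-z detection: a sample is a spike when
   |x − median| / (1.4826 · MAD) exceeds 3.5; spike runs are replaced by
   linear interpolation between the nearest non-spike neighbours
   (endpoints clamp to the nearest good value). Because interpolation
   shifts the median/MAD, detection is repeated up to 5 passes.
   A column with MAD = 0 is returned unchanged. The threshold and the
   interpolation rule are our choices; the source analysis names no
   specific despiking algorithm.
3. **Low-pass filter** — 5th-order Butterworth, cutoff 0.15 Hz, applied
   forward–backward (zero phase). Filter family and order are our
   choice of the common practice for this step. Forward–backward
   filtering leaves decaying transients at the series ends; the chain
   is numerically idempotent (relative RMS < 1e-6) on band-limited
   input away from the edges, and cannot be idempotent on broadband
   input, which carries energy in the filter's transition band.
4. **Nuisance regression** — OLS residualization on an intercept plus
   six head-motion parameters; rank-deficient designs fall back to the
   pseudo-inverse with a warning. Residuals are not re-centered (the
   intercept already removes the mean).

## Windowed connectivity

Windows of 30 TR (60 s) slide in steps of 1 TR. The window count
convention is floor((T − width)/step), giving 200 windows for T = 230
— the count the study design forces; the more common inclusive
convention (T − W + 1) would give 201.

Within each window, columns are standardized and the correlation matrix
is fed to the graphical lasso, the L1-penalized maximum-likelihood
precision estimator: maximize log det Θ − tr(SΘ) − λ‖Θ‖₁(off-diag).
The solver is scikit-learn's coordinate-descent implementation; λ = 0
is special-cased as the direct inverse. The penalty λ is not fixed by
the source analysis; the default is **λ = 0.1** on standardized
data, overridable everywhere. On strongly correlated 30-sample windows
the solver can stall at a residual duality gap around 1e-3; such
near-converged estimates are accepted (they pass positive-definiteness
and all downstream checks) and only genuine solver failures raise.

The precision matrix is converted to partial correlations,
r_ij = −Θ_ij / √(Θ_ii Θ_jj), clipped to |r| ≤ 1 − 1e-7, and
Fisher-transformed (z = atanh r). The exact post-ICOV transform chain
is not pinned down in the source analysis (only "z values" are named); this
partial-correlation + Fisher-z chain is our documented choice, with raw
precision entries available programmatically. Windows are rectangular
by default; a Gaussian taper is available behind a flag.

## State clustering

All subjects' window vectors are clustered by k-means under the
Manhattan (L1) metric: assignment minimizes city-block distance and the
centroid update is the **coordinate-wise median** — the L1-optimal
center; a mean update would not minimize the stated objective. Five
random restarts (distance-weighted seeding on L1 distances) are run and
the lowest-cost solution kept; the per-iteration cost is checked to be
non-increasing. Empty clusters are re-seeded at the observation
farthest from its centroid. Assignment ties break to the lowest
centroid index.

Fitting is two-stage: k-means runs on per-subject **exemplars** — local
maxima of the across-pair variance of the FNC vector over window index
(endpoints eligible; flat profiles fall back to the first global
maximum) — and a final pass assigns every window to the frozen
centroids. A single-stage full fit is available. States are then
relabeled in order of first emergence in the concatenated assignment
stream; relabeling is a pure permutation and changes no cost or count.

The number of states is selected on the exemplars:

* **Elbow** (default): the drop-ratio statistic
  (cost(k−1) − cost(k)) / (cost(k) − cost(k+1)), maximized over interior
  k. We use the ratio rather than the raw second difference because it
  is scale-free and markedly more stable on noisy L1 cost curves; the
  two agree on clean curves. By construction an interior-kink
  criterion cannot select an endpoint of the candidate range.
* **Silhouette**: mean silhouette under the city-block metric,
  maximized over k; reported alongside the elbow choice. When the two
  disagree the elbow wins by default and the disagreement is logged in
  the diagnostics.

## Temporal metrics

From each subject's 1-based window label sequence: mean dwell time
(average length of maximal runs of a state, in window units), fraction
of time (proportion of windows in a state), and number of transitions
(count of label changes). A subject who never visits a state gets
dwell time 0 rather than missing — group contrasts then retain all
subjects, matching degrees of freedom that count the full cohort — with
missing-value semantics available as a flag. Conversion of dwell to
seconds (× step × TR) is a reporting option, never the stored value.

## Group inference

Two-sample contrasts use the pooled-variance t (df = n1 + n2 − 2) by
default, computable identically from raw vectors or printed summary
triples (n, mean, sd). Levene's test (mean-centered; median-centered
variant available) guards homogeneity: when it rejects at 0.05 the
Welch statistic is reported alongside. Correlations are Pearson r with
two-sided p on n − 2 df and row-wise deletion. Multiplicity is
controlled by Benjamini–Hochberg FDR within configurable families; the
default families are (a) the per-state dwell contrasts plus the
transitions contrast, (b) the per-state fraction contrasts, (c) each
state-metric's row of clinical correlations, and (d) per-state
network-block contrasts. Per-state block connectivity averages a
subject's FNC vectors over windows in the state and then within the six
network blocks (DMN–DMN, CEN–CEN, SN–SN, DMN–CEN, DMN–SN, CEN–SN);
subjects absent from a state are excluded from that state's contrasts,
shrinking the degrees of freedom exactly by the number excluded.

## Mediation

Single-mediator linear product-of-coefficients model with binary
exposure (controls 0, patients 1): a from M ~ 1 + X; b and c′ from
Y ~ 1 + X + M; c from Y ~ 1 + X; indirect effect a·b, and
c = c′ + a·b identically. Inference bootstraps subjects with
replacement (default 5000 resamples), recomputing a·b per resample;
resamples in which the exposure collapses to one level are redrawn and
counted. Both percentile and BCa intervals are reported: bias
correction z₀ = Φ⁻¹(fraction of bootstrap values below the point
estimate, clipped away from 0/1), acceleration from the leave-one-out
jackknife skewness. The whole bootstrap runs through per-resample
sufficient statistics (sums of X, M, Y and their products with batched
closed-form solves), so 5000 resamples are a few vectorized reductions.
Whether variables are standardized before mediation is left open in the source analysis; the raw
indirect effect is primary and an outcome-standardized version
(a·b / sd(Y)) is reported alongside. "Partial mediation" is flagged
when the BCa interval excludes 0 while the direct effect c′ remains
significant at the same level — a reporting convention, not a test.

## Classification

A design matrix is formed whose columns are the mean windowed-FNC
patterns of each (group, state) cell — 8 columns for 2 groups × 4
states; empty cells are dropped with a warning. Every window vector is
regressed on the design columns (no intercept; both sides centered
across the pair dimension, which makes the betas scale-comparable),
giving 8 beta coefficients per window; averaging over windows yields 8
features per subject. The source analysis describes this step both as a regression
and as a Pearson correlation; multivariate least squares is the default
and a correlation-features variant sits behind a flag (under
orthonormal columns the two coincide).

Evaluation is a linear SVM (C = 1, our default; the regularization
constant is not specified in the source analysis) with stratified 10-fold
cross-validation repeated 100 times; per-class accuracy is the
sensitivity for that class, averaged over folds and repeats, and an ROC
curve is pooled from decision scores. Because the centroid design in
the original construction is computed from **all** subjects before
cross-validation, two modes exist: `paper_faithful` reproduces that
construction, and the default `fold_safe` refits the state model and
design on training subjects only within each fold, assigning held-out
windows to the frozen training centroids. On signal-bearing cohorts
`paper_faithful` is optimistic relative to `fold_safe`; both record
their mode in every output.

## Synthetic cohort generator

The generator is a first-order hidden-Markov switching model: each
subject's state path is a Markov chain over 4 states; given the state,
a timepoint is drawn from a zero-mean multivariate normal with the
state's covariance, plus isotropic observation noise (sd 0.2).

**States are planted in precision space.** Each state's covariance is
the normalized inverse of a sparse precision matrix: chain partial
correlations between adjacent components within each network block plus
a few cross-network links. This is deliberate: the pipeline clusters
partial correlations, and regimes must differ in conditional-dependence
structure to be distinguishable there — block-constant *marginal*
correlations collapse to near-zero partial correlations in blocks this
large (r/(1 + (p−2)r) for an equicorrelated block) and are
unrecoverable at realistic window lengths. The four presets:

| state | profile | within-network (DMN/CEN/SN) | cross-network |
|---|---|---|---|
| 1 | weak_sparse | 0.05 / 0.05 / 0.05 | — |
| 2 | intermediate_1 | 0.48 / −0.25 / 0.30 | DMN–SN 0.25 |
| 3 | intermediate_2 | −0.25 / 0.45 / −0.15 | CEN–SN 0.22 |
| 4 | strong_dense | 0.40 / 0.38 / 0.38 | 0.12 / 0.25 / 0.12 |

State 1 is weakly connected everywhere; state 4 strongly connected
within and between networks with elevated DMN and DMN–SN coupling; the
intermediates are network-dominant regimes with anticorrelated
counterparts (DMN-dominant with suppressed CEN; CEN-dominant with
anticorrelated DMN). The strengths were balanced so that all six
pairwise regime contrasts are comparable; every precision and
covariance is verified positive definite at construction (smallest
eigenvalues ≥ 0.05).

**Persistence.** Stay probabilities default to
(0.992, 0.985, 0.985, 0.975) for patients and the mirror image for
controls, i.e. expected dwells of roughly 125/67/67/40 TR — well above
the 30-TR window, consistent with published dwell-time scales in comparable
cohorts (tens of windows), and directionally reproducing its group pattern
(patients dwell longer in the weak state 1, shorter in the strong
state 4). Windows that straddle a regime switch are genuinely
ambiguous: on development cohorts, windows lying fully inside one
regime were recovered with ≈ 0.1 % error while straddling windows
carry essentially all label disagreement; persistence therefore
controls the ceiling on window-level recovery.

**Clinical covariates** are linear-Gaussian in occupancy statistics
computed on the majority-vote window labels (fraction/dwell per state,
transitions): covariate = intercept + coef · statistic + noise. The
default table (MoCA-like cognition falling with state-1 occupancy;
anxiety/depression and endocrine measures rising with state-1 or
falling with state-4 occupancy) plants moderate population
correlations, |r| ≈ 0.25–0.55; no attempt is made to match any real
cohort's marginal distributions.

All randomness flows from one master seed through
`numpy.random.SeedSequence.spawn` (one child per subject in order, one
for the clinical table); regeneration is bit-identical.

**What the synthetic experiments show — and don't.** Passing recovery
tests shows the pipeline correctly identifies covariance regimes,
their occupancy statistics, and planted couplings *under the
generator's assumptions*: Gaussian emissions, exact first-order Markov
switching, states shared identically across subjects, and no
hemodynamics, spatial maps, scanner drift or motion structure. Real
fMRI violates all of these; synthetic results bound what the code does,
not what the biology warrants.

## Problem sizes in tests

The default acceptance experiments use 20 subjects per group at the
full design (T = 230, 23 components, 200 windows) — about 8000
graphical-lasso fits per cohort; unit tests use 3 + 3 subjects with
shorter series and strided windows. Mediation coverage uses 500
replicates of n = 200 with 1000 resamples, enabled by the
sufficient-statistic bootstrap. These sizes were chosen as the smallest
that make the statistical assertions stable.

## Known limitations

* Silhouette-based k selection on noisy high-dimensional L1 data has a
  bias toward merging close regimes (small k); the elbow criterion on
  the cost curve is the more reliable selector here and is the
  default.
* The graphical-lasso penalty is global by default (one λ for all
  windows and subjects); `select_lambda_cv` offers per-subject
  selection by cross-validated held-out window log-likelihood over a
  small grid, but is not wired into the default pipeline.
* Window-level state labels near regime switches are intrinsically
  ambiguous; recovery is reported against majority-vote truth.
* The mediation model is linear with no exposure–mediator interaction
  and no covariates by default (covariate support exists but is off).
* `paper_faithful` classification leaks test information through the
  centroid design by construction; it exists for comparability, not
  for performance claims.
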