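# dfnckit

Dynamic functional network connectivity (dFNC) analysis for
resting-state fMRI component time courses, aimed at studies that ask
whether two groups differ in how their brains move through recurring
connectivity "states" — and whether those temporal differences carry
clinical meaning. The package covers the full analysis chain used in
endocrine and psychiatric neuroimaging cohorts (e.g. patients with
chronic hypercortisolism vs healthy controls): time-course cleaning,
sliding-window connectivity, brain-state clustering, temporal state
metrics, group statistics, mediation, and classification. A synthetic
cohort generator with known ground truth makes every stage testable
without access to fMRI recordings.

## The method

Each subject contributes a time × component matrix (23 independent
components spanning the default-mode, central-executive and salience
networks; 230 samples at TR = 2 s). The pipeline:

1. **Post-processing** — per component: polynomial detrend, robust-z
   despiking (median/MAD, threshold 3.5, linear interpolation),
   zero-phase 5th-order Butterworth low-pass at 0.15 Hz, OLS removal of
   six motion parameters.
2. **Windowed connectivity** — 30-TR (60 s) windows sliding by 1 TR
   (200 windows per subject). Per window, the regularized inverse
   covariance (graphical lasso, penalty λ = 0.1) is estimated on
   standardized data and converted to Fisher-z partial correlations
   over the 253 component pairs:
   r_ij = −Θ_ij/√(Θ_ii Θ_jj), z = atanh(r).
3. **States** — k-means under the Manhattan metric (coordinate-wise
   median updates, 5 restarts) on all subjects' window vectors, fit on
   per-subject exemplar windows; k chosen by the elbow criterion on the
   L1 cost curve with silhouette reported alongside; states labeled in
   order of first emergence.
4. **Temporal metrics** — per subject and state: mean dwell time
   (windows), fraction of time, and the number of state transitions.
5. **Group inference** — pooled-variance t-tests (Levene-guarded, with
   Welch alongside where variances differ), Pearson correlations with
   clinical covariates, Benjamini–Hochberg FDR within families, and
   per-state network-block connectivity contrasts.
6. **Mediation** — does a temporal metric mediate the group difference
   in cognition? Product-of-coefficients a·b with a 5000-resample
   bootstrap and bias-corrected-and-accelerated (BCa) intervals.
7. **Classification** — regress each window's FNC vector on the 8
   (group × state) mean centroid patterns; the 8 averaged β
   coefficients per subject feed a linear SVM with 100 × stratified
   10-fold cross-validation and ROC analysis, in either a fold-safe or
   the original all-data-centroids construction.

## Worked example

```python
from dfnckit import (SyntheticSpec, make_cohort, SlidingWindowConnectivity,
                     fit_states, select_exemplars, choose_k, profiles_table,
                     two_sample_t)

spec = SyntheticSpec(n_group_a=20, n_group_b=20, seed=1)
cohort = make_cohort(spec)                        # 40 subjects, 4 planted states
series = SlidingWindowConnectivity().fit().transform(cohort.timecourses)

exemplars, _ = select_exemplars(series)
k, diag = choose_k(exemplars, range(2, 9), "elbow", seed=1)
model = fit_states(series, k=k, seed=1)

groups = {g.subject_id: g.group for g in cohort.ground_truths}
profiles = profiles_table(model.labels, groups, n_states=k)
cd = profiles[profiles.group == "CD"]["dwell_s1"]
hc = profiles[profiles.group == "HC"]["dwell_s1"]
res = two_sample_t(cd.to_numpy(), hc.to_numpy())
print(f"k = {k}")
print(f"state-1 dwell: CD {cd.mean():.1f} vs HC {hc.mean():.1f} windows, "
      f"t({res.df:.0f}) = {res.statistic:.2f}, p = {res.pvalue:.2g}")
```

prints

```
k = 4
state-1 dwell: CD 50.5 vs HC 19.9 windows, t(38) = 2.26, p = 0.03
```

The elbow criterion recovers the four planted covariance regimes, and
the patient group dwells substantially longer in the first-emerging
state — the planted group difference, detected by the pooled
two-sample t-test (df = n₁ + n₂ − 2 = 38).

Published summary statistics can be checked directly: with the printed
group summaries (n, mean, sd) = (50, 89.040, 59.216) vs
(57, 57.491, 40.671), `two_sample_t` gives t(105) = 3.244, p = 0.002.

A CLI mirrors the library (`dfnckit simulate | postproc | dfnc |
cluster | metrics | stats | mediate | classify | run-all`); `run-all`
executes the whole chain from a YAML config and writes every
intermediate artifact with a manifest of parameters, seeds and file
hashes.

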