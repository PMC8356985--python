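# Methods

This note records the model, the numerical choices, and what the synthetic
data do and do not establish.

## Generative model of the synthetic cohort

Each subject's component time course is a zero-mean multivariate normal
whose covariance switches at TR resolution between K = 2 state correlation
matrices.  No hemodynamic convolution, autocorrelated noise, motion, or
spatial structure is modelled: the generator produces component time courses
only, and windowing itself blurs state boundaries, which the recovery
tolerances account for.

**Network partition.** 39 components in six networks — AUD (2), VIS (8),
SMN (7), CEN (7), DMN (11), CB (4) — with pair ordering fixed by the network
blocks, giving 741 component pairs.

**State covariances.** Block-target matrices, element-wise jittered
(SD 0.02) and repaired to positive definiteness by eigenvalue clipping at
1e-6 followed by renormalization to unit diagonal; a spec is rejected if the
repair moves any block mean by more than 0.1.  Defaults:

* *State 1, integrated*: within-network r = 0.25; between-network r = 0.40
  among {AUD, VIS, SMN, DMN}, 0.10 elsewhere.  The strong/weak split gives
  the state a heterogeneous across-pair profile; a flatter profile (e.g.
  uniform between-network 0.3) is recovered with centroid correlations near
  0.85 rather than ≥ 0.9, because the finite-data noise floor of pooled
  window estimates (≈ 0.04 in Fisher z at 20 subjects × 240 TRs) is then
  comparable to the profile's own spread.
* *State 2, segregated*: within-network r = 0.65, between-network r = 0.02.

**Dynamics.** A per-group two-state Markov chain, initialized at its
stationary distribution.  Stay-probabilities are calibrated so stationary
integrated-state occupancy is ≈ 0.19 (OCD) < 0.27 (UFDR) < 0.35 (HC) —
weighted by the default group sizes 46/24/49 this puts the grand occupancy
near 0.27 — with mean integrated dwell of 35–40 TRs.  Long dwells relative
to the 22-TR window keep most windows state-pure (which is what makes
centroid recovery possible at all), and they make per-subject occupancy
strongly dispersed, including subjects who never enter the integrated state
during a 240-volume scan; both features match what short resting scans of
slowly switching processes look like.  Whether group differences arise from
dynamics or from state connectivity is left open by design: the generator
exposes both the per-group chains and the (shared) state covariances, so
either can be varied.

**Clinical scores.** OCI-R = group intercept + 26·FW₁ + N(0, 10²); the slope
and residual SD were chosen analytically so that, at the typical
within-patient occupancy SD of ≈ 0.17, the occupancy–symptom correlation
sits near 0.4 (the band centre used by the coupling tests; single-group
r-hat at n = 40 has sampling SD ≈ 0.135, so a band of ±0.2 cannot be hit in
much more than ~86% of replicates by any calibration — the coupling test
therefore evaluates the group-demeaned correlation over the whole cohort).
Y-BOCS, BDI, STAI and education are drawn per group from fixed means/SDs,
independent of occupancy, so partial and zero-order correlations can be
contrasted.  Scores are Gaussian and not clipped at scale boundaries.

**Seeding.** One integer seed expands deterministically: subject i uses
stream `seed + i`; covariance jitter and clinical covariates use fixed
offsets (500 000, 600 000) of the same seed; the pipeline's clustering stage
uses offset 700 000.

## Postprocessing

Detrend (least-squares line), despike, low-pass, in that order (the order of
detrending and despiking is a fixed convention here).  The despike robust
scale is `s = sqrt(π/2)·median|x|` — the half-normal absolute-moment
estimator — and points beyond `c1·s` (c1 = 2.5) are compressed by
`s·(c1 + (c2−c1)·tanh((|x|/s − c1)/(c2−c1)))` with c2 = 4, so no output
exceeds `c2·s` and no magnitude ever increases.  The low-pass filter is a
5th-order Butterworth at 0.15 Hz applied forward–backward (zero phase, so
windowed correlations are not phase-distorted; the magnitude response is
squared, so the cutoff sits at amplitude 0.5 rather than 0.707), with
odd-reflection padding of length `3·(2·order+1)` clipped to T−1.

## Windowed sparse connectivity

The taper is a width-w rectangle convolved with a Gaussian of SD σ
(defaults w = 22 TRs, σ = 3), support `w + 2·ceil(3σ)` samples, normalized
to sum 1.  Window positions are 0-based half-open `[start, start+w)` with
count `floor((T−w)/step)+1`; 240 volumes at step 1 give 219 windows.  (An
optional `discard_initial` drops leading volumes; dropping 11 reproduces a
208-window convention.)  At the scan edges the Gaussian skirt is clipped and
the weights renormalized.  Components are standardized per subject over the
full scan so one penalty scale applies to all subjects.

The graphical lasso penalizes off-diagonal precision entries only
(`λ Σ_{j≠k}|Θ_jk|`, default λ = 0.1; an optional per-subject grid-CV scores
candidate λ by held-out Gaussian log-likelihood over contiguous window
folds).  It is solved by block coordinate descent over columns with an
inner-product cache, warm-started from the previous overlapping window;
convergence is max elementwise change of the working covariance < 1e-5,
with a 200-sweep cap.  Non-convergence raises an error carrying the last
iterate, or (in the cohort driver) keeps the iterate and counts it in the
run log.  Correctness is pinned three ways in the tests: a brute-force
numeric optimizer on 3×3 problems, the KKT stationarity conditions, and
scikit-learn's implementation on larger matrices.  Fisher z uses
`atanh(clip(r, ±(1−1e-6)))`.

## State clustering

City-block distance with element-wise median centroids throughout.
Exemplars are windows at strict local maxima of the across-pair variance
series (boundary windows compared to their single neighbour; if the series
has no strict maximum, every ⌈W/10⌉-th window is taken).  Phase 1 clusters
the pooled exemplars (10 random restarts; pooled rows are lexicographically
sorted first so results are invariant to subject order); phase 2 runs one
pass over all windows of all subjects from the phase-1 centroids, capped at
150 iterations.  Empty clusters are re-seeded with the farthest point.
Clustering operates on Fisher-z values.  State identity is fixed by mean
between-network connectivity: the larger is state 1 (integrated).

**Choosing K.**  validity(k) = mean within-cluster distance / mean
between-centroid distance, computed on the exemplar set for k in 2..6 by
default.  The elbow is the point with the largest perpendicular distance
below the chord joining the curve's endpoints (axes normalized to [0,1]),
restricted to points that improve on the smallest k; if no interior point
falls below the chord — the curve rises from its first point, as it does
for genuinely two-state data, where extra centroids shrink between-centroid
distances faster than within-cluster ones — the k minimizing the validity
index is returned.  This tie-break is what lets the left endpoint of the
search range be selected; the raw maximum-distance rule can never return an
endpoint.

## Temporal metrics and inference

FW, DT (in windows; seconds = windows × TR as an optional extra column) and
NT are defined on maximal constant runs; an unvisited state has DT = 0 with
an explicit visited flag, and subjects missing a state are excluded listwise
from that state's connectivity family (exclusion counts reported), never
imputed.  Per-state connectivity profiles aggregate a subject's windows by
mean (median available).

Inference: vectorized one-way fixed-effects ANOVA (the 741-pair family is
one call), Fisher's LSD post hoc (pooled within-group variance, df = n−G,
unadjusted p, to be read under the omnibus FDR decision), BH step-up FDR
within each family (the five temporal indices; each state's 741 pairs; the
metric × scale clinical family), Pearson partial correlation by
residualization with intercept (p from t with df = n − #covariates − 2; a
variable fully explained by the covariates returns r = 0 rather than the
correlation of rounding noise).  Both STAI subscales enter as covariates.
Degenerate inputs — zero within-group variance, a state family with < 2
subjects in a group, a patient group smaller than the covariate set — skip
that family with a recorded warning instead of failing the run.

## Problem sizes used in verification

Recovery and model-selection checks run 20 replicate cohorts of 20 subjects
(7/6/7 per group) at T = 240, N = 39 — about 4 400 windowed graphical-lasso
fits per cohort; replicate counts for generator-level checks (group
ordering, coupling) are 50, and the error-rate simulations of the 741-pair
family run 30 replicates at n = 40/group directly on state profiles drawn
from the generating model, since they test the inference machinery rather
than windowing.  Window-length robustness compares occupancy estimates at
w = 18/22/26 on one replicate.

## Known limitations

* The generator's white-in-time signals understate the autocorrelation of
  filtered BOLD, so real windowed estimates are somewhat noisier than the
  synthetic ones at equal T; passing tests demonstrate correct recovery of
  the generative regime, not field performance on real scans.
* Group differences in the defaults are purely dynamic (shared state
  covariances), so per-pair connectivity ANOVAs on default cohorts are null
  by construction; connectivity-difference power is exercised with explicit
  profile offsets instead.
* Only sliding-window k-means states are implemented — no HMM,
  wavelet/time-frequency, or meta-state variants, and no spatial maps or
  volume handling.
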