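# Methods

## The twin ACE model

A phenotype y measured on twin pairs is modeled as
y = √A·a + √C·c + √E·e with unit-variance latent factors: a (additive
genetics) is shared perfectly within MZ pairs and with correlation 0.5
within DZ pairs, c (shared environment) is shared perfectly within every
pair, and e (unique environment plus measurement error) is independent
across subjects. The implied twin-pair correlations are rMZ = A + C and
rDZ = A/2 + C, and heritability is h² = A/(A + C + E). The model assumes
equal shared environments for MZ and DZ pairs, no dominance or epistasis,
no assortative mating, and no gene–environment interaction; violations
bias A in the usual directions (e.g., dominance inflates the MZ/DZ
contrast).

## Estimators

**Falconer contrast.** Given observed pair correlations,
A = 2(rMZ − rDZ), C = 2rDZ − rMZ, E = 1 − rMZ. Raw values are reported
alongside constrained ones.

**LR-SD (regression on squared differences).** For each element, with
d_p = (y_p1 − y_p2)² and z = 1 for DZ pairs, OLS of d on [1, z] gives
intercept 2σ̂²_E and slope σ̂²_A because E[d|MZ] = 2σ²_E and
E[d|DZ] = 2σ²_E + σ²_A. The total phenotypic variance σ̂²_P is the sample
variance pooled over all subjects (unbiased under exchangeability and
independent of the pair labeling), and σ̂²_C = σ̂²_P − σ̂²_A − σ̂²_E.

**Constraint handling.** Negative estimates are truncated in a fixed
order: Â to 0 first, then Ĉ is recomputed as max(σ̂²_P − Â − Ê, 0), and Ê
clipped at 0 last. This keeps all components in [0, σ̂²_P] and h² in
[0, 1]. The order is a convention and is pinned by tests; other
projections (e.g., simultaneous non-negative least squares) would differ
only in the rare doubly-negative corner.

**Test for A > 0.** The one-sided statistic is the regression t for the
slope, set to 0 when the slope is non-positive. Because A = 0 lies on the
boundary of the parameter space, the parametric null is the mixture
½·δ₀ + ½·χ²₁ applied to t²: p = 0.5·P(χ²₁ ≥ t²) for positive slopes,
p = 1 at or below the boundary. At the mass point the p-value jumps
(0.5 as t → 0⁺, 1 at t = 0); this convention keeps P(p ≤ α) = α for all
α < 0.5 under the null. Covariates (age, sex) are removed by OLS
residualization before fitting; phenotypes are mean-centered per element.

## Permutation inference

The exchangeability blocks are intact twin pairs. The null for any
A-contrasting statistic is generated by **shuffling zygosity labels
across pairs** while preserving the MZ and DZ counts: within-pair
dependence is untouched, only the differential genetic sharing that
identifies A is broken. All permutation p-values use (1 + b)/(m + 1) and
are never zero.

* *Element-wise FWE*: the observed statistic per element is compared with
  the permutation distribution of the maximum statistic over elements.
* *Cluster extent*: elements with parametric p below the cluster-forming
  threshold (default 0.05) are grouped into connected components under a
  user-supplied element adjacency; the null is the distribution of the
  maximum component size. The cluster statistic is extent (element
  count), not mass.
* *NBS on edgewise h²*: edges with h² strictly above a threshold τ are
  binarized; the size (edge count) of the largest connected component is
  compared with the same quantity from h² matrices recomputed under
  permuted zygosity. Ties between equal-edge-count components are broken
  by node count, then by smallest minimum node id, making the output
  deterministic. Threshold sweeps reuse a single permutation stream (the
  same permuted h² matrices re-thresholded per τ), so a sweep costs one
  permutation pass and is internally consistent across thresholds.

Because the per-edge regressions share the pair structure, permuted
statistics for all elements and all permutations are computed with one
closed-form vectorized pass (the centered-indicator cross-product), which
is what makes 10⁵–10⁶ element × permutation combinations cheap.

## Power simulation

`twin_power_curve(n_mz, n_dz, a_grid, alpha, n_rep, seed)` simulates, for
each additive fraction a, `n_rep` independent phenotypes with
(A, C, E) = (a, 0, 1 − a) on a fresh cohort and applies the same LR-SD
A > 0 test used by the mapping pipeline; power is the rejection fraction
and the 80% crossing is linearly interpolated between grid points. The
acceptance script runs this at 56 MZ + 67 DZ pairs, α = 0.05, grid
0.10–0.90 in steps of 0.05, 2000 replicates per point. Note that the
power of the squared-differences test is driven by the contrast of
within-pair difference variances (2σ²E for MZ versus σ²A + 2σ²E for DZ);
a full maximum-likelihood ACE fit would also exploit the between-pair
(pair-sum) information and is somewhat more powerful, but an expected-LRT
calculation shows the difference moves the 80% crossing at this sample
size by less than 0.05. SEM/ML fitting is deliberately out of scope.

## Task-weighted functional connectivity

* **HRF**: canonical double-gamma — response gamma with shape 6, unit
  scale (mode at 5 s), undershoot gamma with shape 16, ratio 1/6 —
  sampled on [0, 32] s and normalized so the positive lobe sums to 1.
* **Condition weights**: unit boxcar over each event's [onset,
  onset + duration), sampled at volume times, convolved with the HRF.
  Negative convolution lobes are rectified to 0 because weighted
  correlation requires nonnegative weights. The reinforced-cue condition
  merges the cue and stimulus intervals into one boxcar (they are
  contiguous by design).
* **Confound regression**: OLS residualization against an intercept, one
  HRF-convolved regressor per trial type (removing task-evoked mean
  responses so that condition contrasts reflect correlation changes, not
  mean shifts), 6 motion parameters and their squares, and one-hot scrub
  regressors that force flagged volumes' residuals to zero. Collinear
  columns are dropped with a logged warning.
* **Band-pass**: zero-phase ideal FFT mask on [0.008, 0.09] Hz (inclusive
  bins). Chosen for determinism and exact idempotence; an IIR/FIR filter
  would introduce phase or edge effects irrelevant at these series
  lengths. The high cutoff must lie below Nyquist = 1/(2·TR).
* **Weighted correlation**: r_ij from weighted central moments with
  weighted means; z = atanh(r) with r clipped to |r| ≤ 1 − 1e−7 so z is
  finite (cap |z| ≈ 8.4). Nodes with zero weighted variance get a zeroed
  row/column and a logged warning. Spatial smoothing is never applied
  before FC.
* **Network summary**: for networks A ≠ B, the sum of A–B edge values
  divided by |A| + |B|; within a network, the sum over unordered pairs
  divided by |A|.

## Quality control conventions

* **Framewise displacement**: backward differences, FD = Σ|Δtrans| +
  50·Σ|Δrot| (rotations in radians converted to arc length on a 50 mm
  sphere); FD of the first volume is 0.
* **High motion**: flagged iff the fraction of volumes with FD strictly
  above 0.5 mm strictly exceeds 0.5. Both inequalities strict, so "exactly
  half" does not flag.
* **Amplitude outliers**: |x − median| > k·1.4826·MAD with k = 3; the
  1.4826 factor makes the rule "k robust standard deviations" under
  normality (tail fraction ≈ 0.27% at k = 3). When MAD = 0 only strictly
  deviating values flag. Outliers are removed together with their
  co-twin.
* **Stage order**: motion → outliers → missing data, each exclusion
  counted at the first stage that triggers it; the MAD rule is evaluated
  on motion-stage survivors. A final sweep removes any subject whose
  co-twin is gone, so the output roster always consists of intact pairs
  (high-motion removal also takes the co-twin by default,
  flag-controlled). The cascade is idempotent.

## Synthetic data: what it does and does not emulate

The generator reproduces the *statistical* structure the inference chain
relies on: exact ACE twin covariance per element (DZ sharing built by the
latent construction a = √½·a_pair + √½·a_own rather than a joint
covariance draw — exact and O(n)); a conditioning schedule of 16
six-second cues, 8 reinforced by a 3 s stimulus regressor, inter-stimulus
intervals uniform on 8–12 s (only the 8–12 s jitter range is fixed by
the paradigm; the uniform distribution is this package's convention), run length capped at 587 s,
habituation trials not generated; ROI time series in which designated
node pairs load on a shared latent factor during reinforced-cue frames,
with a per-subject gain that is itself ACE-structured (so the planted
connectivity contrast is heritable), implemented as correlation
modulation rather than mean shifts so task-mean confound regression
leaves it intact; and motion traces as small-step random walks
(translation steps ~0.02 mm, rotation steps ~2×10⁻⁴ rad) with optional
injected spikes.

It does **not** emulate: voxel-level 4-D images, scanner physics or
physiological noise spectra, spatial autocorrelation between
parcellation nodes, hemodynamic variability across regions, or
safety-cue (CS−) trials. Passing tests therefore demonstrate
correctness of the estimators and the validity/power of the permutation
tests under the stated covariance structures — not robustness to the
spatially and temporally structured noise of real fMRI.

Default background FC edges use (A, C, E) = (0, 0.2, 0.8): no genetic
signal with a modest familial (shared-environment) resemblance, which is
the realistic regime for non-heritable connectivity phenotypes in twin
samples.

## Problem sizes and reproducibility

Moment-convergence checks use 2000+2000 pairs (twin correlations within
±0.03), estimator-agreement checks 5000+5000 pairs, error-control
calibrations 200 replicate datasets with 200 permutations each, and the
planted-component study 50 replicates of a 50-node, 150+150-pair
connectome — sizes at which the Monte-Carlo error of each assertion is
well below its tolerance. Every random quantity descends from an explicit
seed; the pipeline derives per-stage substreams by hashing the stage name
with the master seed, so toggling one stage never perturbs another, and
reruns are byte-identical.

## Known limitations

* The LR-SD estimator discards pair-sum information; its per-element h²
  standard error at a few hundred pairs is ≈ 0.2–0.3, so single-edge
  estimates are noisy and threshold-based graph statistics inherit that
  noise. In particular, at low thresholds a matrix with *no* genetic
  signal still binarizes to a dense random graph whose giant component
  spans most nodes; the NBS permutation test remains valid (calibrated)
  in this regime but loses power for small planted components, because
  observed and null giants differ by only the planted edge count.
  Conservative (higher) thresholds restore detection for strongly
  heritable components.
* The boundary-mixture parametric p-value is asymptotic in the pair
  counts; squared differences are skewed, and at very small cohorts the
  cluster-forming threshold is only approximately calibrated (the
  permutation layer above it does not depend on that calibration).
* Heritability of FC contrasts is estimated edge by edge; no shrinkage or
  spatial pooling across edges is attempted.
* No SEM/maximum-likelihood ACE fitting, no dominance (ADE) or
  sex-limitation models, no rater/measurement models.
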