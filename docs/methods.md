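# Methods

`dfcstates` implements a complete dynamic functional connectivity (DFC)
state analysis for parcellated resting-state fMRI: from ROI time courses
to reoccurring connectivity states, state occupancy, stationarity nulls,
mixed-effects brain–behavior association, bootstrap mediation, and
weighted graph topology. Because the class of study it targets uses
restricted cohort data, the package ships a synthetic cohort generator
that plants every quantity the analysis is meant to recover, and the
test suite scores recovery against that ground truth.

## Parcellation

All connectivity matrices are ordered by the packaged 53-ROI
parcellation, grouped into seven functional networks: subcortical
(SC, 5 ROIs), auditory (AUD, 2), sensorimotor (SM, 9), visual (VS, 9),
cognitive control (CC, 17), default mode (DM, 7), and cerebellar
(CB, 4). ROI labels are generic per-network placeholders
(`SM_01` … `SM_09`); the network partition, not the anatomical naming,
is what the computations depend on, and it is verified on every load.

## Post-processing of ROI time courses

Four steps, per ROI column, in fixed order:

1. **Polynomial detrending** (orders 0–3) by projection onto an
   orthonormalized Vandermonde basis, so residuals are exactly
   orthogonal to every polynomial up to cubic.
2. **Nuisance regression** of the six realignment parameters and their
   backward-difference derivatives (first sample zero), plus intercept.
   Rank-deficient designs fall back to the pseudoinverse with a warning.
3. **Outlier repair**: samples whose robust z-score (per-column
   median/MAD, MAD scaled by 1.4826) exceeds 3 are replaced by linear
   interpolation between the nearest clean neighbors; endpoints clamp.
   A column that is majority-outlier is left untouched and flagged —
   repairing it would be inventing data. Repair (rather than frame
   deletion) keeps window indexing uniform across scans.
4. **Band-pass filtering** 0.01–0.15 Hz with a 5th-order Butterworth
   filter applied forward–backward (zero phase). The filter family is a
   numerical choice; the tests pin the behavior through amplitude
   contracts (≥95% passband retention, ≥90% stopband attenuation)
   rather than through implementation details.

Applying the recipe twice reproduces the first pass to well under 1%
RMS on smooth in-band signals away from the filter's edge transients.

## Windowed connectivity

DFC is estimated in a sliding window of 40 TRs (32 s at TR = 0.8 s),
stepped by 1 TR. The taper is the discrete convolution of a 40-sample
rectangle with a Gaussian of σ = 3 TRs (kernel truncated at ±⌈4σ⌉);
the central 40 samples are kept and normalized to unit sum, preserving
the literal window length while down-weighting edges. Within each
window the weighted Pearson correlation is computed for every ROI pair;
the row-major upper triangle (1378 values for 53 ROIs) is the window's
connectivity vector. Correlations are clipped to [−1, 1] against
floating-point spill; a pair with zero weighted variance is set to 0
and flagged. Raw correlations are clustered (no Fisher z by default):
at these correlation magnitudes the transform is nearly affine and
k-means with Euclidean distance is insensitive to it.

## State identification

All windows from all scans are pooled and clustered by k-means
(k-means++, best of 10 restarts, fixed seed). Fractional rate =
percent of a scan's windows assigned to each state, averaged over a
subject's scans. Centroid sets from different fits are matched by the
Hungarian algorithm on cost 1 − Pearson r between centroids, which
makes permutation recovery exact rather than greedy. Split-half
reliability partitions whole sites at random into halves, refits each
half, and reports matched centroid correlations.

### The elbow criterion, formalized

The state count is chosen from the dispersion-ratio curve
score(k) = within-cluster / between-cluster sum of squares. Two facts
shape the rule, both measured on data with known ground truth:

* the raw second difference of score(k) is maximized at the smallest
  interior k whenever the curve decays convexly — which it does even
  for perfectly separated, equal-mass clusters — so curvature alone
  cannot locate the true K;
* windowed-correlation noise is strongly anisotropic, so k-means keeps
  finding splittable structure beyond the true K and the curve never
  goes flat.

The rule therefore works on the scale-free slope-collapse ratio
R(k) = [score(k−1)−score(k)] / [score(k)−score(k+1)] after a
monotonicity repair of the curve:

* if the first step beyond k_min barely improves the score (relative
  drop < 0.27), the structure is judged captured at k_min and k_min is
  returned — two-state cohorts sit at 0.13–0.16 on this statistic,
  five-state and structureless cohorts at 0.32–0.49;
* otherwise the selected k is the **largest** k whose collapse is
  substantial: R(k) ≥ 2.5 (structureless surrogate cohorts never
  exceed ≈2.3 beyond the first interior k) with a leading drop of at
  least 3% of the curve's total decay (so ratios of two near-zero
  fit-noise drops never qualify). Hierarchically structured cohorts
  show a coarse elbow (sparse-versus-connected) before the true one;
  taking the last substantial collapse resolves the fine structure.
* if no k qualifies, the maximal ratio wins; a selection sitting at
  the first interior k with R < 4 is flagged as a weak elbow
  (structureless data lands there at R ≈ 2.2–2.9).

Model-selection sweeps subsample to at most 20 000 windows and run in
single precision on the leading 150 principal components; the variance
orthogonal to the retained subspace is constant in k and is added back
to the within term, so the curve's drop structure is that of the full
space at a fraction of the cost. The final state model is refit at the
chosen k on all windows in double precision.

## Stationarity nulls

The test statistic per ROI pair is the temporal standard deviation of
its windowed correlation. Two surrogate models generate stationary
references that preserve a scan's static structure:

* **VAR bootstrap** — least-squares VAR(p) fit (default p = 1),
  simulated forward driven by i.i.d.-resampled residuals, 100-step
  burn-in discarded; an unstable fit is shrunk to spectral radius 0.98
  with a warning.
* **Phase randomization** — one uniform random phase per positive
  frequency added to *every* column's Fourier transform (DC and
  Nyquist untouched). Common phases, not independent ones: they
  preserve all stationary cross-spectra and hence the static
  correlation structure, which is the null being tested. Power spectra
  are preserved to machine precision.

One-sided p per pair uses the standard surrogate estimator
p = (1 + #{null ≥ observed}) / (1 + n_surr); the summary is the
fraction of pairs with p < 0.05. Type-I error at the nominal 5% level
is verified inside [0.02, 0.08] for both methods on stationary
multivariate-normal scans.

## Brain–behavior association

For each (state, score) cell a linear mixed model is fit by REML:

    occ_state ~ score + age + gender + race + height + weight
                + (1 | site) + (1 | family-within-site)

Race is dummy-coded; a singular nested fit falls back to a site-only
random intercept and flags the result. The score coefficient's
t-statistic is converted to the effect-size correlation
r = t/√(t² + df) and Cohen's d = 2t/√df with df = n − (number of fixed
effects) — the residual-df convention is stated because r and d depend
on it. Benjamini–Hochberg FDR runs over the full states × scores family
by default (per-state available). Failed cells are kept as NaN rows;
a screen never silently drops a comparison.

A practical note on reading screens: with a handful of strong true
associations present, the BH step-up raises the effective threshold for
the remaining cells, and a stray null cell crosses it in roughly one
screen in seven. FDR controls the expected false-discovery proportion,
not per-screen purity; single isolated cells at small |r| should be
read accordingly.

## Mediation

Standard three-variable path model with confounders regressed in every
equation: a from M ~ X + C; b and c′ from Y ~ X + M + C; c from
Y ~ X + C. With identical covariates the OLS identity c = c′ + a·b
holds to machine precision and is asserted. Inference on ab uses
case-resampling bootstrap (rows resampled jointly, preserving covariate
structure) with the bias-corrected (BC, no acceleration term)
percentile interval: z₀ = Φ⁻¹(#{ab* < ab}/B), interval endpoints at
bootstrap quantiles Φ(2z₀ ± z_{1−α/2}); the two-sided p-value is the
smallest α at which the BC interval excludes zero, computed in closed
form as 2Φ(−|2z₀ − Φ⁻¹(F*(0))|). Degenerate resamples are redrawn
with bounded retries. Site/family structure is not modeled inside
mediation (confounders only), matching the three-variable design;
coverage of the 95% interval is verified in [0.92, 0.98] over replicate
datasets. Mediation here quantifies shared covariance along a specified
path; it carries no causal direction claim.

## Graph topology

A state's mean connectivity matrix (per subject: element-wise mean of
windows assigned to the state; a subject who never visits the state is
excluded from that state's comparison, not errored) is split into three
nonnegative-weight graphs: positive max(FC, 0), negative max(−FC, 0),
absolute |FC|, zero diagonal. No thresholding is applied before
metrics. Node strength is the incident weight sum. Path lengths are
inverse weights; global efficiency is the mean inverse shortest-path
length over ordered pairs (complete unit-weight graph ⇒ exactly 1);
local efficiency per node uses the standard weighted formula with
cube-root weighting of the triangle terms on each node's neighborhood
subgraph. Both scale linearly under uniform weight scaling, which is
asserted numerically. Between-state comparisons are paired t-tests per
ROI with BH-FDR across ROIs; zero-variance differences are flagged with
p = 1.

## The synthetic cohort generator

The generator's default parameters are the package's reference study
conditions; every calibration quoted above is measured under them.

**States.** K = 5 planted correlation matrices over the 53 ROIs. State
1 is the "segregated" pattern: strong positive within-network blocks
(sensory networks strongest, 0.65) with negative SM–VS (−0.45) and
VS–CB (−0.40) coupling. State 5 is the "sparse" pattern: a
weak-amplitude (0.14×) block pattern, mean |off-diagonal| ≈ 0.04 —
weak but still a recoverable direction, since the Pearson match of a
recovered centroid to an exactly-zero pattern would be undefined. The
middle states carry their own seeded network-block signatures (random
within-network profile 0.35–0.70; ~60% of network pairs at ±0.25–0.55),
redrawn until every pair of states has off-diagonal pattern correlation
≤ 0.5. Separations are deliberately large: a 40-TR band-limited window
yields correlation sampling noise of ~0.3 per pair, far noisier than
windows of real BOLD with its longer correlation time, and states must
be separable at window level for any recovery to be demonstrable. All
matrices are repaired to positive-definite correlation form by
eigenvalue clipping with unit-diagonal restoration.

**Dynamics.** A reversible first-order Markov chain at window-block
resolution (blocks of 40 TRs, expanded to TR resolution), with
off-diagonal flow between states proportional to π_i π_j (detailed
balance) scaled so the run-averaged mean dwell is 4 blocks ≈ 128 s —
the upper range of reported DFC dwell times, chosen so most sliding
windows are state-pure. The stationary distribution equals the base
occupancy exactly: default (0.12, 0.147, 0.147, 0.147, 0.44) — rare
segregated state (reported range ~8–13%), dominant sparse state
(~39–48%). Dwell requests that are infeasible for a very rare state
are errored for direct calls and feasibility-capped inside subject
simulation (the rare state then dwells single steps).

**Subjects and behavior.** Each subject carries a latent N(0, 1) trait
that shifts the log-odds of segregated-versus-sparse occupancy by
`occupancy_effect` × trait, moving mass strictly between those two
states. Time points are drawn from the current state's multivariate
normal plus isotropic noise (sd 0.15). Behavioral scores couple to the
trait — never to realized occupancy, whose compositional noise would
leak correlation into the untouched middle states — with cognitive
scores negative and psychiatric scores positive, calibrated so the
correlation with realized segregated-state occupancy equals
`assoc_effect_r` (default 0.08, the magnitude scale of reported
brain-wide associations; capped at the attainable maximum). Covariates
(age 9–11 y in months, gender, three-level race, height, weight) have
plausible ranges and small nuisance effects; site and family-within-
site random intercepts (sd 0.15 / 0.20) enter every score. One
designated triple carries the mediation structure on z-scored
occupancy: M = a·occ + …, Y = c′·occ + b·M + … with defaults a = 0.3,
b = −0.3, c′ = −0.36, hence ab = −0.09 and 20% of the total effect
mediated. All randomness flows from one `SeedSequence`; per-subject
streams are spawned children, so cohorts are byte-reproducible.

**What the generator does not emulate** — and therefore what passing
tests do not show about real data: hemodynamic convolution and the
autocorrelation of real BOLD, scanner drift and physiological noise,
realistic motion spikes, within-state temporal autocorrelation (states
are white within dwell), site differences beyond additive intercepts,
and real centroid geometry (planted separations are larger than real
states'; recovery results bound the pipeline's correctness, not its
sensitivity on weakly separated real data).

## Problem sizes and numerical choices

End-to-end validations run at desk scale, sized to finish in minutes on
one core: elbow recovery on ten 60-subject cohorts (T = 380, TR = 0.8);
state/occupancy recovery at 100 subjects; null calibration on 50 scans
(R = 10, T = 500, 99 surrogates); association screens at n = 500;
mediation coverage over 200 datasets × 1000 bootstrap resamples
(a desk-scale stand-in for the 10 000-resample setting used at full
scale). Linear algebra is pinned to one thread in the test harness so
k-means sweeps are bit-reproducible across machines. Tolerances:
positive-definiteness repaired to minimum eigenvalue 10⁻⁴; correlation
clipping at ±1; zero-variance detection at 10⁻¹² relative; k-means ties
broken by lowest inertia then restart order (sklearn's deterministic
seeded behavior).

## Known limitations

* The elbow rule's thresholds (0.27 / 2.5 / 3% / 4) are calibrated on
  this generator's noise class; data with substantially different
  window-noise anisotropy may need recalibration.
* Per-window state assignment is noisy near dwell boundaries; occupancy
  is accurate to a few percentage points, not per-window.
* MixedLM with family-within-site variance components can be slow or
  singular on tiny cohorts; the site-only fallback is flagged, not
  hidden.
* The sparse state's recovered centroid correlates with its planted
  pattern more weakly (r ≈ 0.8) than the strong states' (r ≈ 0.97);
  selection bias of assignment pulls near-origin centroids around.
* Mediation ignores clustering by site/family (as in the three-variable
  design); a cluster bootstrap is not implemented.
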