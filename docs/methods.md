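# Methods

## The analysis this package implements

Severely brain-injured patients recovering from coma cannot be studied
with tractography reliably: lesions and deformations break fibre
tracking and heterogeneous acquisition protocols make tracking results
incomparable across subjects. The atlas-based alternative implemented
here sidesteps tracking entirely. A population-derived probabilistic
bundle atlas states, for every pair of grey-matter regions in a
parcellation, which voxels the connecting white-matter bundle occupies
and how consistently across the atlas population. A subject's structural
connectome is then obtained by averaging their fractional-anisotropy
(FA) map — a voxel-wise scalar in [0, 1] indexing white-matter
microstructural coherence — over each bundle's voxels.

Formally, for subject *i* and region pair (*a*, *b*):

    C_i(a, b) = mean{ FA_i(v) : v in V(a, b) }

where V(a, b) is the bundle's *consistent* voxel set. Two inclusive
filters define it: the edge is kept only if the bundle is present in at
least 80% of the atlas population, and a voxel only if it belongs to the
bundle in at least 90%. The mean is unweighted over the retained voxels
(the filters already encode confidence; weighting by occupancy would
double-count it), and voxels are accumulated in sorted linear-index
order so the result does not depend on how the atlas enumerated them.

The clinical question — which connections' FA tracks functional
recovery? — is answered with Network Based Statistics (NBS). At every
edge an ordinary-least-squares GLM is fit:

    C_i(e) = b0 + b1 * score_i + b2 * age_i + b3 * sex_i + b4 * acqPC1_i + eps_i

with the contrast t-statistic t(e) = c'b / sqrt(s^2 c'(X'X)^-1 c),
s^2 = RSS/(n - rank). The score is a discharge outcome scale: DRS
(Disability Rating Scale, 0 = no disability … 29 = extreme vegetative
state) tested with a negative contrast, or CRS-R (Coma Recovery
Scale – Revised, 0–23, higher = more conscious) tested with a positive
one; in both cases the hypothesis is "stronger connectivity with better
outcome". Edges with t at or above the primary threshold (3.5 by
default) form a graph; its connected components are the candidate
subnetworks, and each component's *extent* (edge count) is referred to
the permutation null distribution of the *maximal* component extent,
which controls the family-wise error rate across the whole network.

## Nuisance covariates and the acquisition PC

Retrospective cohorts mix scanners and protocols. Four acquisition
parameters (TR in ms, TE in ms, number of diffusion directions,
interslice gap in mm) are strongly inter-dependent, so they are
compressed into one covariate: each column is z-scored (their units are
incommensurate, so the PCA is run on the correlation structure) and the
first principal component's per-subject scores are used. The component
sign is fixed so the first column's loading is nonnegative; any fixed
convention leaves the score contrast's inference unchanged, which the
test suite verifies directly.

## Permutation scheme

With nuisance covariates in the model, raw-label permutation is not
exchangeable under the null. The package uses Freedman–Lane residual
permutation, the accepted standard for GLM permutation inference in
neuroimaging: fit the reduced (nuisance-only) model once, permute its
residuals with a seeded generator, add them back to the reduced fit, and
recompute the full-model t-statistics on the reconstituted data. With no
nuisance columns beyond the intercept this is algebraically identical to
permuting the raw rows (asserted in the tests). The p-value estimator is
the add-one form p = (1 + #{null max extent >= observed}) / (1 + N),
which is valid (cannot be anti-conservative in expectation, never
returns zero). Permutations are sampled independently without
deduplication. A threshold sweep (3.3 / 3.5 / 3.7 conventionally) reuses
one permutation sequence: permuted t-statistics are computed once per
permutation and thresholded at every level, so the sweep costs no more
than a single run and results are comparable across thresholds.

Numerical decisions: ties at the primary threshold are suprathreshold
(inclusive), and the null comparison uses >= (conservative). Edges whose
residual root-mean-square falls below 1e-12 of the data's scale are
treated as exactly determined: their t is set to signed infinity with a
warning, and NaN edges never enter the suprathreshold graph. Component
size is edge count (the extent statistic); the intensity variant is not
implemented.

## Diffusion-tensor layer

FA maps are normally produced upstream, but a minimal tensor layer is
included so the whole chain is testable from raw signals. The
single-tensor model S = S0 exp(-b g'Dg) is fit by OLS on the log-signal
against the 7-column design (ln S0 plus the six unique tensor
components) — the simplest consistent estimator; weighted and nonlinear
variants are out of scope. The fit requires at least one b = 0 volume
and six independent directions (rank checked, not silently truncated),
and strictly positive signals (no clamping of inputs). Negative
eigenvalues from noisy fits are clamped to zero only at the FA stage,
with the clamp count logged; an all-zero triple yields FA 0 so
background voxels are well-defined.

The quality screen mirrors automated diffusion QC practice for
uncooperative patients: a scan is excluded when at least two of
{average absolute motion >= 2 mm, average relative motion >= 0.5 mm,
outlier slice percentage >= 2%} hold. Comparisons are inclusive, making
the rule monotone: worsening a metric can never rescue a scan.

## The synthetic cohort generator

No imaging data of such a cohort is distributable, so the generator
produces every input with the statistical structure the analysis
assumes, plus a ground-truth record for oracle checks.

* **Toy atlas** — nodes seated on a jittered lattice, bundles drawn as
  straight voxel tubes, deliberately including edges with presence
  below 0.8 and voxels with occupancy below 0.9 so the consistency
  filters are exercised. Bundles are voxel-disjoint (later bundles drop
  claimed voxels), which makes the forward model exactly invertible:
  painting each bundle uniformly with its designed edge value and
  averaging it back reproduces that value to floating-point precision.
* **Forward model** — edge FA = per-edge baseline (0.5 ± 0.05 jitter)
  + effect_slope × z(score) on the planted edges + nuisance terms
  (−0.0003 FA per centred year of age, 0.005 per sex unit, 0.003 per
  unit of the latent acquisition factor) + i.i.d. Gaussian voxel noise
  (SD 0.02). An optional edge-level shared-noise term exists because
  voxel-level noise shrinks with bundle size, which is only one of the
  two plausible regimes; the residual noise structure of edge FA across
  subjects is a modelling choice, not an empirical fact. Default
  effect_slope is −0.05 FA per SD of DRS: worse outcome, lower FA.
  Defaults keep every painted value far from the [0, 1] clip (the tests
  assert no clipping occurs).
* **Cohort table** — n = 40 subjects; integer scores uniform on the
  DRS range; ages Normal(53.5, 16.4) clipped to 16–84; 40% female;
  etiology and admission-diagnosis frequencies matching a
  neurorehabilitation coma cohort; skewed (lognormal) injury-to-MRI and
  MRI-to-discharge intervals. Acquisition parameters follow a
  one-factor model with loadings (0.97, 0.95, 0.93, 0.90) — strong
  collinearity is the premise of the PCA compression step, and these
  loadings keep corr(PC1 scores, latent factor) above 0.95 at n = 40
  despite integer rounding of the direction count.
* **QC tables** — a chosen fraction of subjects is planted to exceed at
  least two exclusion thresholds and self-labelled, so the screen can be
  checked against the generator's own record.
* **DWI signals** — noiseless or Gaussian-noised signals from known
  SPD tensors for tensor-fit round-trips.

What the generator does **not** emulate: lesions and mass effect,
registration error, eddy/susceptibility artefacts, spatially correlated
noise, or bundle-geometry realism. Passing tests therefore demonstrate
the statistical machinery is correct under its stated assumptions, not
that those assumptions hold in patient data.

## Cohort descriptives conventions

Age is summarised as mean and SD (n − 1 denominator); scores and
intervals as median and IQR. The IQR uses the *midpoint* quantile
convention (average of the two bracketing order statistics), which is
the convention clinical tables of this kind print. Normality is
screened with the plain one-sample Kolmogorov–Smirnov statistic against
a normal with the sample mean and SD (no small-sample correction on D).
Transitional "MCS-" rows count as MCS in diagnosis tallies. The
analysed sample size is taken from the cohort table's row count; the
screening-funnel helper reports stage-wise exclusion counts verbatim
alongside it rather than deriving one from the other.

## Problem sizes used in validation

The test suite and the reproduction script validate the method core at
desk scale: a 12-node toy atlas on a 24³ grid with 18 bundles (14
surviving the presence filter); cohorts of 40 subjects; a planted
6-edge subnetwork at slope −0.05 / voxel noise 0.02; family-wise error
measured over 500 global-null simulations of 40 subjects × 100 edges
with 200 permutations each; exhaustive permutation enumeration at
n = 5 (120 permutations); component extraction checked exhaustively on
all 4-node graphs and on 300 random 8-node graphs. These sizes make
every Monte-Carlo bound explicit in the tests (binomial standard
errors are carried through the assertions).

## Known limitations

* Only the extent (edge-count) component statistic is implemented.
* The tensor fit is unweighted log-linear OLS; no RESTORE/robust
  variants.
* The bundle mean is unweighted; occupancy-weighted means are not
  offered.
* Edge-level missingness is handled by complete-case intersection
  across subjects — with a shared atlas and grid the per-subject masks
  coincide anyway, so this matters only for unusual inputs.
* The atlas container is a simple directory layout (one NIfTI per
  edge); very large parcellations would want a consolidated format.
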