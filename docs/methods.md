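# Methods

`neuromlm` implements a two-level multivariate linear model (MLM) for
block-design task fMRI and the classification of diagnostic groups from
its outputs, together with a synthetic cohort generator that realizes
exactly the generative model the analysis assumes.

## Individual-level model

Per subject, the BOLD data `Y` (scans x voxels) are modeled by a GLM
whose design holds three condition regressors — depression-specific
(DS), paranoia-specific (PS) and diagnostically neutral (DN) statement
blocks, boxcars convolved with a canonical double-gamma HRF (peak delay
6 s, undershoot delay 16 s, unit dispersions, undershoot ratio 1/6,
unit peak, 32 s support) — plus nuisance regressors: six rigid-body
motion parameters, an optional cosine/sine drift pair, and an
intercept.

Temporal autocorrelation is summarized by a single AR(1) coefficient
`rho`, the lag-1 autocorrelation of the OLS residuals pooled over all
in-mask voxels.  A pooled estimate from OLS residuals (rather than an
iterated restricted-likelihood fit) is stable at small problem sizes,
and the coefficient enters the decomposition only through the 3x3
matrix `Xc' S Xc` with `S[t,u] = rho^|t-u|`, which is insensitive to
small estimation error.

The individual MLM is the SVD of the whitened cross-covariance

    Z = (Xc' S Xc)^(-1/2) Xc' Y = U L V',

where `Xc` are the condition regressors after the nuisance columns have
been partialled out of both `Y` and `Xc` (Frisch–Waugh), so the
decomposition lives in exactly three condition-space directions.  `U`
columns are the subject's clinical loadings, `V'` rows the unit-norm
eigenimages, `L` the (descending, non-negative) eigenvalues.  Voxel
time series are mean-centered first (the intercept partialling implies
this; the flag `center` exposes it).  The inverse square root is the
eigendecomposition pseudo-inverse with a relative eigenvalue cutoff of
1e-12; SVD signs are fixed by making the first non-negligible entry of
each `U` column positive, and near-degenerate singular values (relative
gap < 1e-8) are ordered by the lexicographic order of their sign-fixed
`U` columns, so results are deterministic across runs.

Across subjects, component signs are aligned to a reference subject
(index 0 by default): for each rank the sign of the dot product between
subject and reference loading columns is made positive by flipping the
`U` column and `V` row jointly, preserving `U L V'`.

## Group level

For each component rank k, the aligned rank-k eigenimages are stacked
into `Y_G` (subjects x voxels).  Age (centered) and sex (M/F coded ±1)
are regressed out of both `Y_G` and the diagnosis contrast (+1
schizophrenia / −1 depression) together with an intercept, so nothing
downstream can be driven by these confounds; diagnosis is a single ±1
contrast column after residualization.  Subjects are treated as
exchangeable (identity covariance at the group level).

Two coupled decompositions are computed:

- the subject-space SVD `Y_G = U_G L_G V_G'`.  Its first right singular
  vector is the **brain signature** for rank k — the most consistent
  spatial pattern across individuals in variance-explained terms — and
  the projections of the adjusted eigenimages onto it are the
  **subject loadings** (equal to the scaled first left singular
  vector), the per-subject contribution to the signature;
- the design-space cross-covariance `Z_G = (X'X)^(-1/2) X' Y_G` and its
  SVD, whose left factors are the design-space group loadings.  The
  hat-matrix fit of the subject loadings on the reduced design is
  reported as the design projection.

Defining the signature through the stack's own SVD rather than through
`Z_G` is a deliberate design choice.  With a single group contrast,
`Z_G` is proportional to the empirical group-difference image of the
stack; projecting every subject onto that direction feeds each
subject's own noise back into its loading (the self-projection term
dominates by a factor ~ sqrt(voxels/subjects)), so even label-shuffled
data would classify nearly perfectly.  The stack-SVD signature has no
such circularity: on effect-free cohorts the loadings are uncorrelated
with diagnosis (median 2-fold CV accuracy ≈ 0.5), while a genuine group
difference — the largest coherent structure left in the adjusted stack
— is captured as before.

The signature T-map converts the voxelwise Pearson correlation `r`
between subject loadings and stack columns to `T = r sqrt((s−2)/(1−r²))`
with `s − 2` degrees of freedom (s subjects); at s = 30 the one-sided
p < 0.05 threshold is T > 1.70 and p < 0.001 is T > 3.41.  Constant
voxel columns get T = 0 (counted and logged); |T| is capped at 1e4 as
r → ±1.  Cohort-level clinical loadings are reported as the
subject-loading-weighted average of the individual clinical loading
columns, normalized by the total absolute weight.

## Classification

Each rank's subject loadings feed a linear discriminant (pooled
covariance, empirical priors; scikit-learn's SVD solver).  Accuracy is
estimated by stratified 2-fold cross-validation repeated 100 times
(one pooled held-out accuracy per repeat) and summarized by the median
and quartiles (linear-interpolation quantiles).  Stratification keeps
both classes in every training fold at 16/14; a degenerate fold would
be redrawn and logged.  ROC curves use schizophrenia as the positive
class, with tied scores handled by the Mann–Whitney convention; the
reported curve comes from the held-out discriminant scores of one
seeded CV pass, and an in-sample curve is emitted alongside, labeled
as such.

## Synthetic cohorts

The generator produces, per subject, `Y = Xc B' + drift + AR(1) noise`
on a 16x16x8 voxel grid (ellipsoid mask, ~820 voxels, 3 mm affine),
with the study timing: four 32 s active blocks per condition (four 8 s
statements each) cycling DS → DN → PS, 20 s rest after each, and 40 s
lead-in/lead-out rest — 704 s, 352 scans at TR 2 s.  The printed block
arithmetic (12 x 32 s + 12 x 20 s = 624 s) does not reach the stated
total on its own; the lead-in/lead-out rest is the configurable bridge.

`B` encodes three planted components: orthonormal condition-space
directions (a profile matching +DS −PS +DN / +DS +PS −DN / −DS +PS +DN,
orthonormalized), three orthonormal smooth spatial maps (seeded Gaussian
random fields, 1.5-voxel smoothing, QR-orthonormalized), and descending
amplitudes (100, 75, 50 with 0.1 log-normal subject jitter).  `B` is
pre-colored with `(Xc'Xc)^(-1) (Xc' S Xc)^(1/2)` so the planted
components are fixed points of the whitened decomposition: on
noise-free data the individual MLM returns the planted directions, maps
and amplitudes exactly.  The amplitude scale makes the single-voxel
time-series SNR ≈ 0.3, typical of block-design task fMRI.

A diagnosis effect of size delta at rank k tilts that component's
spatial direction by ±(delta/2) along a dedicated unit-norm difference
map orthogonal to all base maps, with opposite signs per group (default
delta = 1 at rank 3, a strong effect consistent with a best-signature
classification near 0.9).  A pure amplitude difference would vanish
under eigenimage unit-normalization; the tilt is precisely the kind of
group structure the eigenimage-stacking group stage can detect.

Noise is stationary AR(1) (rho = 0.3, marginal SD 1); drift is a single
spatially uniform cosine (period 128 s, amplitude 1, random phase),
modeled in the analysis by the cos/sin pair at the same period; motion
files are smoothed low-amplitude random walks used only as nuisance
regressors (they do not corrupt the signal).  Ages are truncated
normals (means 36.4 / 45.3, SD 12.5, range 18–65) and sex counts are
exactly 10/6 and 5/9 per group.  All randomness flows from a single
integer seed through named `SeedSequence` streams, so output is a pure
function of (config, seed).

What the generator does not emulate: hemodynamic nonlinearity,
physiological (cardiac/respiratory) noise, motion-induced signal
artifacts, spatial noise correlations, inter-subject anatomical
variability, and multi-run sessions.  Passing tests therefore show the
pipeline recovers the assumed generative structure, not that it is
robust to every artifact of real fMRI.

## Numerical and calibration notes

- The drift model is the cos/sin pair, not a discrete-cosine high-pass
  basis: with three conditions, each condition's block cycle repeats
  every 156 s, slower than the 128 s drift, so a DCT basis with a
  128 s cutoff would absorb task variance (measured ~25% eigenvalue
  attenuation and cross-rank leakage).
- Degenerate inputs: all-zero residuals, zero contrasts, rank-deficient
  designs and confound matrices, empty masks, non-finite voxels, zero
  loading columns and constant loadings all raise immediately with
  specific messages; constant T-map columns and constant classifier
  scores degrade gracefully (T = 0, AUC = 0.5) with a logged warning.
- Null calibration at n = 30 is inherently noisy: an effect-free cohort
  still has a realized, accidental correlation between loadings and
  labels (SD ≈ 1/sqrt(29)), which repeated CV on the fixed cohort
  genuinely measures.  Null median accuracies are therefore slightly
  upward-skewed (mean ≈ 0.51–0.53, SD ≈ 0.07 across cohorts), and the
  fraction of cohorts whose median falls in [0.35, 0.65] is about
  0.90–0.98 depending on the seed stream.  This mirrors why small-n
  classification accuracies should be read with their dispersion, not
  as point values.
- Problem sizes used in the shipped tests and acceptance script: one
  full study-condition cohort (30 subjects, 16x16x8 grid, 352 scans)
  for recovery, 50 effect-free cohorts for null calibration, and
  2000–4000-voxel single subjects for autocorrelation and F-statistic
  calibration.
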