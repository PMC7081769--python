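# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limitations of `gfcdmap`. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Preprocessing model

BOLD series are assumed already spatially aligned and resampled (3 mm
isotropic by default, TR 3 s). Conditioning runs in the order
**discard → detrend/band-pass → nuisance regression**:

- `discard_initial` removes the first 10 volumes (signal equilibration);
  140-volume acquisitions retain 130.
- `detrend_and_bandpass` restricts each voxel to 0.01–0.1 Hz. The stated
  band is two-sided, so it is implemented as a band-pass. The default
  filter is realized as a single least-squares projection: the voxel course
  is residualized against the span of the constant, the linear ramp, and
  every out-of-band DFT basis vector. A projection is exactly idempotent
  and annihilates out-of-band sinusoids exactly, which makes the filter's
  contract testable to machine precision; a 4th-order zero-phase
  Butterworth is available behind `method="butterworth"` for users who
  prefer a smooth transition band.
- `nuisance_regress` residualizes every voxel on an intercept plus the six
  motion parameters and the mean white-matter and CSF signals. The
  regressors are **not** band-pass filtered before regression, and tissue
  signals are extracted from the *filtered* series — both points are
  under-determined in common pipeline descriptions; the choices are fixed
  here and flagged (`filter_nuisance_regressors` config switch for the
  first).
- Framewise displacement follows the Power convention:
  FD_t = Σ|Δd_i| + r·Σ|Δθ_i| with r = 50 mm (configurable). FD of the
  first frame is 0, and mean FD is computed over post-discard frames.
- Subject-level QC excludes (never censors frames) subjects whose motion
  exceeds 3 mm translation on any axis or 2° rotation, both relative to
  the first frame. Relative-to-first is a choice — raw parameters include
  an arbitrary reference offset that is not motion.

## gFCD

Raw gFCD at voxel x0 is the count of *other* qualified voxels j with
Pearson r(x0, j) strictly greater than 0.6. Choices:

- **Qualified mask**: gray matter ∩ (temporal-mean intensity > 50% of the
  gray-matter grand mean). The "SNR > 50%" criterion is under-specified in
  the field; mean-intensity fraction is the convention of the connectivity
  density literature. The fraction is configurable and logged in the mask
  provenance.
- **Strict inequality** at the threshold; ties at exactly 0.6 do not count.
- **Positive correlations only** by default (r < −0.6 is not a
  connection); `absolute_r=True` selects the alternative reading.
- Self-correlation is excluded; consequently counts lie in [0, V−1] and
  the connection relation is symmetric, so the total count over voxels is
  even — both are tested invariants.
- The O(V²) correlation pass runs in row blocks of standardized courses
  (`r = z_i · z_j`), with exact agreement against a naive per-voxel loop
  enforced in tests. A zero-variance qualified voxel is an error listing
  the offending indices, never a silent NaN.

Grand-mean scaling divides qualified values by their mean (qualified mean
becomes 1 within 1e-10). Smoothing is Gaussian with σ = FWHM/(2√(2 ln 2)),
FWHM 6 mm per axis, applied **after** scaling; only shear-free (diagonal)
affines are supported. `reflect` boundary handling preserves constant maps.

## Voxel-wise and scalar ANCOVA

One shared core (`ols_f_tests`) serves both the voxel-wise and the scalar
analyses, and a test asserts they agree exactly on a 1-voxel image. The
design has an intercept, diagnosis (2 levels, sum-to-zero), genotype
(3 levels, sum-to-zero), their interaction, and covariates. F statistics
are Type-III: F = [(RSS_reduced − RSS_full)/df_effect] / [RSS_full/df_error],
with the reduced model dropping the effect's columns. Type III with
sum-to-zero coding is fixed because Type I and Type III genuinely differ
under imbalance; the implementation is cross-checked against a brute-force
projection oracle and against an independent Type-III ANOVA implementation.
Voxels with zero variance across subjects are excluded from the analysis
mask and counted, since F is undefined there.

Covariates: age, sex, education and mean FD for imaging outcomes; age, sex
and education for cognitive scores; intracranial volume for structural
volumes. Demographics use Kruskal–Wallis across the six cells, except sex,
which uses a contingency chi-square (a rank test is ill-suited to a binary
variable). Post-hoc genotype contrasts are t tests on covariate-adjusted
marginal means, Fisher LSD by default with Tukey HSD selectable.

## Cluster-extent correction

The Monte-Carlo null simulates standard-normal fields on the mask grid,
smooths them to the *estimated residual smoothness*, standardizes within
the mask, and thresholds at the two-tailed |z| quantile of the
cluster-forming p (two-tailed emulates the classic simulator's default; a
one-tailed switch exists). k_min is the smallest k such that the fraction
of null iterations whose largest cluster reaches k is ≤ α. k_min is always
recomputed for the data at hand — published extent thresholds are
properties of a particular mask and smoothness and are never hard-coded.

Residual smoothness per axis comes from the lag-1 spatial autocorrelation
ρ of the model residuals (variance of first differences between in-mask
neighbors): FWHM = d·√(2 ln 2 / −ln ρ) for voxel size d, averaged over
residual maps, with ρ clipped to (1e-8, 1−1e-8) to handle degenerate
fields. This Gaussian-shaped-noise null is the classic formulation; it
does not model heavier-tailed empirical autocorrelation functions, a known
fidelity limit of that formulation.

Cluster connectivity defaults to 26-neighbor (faces+edges+corners), with
6 and 18 selectable and recorded in the report. Cluster peaks are reported
in world (mm) coordinates via the affine; sizes in voxels and mm³.

## Mediation

Three OLS regressions (M ~ X + cov; Y ~ X + M + cov; Y ~ X + cov) give
a, b, c′, c; the decomposition c = c′ + a·b is an algebraic identity of
OLS on a shared sample and is asserted to 1e-10. The bootstrap resamples
whole subject rows (case resampling, preserving the joint X–M–Y–covariate
structure), 10,000 draws by default, vectorized via batched normal
equations. Confidence intervals are bias-corrected percentile (z₀
correction only, the historical default of the common macro; acceleration
is deliberately not applied). The z₀ proportion is clipped to
[1/B, 1−1/B] to keep the normal quantile finite in degenerate resamples.
Genotype enters as an ordinal risk code (ε2+ = 1, ε3ε3 = 2, ε4+ = 3);
the coding is configurable. The battery fits every (mediator, outcome)
pair within one diagnosis group (MCI by default) and reports all CIs
without multiplicity adjustment — adjustment policy is left to the user
and should be stated by them.

A screening regression (genotype term on each cognitive outcome within
each diagnosis group, covariate-adjusted) shortlists outcome candidates,
but a non-significant X→Y association does not bar a mediation test.

## Synthetic cohorts

The generator produces what the downstream stages assume, not realistic
physiology:

- **Hubs**: each hub region shares one latent unit-variance signal; a
  member's course is baseline + σ·(s·latent + ε), ε ~ N(0,1), so two
  members correlate at s²/(s²+1) — chosen for closed-form testability
  (s = 1.25 sits near the 0.6 counting threshold: expected r ≈ 0.61).
  Group and group×genotype effects on connectivity are planted by varying
  s per (diagnosis, genotype) cell.
- **Background noise** is temporally white and, by default, spatially
  independent (preserving the closed form). `spatial_noise_fwhm_mm > 0`
  smooths each frame spatially and restores unit temporal variance per
  voxel, giving the local correlation floor real data has. This matters
  for grand-mean scaling: with no background connections, scaling maps
  every hub to V/(hub size) regardless of strength and erases planted
  effects — a genuine property of grand-mean scaling worth knowing when
  interpreting real data too. Calibration simulations that exercise the
  full chain therefore enable spatial noise, and planted interaction
  designs use an antisymmetric pair of hubs (strength increased in one
  region, decreased in a distant one) so the scaling denominator stays
  flat across cells.
- **Phenotypes**: outcome = cell mean + slopes·(covariate − generative
  mean) + N(0, sd), with cell means and SDs at published cohort scale
  (ADAS13, MMSE, RAVLT, hippocampal volume, …) as plausibility dressing;
  age ~ N(73, 6), education ~ N(16, 2.5) years, sex ~ Bernoulli(0.5).
  Planted mediation triples (a, b, c′) generate M = a·X + N(0,1),
  Y = b·M + c′·X + N(0,1) from the ordinal genotype code.
- **Motion**: 6-parameter random walk, translation increments
  N(0, amplitude²) mm and rotation increments N(0, (amplitude/50)²) rad
  so both contribute comparably to FD; amplitude 0 gives an exactly zero
  trace.
- **Geometry**: spherical brain with a small central CSF core and a
  white-matter shell, diagonal RAS affine with the origin at the grid
  center. A `max_grid_voxels` guard (default 32³ = 32,768) keeps the
  O(V²) connectivity pass desk-scale; it is configurable for larger runs.
- **Determinism**: one root seed sequence spawns per-subject streams;
  NIfTI gzip streams are written with mtime 0, so equal (spec, seed)
  yields byte-identical files.

What passing tests show: the statistics are calibrated (nominal null
rates, CI coverage, FWER control) and effects of the planted form are
recovered *under the generator's assumptions* — white or
short-range-correlated Gaussian noise, linear covariate effects, a shared
latent per hub. They do not certify behavior under hemodynamic structure,
physiological noise, scanner drift beyond a linear trend, registration
error, or multi-site heterogeneity, none of which the generator emulates.

## Problem sizes used in the shipped checks

The shipped test suite and acceptance script size their simulations for a
desk-scale run: gFCD oracle instances up to 1,000 qualified voxels and
50–200 frames; FWER over 200 null cohorts on a 20³ grid with 6
subjects/cell at cluster α = 0.05 (1,000-iteration null); CI coverage over
500 datasets of n = 100 with 2,000 bootstrap draws; planted-interaction
recovery over 25 full-chain replicate cohorts on a 14³ grid. Production
defaults (10,000 bootstrap draws; cluster α = 0.001 with
≥ 10,000-iteration nulls) remain the package defaults.

## Known limitations

- The Gaussian-field Monte-Carlo null understates cluster sizes under
  heavy-tailed spatial autocorrelation (see above); on such data the
  correction can be anticonservative.
- Slice-timing, realignment, and nonlinear normalization are out of scope;
  inputs must be pre-aligned.
- Frame censoring is not implemented (subject-level exclusion only).
- Single-mediator models only; no serial/moderated mediation, no
  sensitivity analysis for unmeasured confounding.
- The smoothness estimator assumes an approximately Gaussian spatial
  autocorrelation and at least two in-mask neighbors per axis.
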