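# Methods

`alpsim` reimplements, as a tested pipeline, the analysis workflow of a
case–control diffusion-MRI study of glymphatic function: chronic-tinnitus
patients versus matched healthy controls, compared on the DTI-ALPS index
and a neuropsychological battery, with covariate-adjusted correlations
between imaging and cognition. Because the underlying patient data are
not deposited, the pipeline is built around (a) summary-statistic entry
points that recompute every published test from printed group means/SDs,
and (b) a synthetic-cohort generator with known ground truth against
which every stage is validated.

## The ALPS model

At the level of the lateral ventricles, projection fibers run
inferior–superior (image z), association fibers anterior–posterior
(image y), and the medullary veins — with their perivascular spaces —
run left–right (image x), perpendicular to both fiber systems. Water
mobility along x in those two ROIs is therefore attributed to
perivascular (glymphatic) transport, and the index

    ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)

contrasts it with the diffusivities perpendicular to both the fibers and
the perivascular axis. Dij are diagonal elements of the fitted diffusion
tensor read in the image frame (not eigenvalues). Subcortical-fiber
diffusivities (Dxx/Dyy/Dzz_sub) are extracted and reported but never
enter the index. An ALPS of 1 means no preferential x-mobility; the
reference study reports 1.52 ± 0.12 in patients vs 1.62 ± 0.14 in
controls.

## Tensor estimation

Single-shell signals follow the monoexponential model
S = s0·exp(−b·gᵀDg). Taking logs gives a linear model with a fixed N×7
design (six tensor elements + ln s0), solved per voxel by ordinary least
squares. OLS is the default because it is deterministic and exact on
noiseless data, which anchors the phantom round-trip contract
(truth → phantom → DWI → fit → ROI extraction reproduces every
diffusivity to < 1e-6 relative at σ = 0; measured ~1e-12). A one-pass
weighted variant (weights = observed signals, the usual
variance-stabilizer for log-transformed magnitude data) is available via
`weighted=True`. Signals below 1e-6 of the voxel's mean b0 signal are
clamped before the log and the voxel is flagged invalid; ROI means use
only valid voxels (positive-definite, finite, unclamped) and warn when
an ROI drops below 50% valid.

The manual radiological review of ROI placement is replaced by an
automated orientation check: per ROI block, the principal eigenvector of
the ROI-mean dyadic tensor (sign-ambiguity-free axis average) must lie
within 20° (configurable) of the expected fiber axis (projection→z,
association→y, subcortical→x).

## Synthetic cohorts

The generator's defaults are the study's conditions: 50 + 50 subjects;
nine regional diffusivities per subject drawn as independent truncated
normals at the published per-group means/SDs; b = 0 and 1000 s/mm² with
32 gradient directions (deterministic golden-angle hemisphere, since
only the counts are fixed by the acquisition); Rician noise
(S' = √((S+ε₁)² + ε₂²)) at SNR s0/σ = 30; demographics and cognitive
scores at the published means/SDs, gender Bernoulli at the published
23/27 split. Phantom: 40×40×20 grid of 2 mm voxels with six 2×2×2 ROI
blocks (projection/association/subcortical × left/right, diagonal
tensors in the image frame) on an isotropic 0.0008 mm²/s background —
deliberately desk-scale.

Two imaging–cognition couplings are injected in the patient group:
ALPS↔TMT-B at r = −0.309 and Dyy_proj↔AVLT at r = −0.413. Each coupled
score is m + r·s·z + s·√(1−r²)·ε, where z is the standardized imaging
truth, so the marginal mean/SD are preserved while the population
correlation equals the target. For Dyy_proj, z is exact (the truth is
normal). For ALPS — a ratio of two independent normal means — the
population moments are computed from the reciprocal-normal moments
E[1/D], E[1/D²] by 80-node Gauss–Hermite quadrature restricted above the
positivity floor; a first-order delta expansion was tried first and
rejected because its ~4% SD underestimate visibly biased the realized
correlation. Covariates (age, gender, education, hearing, GM volume)
are drawn independently of the imaging truths, so marginal and
covariate-adjusted correlations coincide in expectation.

Determinism: per-subject seeds are CRC32 hashes of
"(master seed):(subject index)", so any subject is reproducible in
isolation and repeated runs are byte-identical.

What the generator does *not* emulate: inter-diffusivity covariance
(only marginal summaries are published — consequently the per-subject
ALPS SD of independent draws is ≈ 0.21, larger than the printed 0.119,
and the printed ALPS mean ± SD is deliberately not a generation target);
anatomy, CSF compartments, motion/eddy/Gibbs artifacts (preprocessing is
assumed done upstream); left/right hearing correlation (the average
threshold is computed from independent per-ear draws, so its SD
undershoots the printed 2.40). Passing tests therefore certify the
estimator and statistical machinery under the stated generative model,
not performance on real scanner data.

## Statistics

Continuous group comparisons route by normality: Shapiro–Wilk on each
group (scipy's implementation; the routing rule, not the normality test,
is the procedure of interest), Student's pooled-variance t when both
p ≥ 0.05, otherwise Mann–Whitney U. Pooled (not Welch) t is the default
because, with df = 98, it reproduces the published p-values for Age,
MMSE, MoCA, AVLT, TMT-A, TMT-B and the ALPS row exactly at printed
precision; a Welch flag exists. A handful of published rows (e.g. the
projection-fiber Dyy row's 0.004, where the pooled t gives 0.008) are
*not* reproducible from the printed summaries under any t convention —
consistent with those variables having been Mann–Whitney-routed on the
raw data, which is unavailable; the test suite asserts the mismatch
rather than the published number.

Mann–Whitney: midranks for ties; exact enumeration of all
C(n1+n2, n1) labelings when n1+n2 ≤ 12 (two-sided p as the permutation
probability of a U at least as far from n1·n2/2 as observed — the
permutation distribution is symmetric about that point, ties included);
otherwise a normal approximation with tie-corrected variance,
continuity correction 1/2, and an Edgeworth kurtosis term
γ₂ = −(6/5)(n1²+n2²+n1n2+n1+n2)/(n1n2(n+1)). The kurtosis term matters:
the plain corrected-normal tail deviates from exact enumeration by up to
0.0155 at n1 = n2 = 6, the Edgeworth-corrected one by < 0.002 (both
verified by exhaustive enumeration).

Categorical variables use Pearson's chi-square on the 2×2 table without
continuity correction (df = 1), matching the published gender p = 1 for
identical 23/27 splits.

Partial correlations residualize x and y on an intercept plus covariates
by least squares (rank-transforming first for Spearman), correlate the
residuals, and take p from t = |r|√df/√(1−r²) with df = n − 2 − k. The
k = 5 covariate set (age, gender as 0/1, education, mean hearing
threshold, GM volume) with df = 43 reproduces both published (r, p)
pairs — (−0.309, 0.039) and (−0.413, 0.005) — at printed precision,
which pins down the df convention; Pearson is the default since the
consistency holds under it. A variable exactly explained by the
covariates gets r = 0 (its residual is floating-point noise; correlating
noise would report an arbitrary value).

Bonferroni adjustment is min(1, m·p) with a configurable family; the
diffusivity table (10 rows) is the default family.

Report tables round p half-away-from-zero to the printed precision
(3 decimals, 2 for rows printed with 2) and keep the raw p in machine
output.

## Numerical and protocol choices

- Diffusivity draws truncate at 1e-5 mm²/s; ≥ 6 SD below every default
  mean, so moment distortion is < 0.1% (tested).
- Degenerate inputs: SD = 0 group parameters are allowed (deterministic
  draws used by the noiseless round-trip checks); zero-variance t-tests
  return p = 1 when means agree and raise otherwise; groups of n < 3
  fall back to Mann–Whitney with a warning; single-subject groups yield
  NaN p-values with warnings rather than errors.
- Eigenvectors fix their sign by making the largest-magnitude component
  positive; eigenvalues are sorted descending; FA uses the standard
  normalized eigenvalue-dispersion formula.
- Problem sizes in the test suite and acceptance script: 10,000 subjects
  for coupling recovery (Monte-Carlo SE ≈ 0.01 on r), 2,000 replicates
  for type-I calibration (SE ≈ 0.005), 200 replicates for power at the
  published ALPS effect size, 5,000 subjects for moment recovery —
  chosen so sampling error is small against each check's tolerance
  while runs stay desk-scale. Note the power protocol is the one check
  whose Monte-Carlo resolution (SE ≈ 0.014) is not small against its
  margin: the true routed power at the published effect size is 0.961
  (analytic noncentral-t), so a 200-replicate estimate lands below the
  0.95 line for roughly a quarter of seeds.

## Known limitations

- No tractography, multi-shell or kurtosis models, no VBM/segmentation
  (tissue volumes are consumed as precomputed columns), no DICOM
  ingestion, no automated ROI search on real color-FA maps — ROI masks
  are caller-supplied for real data.
- The simulator's independence assumptions (between diffusivities, and
  between covariates and imaging) are conveniences, not claims about
  physiology; real covariate-confounded data would separate marginal
  from partial correlations, which the generator by design does not.
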