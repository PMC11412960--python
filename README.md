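# alpsim

Synthetic diffusion-MRI cohorts, log-linear diffusion-tensor fitting,
the DTI-ALPS glymphatic index, and the group-comparison / correlation
statistics used in case–control ALPS studies.

## What this is for

The DTI-ALPS index is a non-invasive proxy for glymphatic (perivascular)
function: at the lateral-ventricle level, perivascular spaces run along
the image x-axis, perpendicular to both the projection fibers (z) and
association fibers (y), so

    ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)

where Dij are the diagonal elements of the fitted diffusion tensor in
the image frame within fiber-type ROIs. Lower values indicate reduced
perivascular water mobility, a pattern reported in neurodegeneration
and, in the case–control study this package reproduces, in chronic
tinnitus (patients 1.52 ± 0.12 vs controls 1.62 ± 0.14 at n = 50/50,
with ALPS–executive-function and diffusivity–memory correlations of
r = −0.309 and −0.413 after covariate adjustment).

Since such studies rarely deposit raw scans, `alpsim` gives researchers
two things:

- **summary-statistic machinery** to recompute every published test from
  printed group means/SDs (pooled t, chi-square, partial-correlation
  p-values via the t transform with df = n − 2 − k), and
- **a ground-truth synthetic cohort generator** (tensor phantoms with
  Rician-noise DWI, plus demographic/cognitive tables with injected
  imaging–cognition couplings) against which the full pipeline — tensor
  fit, ROI extraction, ALPS, statistics — is validated end to end.

It is a library first (see `examples/`), with a thin `alpsim` CLI
(`simulate`, `fit`, `alps`, `stats`, `run-all`, `report`) for chaining
the stages from a shell.

## Worked example

```python
import alpsim
from dataclasses import replace

# 1. Recompute a published group comparison from its printed summaries.
res = alpsim.pooled_t_from_summary(1.51839, 0.11933, 50,
                                   1.61730, 0.14277, 50, variable="alps")
print(f"ALPS row: t = {res.statistic:.3f}, df = {res.df}, p = {res.p_two_sided:.6f}")

# 2. Adjusted-correlation p-value at the study's df convention (k = 5).
print(f"TMT-B correlation: p = {alpsim.p_from_r(-0.309, 50, 5):.4f}")

# 3. Noiseless phantom at the patient group means, through the full chain.
params = alpsim.tinnitus_group_params()
params = replace(params, diffusivity_sd={k: 0.0 for k in params.diffusivity_sd})
truth = alpsim.draw_subject_truth(params, alpsim.CouplingSpec(), 0)
geom = alpsim.PhantomGeometry()
field = alpsim.build_tensor_field(truth, geom)
dwi = alpsim.simulate_dwi(field, alpsim.default_gradient_table(), s0=1000.0, sigma=0.0)
fit = alpsim.fit_tensor_loglinear(dwi, alpsim.default_gradient_table())
prof = alpsim.extract_roi_diffusivities(fit, geom.label_mask())
res = alpsim.alps_index(prof)
print(f"phantom ALPS = {res.alps_index:.6f}  "
      f"(numerator {res.numerator:.6g}, denominator {res.denominator:.6g})")
```

prints

```
ALPS row: t = 3.759, df = 98, p = 0.000290
TMT-B correlation: p = 0.0389
phantom ALPS = 1.537500  (numerator 0.000615, denominator 0.0004)
```

The first line is the patient-vs-control ALPS comparison recomputed from
the printed means/SDs — p rounds to 0.000 at three decimals, matching
the published table. The second reproduces the published adjusted
correlation p = 0.039. The third runs a noiseless tensor phantom built
at the patient group means through fitting and ROI extraction: the
recovered index equals the hand-computed value
(0.000615 / 0.000400 = 1.5375 mm²/s over mm²/s, dimensionless) to
machine precision, which is the package's core correctness contract.

A full synthetic study is one call:

```python
cfg = alpsim.SimulationConfig(seed=7)          # 50 + 50 subjects
reports = alpsim.run_all(cfg, "out/")          # simulate -> fit -> ALPS -> stats
print(reports["diffusivity"])                  # per-variable routed tests
```

or from the shell: `alpsim run-all --seed 7 --out out/`.

## Layout

- `src/alpsim/cohort.py` — group parameters, subject truths, phantoms,
  DWI simulation, cognitive-score generation, cohort orchestration
- `src/alpsim/tensor.py` — gradient tables, log-linear tensor fit,
  eigen-decomposition and FA
- `src/alpsim/alps.py` — ROI diffusivity extraction, the ALPS index,
  automated ROI orientation validation
- `src/alpsim/stats.py` — normality-routed two-sample tests,
  chi-square, partial correlations, Bonferroni, report tables
- `src/alpsim/io.py`, `src/alpsim/pipeline.py`, `src/alpsim/cli.py` —
  NIfTI / bval-bvec / CSV / YAML I/O, stage chaining, CLI
- `docs/methods.md` — models, assumptions, parameter choices, limits
- `examples/` — one short narrative script per capability
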