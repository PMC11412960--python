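"""Simulate a two-group cohort and inspect its ground truth.

Draws the study-sized cohort of 50 patients and 50 controls (tables
only, no DWI volumes), then shows that the simulated regional
diffusivities sit where the group parameters put them and that patients
carry a lower true ALPS index on average than controls.
"""

import alpsim

cfg = alpsim.SimulationConfig(seed=42, write_dwi=False)
bundle = alpsim.simulate_cohort(cfg)

print("cohort table (first rows):")
print(bundle.cohort[["subject_id", "group", "age", "avlt", "tmt_b"]].head())

truth = bundle.truth
for group in ("tinnitus", "HC"):
    g = truth[truth["group"] == group]
    print(f"\n{group}: true ALPS mean = {g['alps_true'].mean():.4f}, "
          f"Dyy_proj mean = {g['dyy_proj'].mean():.6f} mm^2/s")

# Patients are generated around published summaries (ALPS numerator
# 0.000615/denominator 0.000400 -> population ratio ~1.56 with spread
# from the independent per-diffusivity draws); controls sit higher.
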