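"""One subject end to end: phantom -> DWI -> tensor fit -> ALPS.

Builds a noisy (SNR 30) DWI acquisition from a known tensor phantom,
fits the tensor field by log-linear least squares, extracts the
fiber-type ROI diffusivities, checks ROI orientation, and compares the
measured ALPS index with the subject's ground truth.
"""

import alpsim

params = alpsim.tinnitus_group_params()
coupling = alpsim.CouplingSpec()
geom = alpsim.PhantomGeometry()
gtab = alpsim.default_gradient_table()  # b = 0 + 32 directions at b = 1000

truth = alpsim.draw_subject_truth(params, coupling, rng_seed=3)
field = alpsim.build_tensor_field(truth, geom)
dwi = alpsim.simulate_dwi(field, gtab, s0=1000.0, sigma=1000.0 / 30, rng_seed=4)

fitted = alpsim.fit_tensor_loglinear(dwi, gtab)
roi = geom.label_mask()
profile = alpsim.extract_roi_diffusivities(fitted, roi)
checks = alpsim.validate_roi_orientation(fitted, roi)
result = alpsim.alps_index(profile, orientation=checks)

print(f"true ALPS      = {truth.alps_true:.4f}")
print(f"measured ALPS  = {result.alps_index:.4f}")
print(f"Dyy_proj: true {truth.diffusivities['dyy_proj']:.6f}, "
      f"measured {profile.dyy_proj:.6f} mm^2/s")
for c in checks:
    print(f"ROI {c.label} ({c.fiber}-{c.side}): expected axis {c.expected_axis}, "
          f"angle {c.angle_deg:.1f} deg, pass={c.passed}")

# At SNR 30 the ROI-mean diffusivities land within a few percent of
# truth, so the measured index tracks the true one closely; all six
# orientation checks pass because the phantom's fibers are axis-aligned.
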