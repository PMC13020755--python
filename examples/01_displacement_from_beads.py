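"""Recover a substrate displacement field from a bead-image pair.

Builds a small synthetic experiment (a contractile dipole on a 20 kPa
gel), renders relaxed/tensed bead images, removes drift, and runs TV-L1
optical flow.  Prints the recovered displacement statistics next to the
ground truth.
"""

import numpy as np

from tfmkit import (
    BeadImagePair,
    DipoleScenario,
    ElasticSubstrate,
    FlowParams,
    VectorField2D,
    compute_flow,
    drift_correct,
    field_correlation,
    forward_displacement,
    make_dipole_traction,
    render_bead_image,
    warp_image,
)

pixel_size = 0.108  # µm/px (60x objective, 6.5 µm camera pixel)
shape = (256, 256)

spec = DipoleScenario(total_force=0.01, pole_separation=14.0, region_radius=2.0)
traction, _ = make_dipole_traction(spec, shape, pixel_size)
disp_um = forward_displacement(traction, ElasticSubstrate(E=20_000, nu=0.5))
gt = VectorField2D(disp_um.u / pixel_size, disp_um.v / pixel_size, pixel_size, "px")

rng = np.random.default_rng(0)
relaxed = render_bead_image(shape, pixel_size, rng=rng)
tensed = warp_image(relaxed, gt)

pair, drift = drift_correct(BeadImagePair(tensed, relaxed, pixel_size))
flow = compute_flow(pair, FlowParams(lam=0.1, n_scales=4, warps=5))

print(f"estimated drift: ({drift[0]:+.2f}, {drift[1]:+.2f}) px")
print(f"max |u|: true {gt.magnitude().max():.3f} px, "
      f"recovered {flow.magnitude().max():.3f} px")
print(f"magnitude correlation with ground truth: "
      f"{field_correlation(flow, gt):.4f}")
# The correlation is the standard per-scenario accuracy summary: ~0.99
# means the recovered field reproduces the spatial displacement pattern.
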