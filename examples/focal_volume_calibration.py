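"""Calibrate the confocal focal volume with a reference dye.

A noiseless Alexa-647-like curve (D = 330 um^2/s at 25 C) is fitted with
the single-component 3D diffusion model; the fitted diffusion time
converts to the lateral focal radius via w_xy = sqrt(4 D tau_D).
"""

from oligofib.fcs import calibrate_focal_volume, diffusion_coefficient
from oligofib.synthetic import generate_fcs_curve

curve = generate_fcs_curve("alexa647")
focal = calibrate_focal_volume(curve, d_ref=330.0)
print(f"calibrated w_xy = {focal.lateral_radius * 1000:.1f} nm (expected ~300 nm)")

# with the calibrated volume, the monomer/oligomer cutoff of 150 um^2/s
# corresponds to a diffusion time of:
tau_cut = focal.lateral_radius**2 / (4 * 150.0)
print(f"D = 150 um^2/s corresponds to tau_D = {tau_cut * 1e6:.0f} us")
print(f"round trip check: D(tau_cut) = {diffusion_coefficient(tau_cut, focal):.1f} um^2/s")
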