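"""Simulate a compressed-breast acquisition and estimate its glandular map.

Builds a 4 cm breast with 30% glandular fraction, projects it under the
broad W/Al 28 kV beam with an anti-scatter grid, runs the two-step
maximum-likelihood pipeline, and compares the per-pixel estimates with the
traced ground truth.
"""

import numpy as np

from glandfrac import ProjectionGeometry, apply_asg, build_phantom, compute_vgf, simulate_projection
from glandfrac.evaluate import study_spectrum
from glandfrac.gf import estimate_gf_from_sim

geom = ProjectionGeometry()                 # 70 cm SDD, 20x15 cm detector, 1 mm pixels
spectrum = study_spectrum("W/Al")           # 14-28 keV, 2 keV bins
phantom = build_phantom(thickness=4.0, gf_target=0.3)

img = simulate_projection(phantom, geom, spectrum, counts_per_pixel_flatfield=30000,
                          seed=0)
img = apply_asg(img, removal_fraction=0.75, seed=1)   # grid keeps 25% of scatter

est = estimate_gf_from_sim(img, ref_glandular_fraction=0.3)
interior = img.paths.glandular_interior(erode_px=2) & est.mask
truth = img.paths.m_true

err = (est.m[interior] - truth[interior]) * 100
vgf = compute_vgf(est, img.paths.t_breast)

print(f"working effective energy : {est.meta['e_eff']:.2f} keV")
print(f"mean GF over glandular interior : {est.m[interior].mean():.4f} "
      f"(truth {truth[interior].mean():.4f})")
print(f"per-pixel error : bias {err.mean():+.2f} pp, RMSE {np.sqrt((err**2).mean()):.2f} pp")
print(f"volume glandular fraction : {vgf.vgf:.4f}")
# The bias is the systematic part (scatter model + effective energy); the
# RMSE is dominated by Poisson noise at ~30k flat-field counts per pixel.
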