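"""Quantify invasion on a synthetic spheroid with a known answer.

Builds a disk spheroid (r0 = 50 px) whose Day-2 image adds a uniform
ring of invading pixels out to r1 = 60 px, runs the full quantification
(boundary segmentation, centroid alignment, outer-pixel distances), and
compares the results with the closed-form ring integrals.
"""

from spheroquant import Annulus, Disk, FixtureSpec, generate_pair
from spheroquant.pipeline import quantify_pair

spec = FixtureSpec(
    image_shape=(161, 161),
    pixel_size_um=1.0,
    spheroid=Disk(50.0),
    invasion=Annulus(50.0, 60.0),
)
day0, day2, truth = generate_pair(spec)
rec = quantify_pair(day0, day2, directionality=False)

print(f"outer pixels          : {rec['n_outer_pixels']}")
print(f"area change (mm^2)    : {rec['delta_area_mm2']:.6f}  (truth {truth['delta_area_mm2']:.6f})")
print(f"mean distance (px)    : {rec['mean_distance_mm'] * 1e3:.4f}  "
      f"(ring integral {truth['mean_distance_px_continuum']:.4f})")
print(f"radial moment I_r (px^4): {rec['I_r_mm4'] / 1e-12:.1f}  "
      f"(ring integral {truth['I_r_px4_continuum']:.1f})")
print()
print("The mean distance and I_r land within rasterization error (<1%) of the")
print("analytic ring values: every pixel past the Day-0 boundary contributes")
print("its ray distance d, and I_r = sum(d^2 * dA) weights far invaders quadratically.")
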