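"""Build a digital dermis phantom and simulate its diffuse reflectance.

Creates the standard 30 x 30 x 10 mm dermis block with a 2 mm-radius
pigmented cap reaching 1 mm depth, runs the Monte-Carlo forward model for
one illumination point and prints the photon budget bookkeeping and the
radial falloff of the re-emitted light.
"""

import numpy as np

from mdoi import SourceSpec, run_mc, table1_phantom

phantom = table1_phantom(depth_mm=1.0)
print(f"phantom: shape {phantom.shape}, voxels {phantom.voxel_size} mm, "
      f"{int(phantom.feature_mask.sum())} feature voxels")

src = (24.25, 24.25)  # plain dermis, away from the feature
result = run_mc(phantom, SourceSpec(src), n_photons=50_000, seed=7)
print(f"weight fractions: reflected {result.reflected_total:.4f}, "
      f"absorbed {result.absorbed_total:.4f}, "
      f"transmitted {result.transmitted_total:.2e} "
      f"(sum {result.weight_sum:.12f})")

xs = (np.arange(60) + 0.5) * 0.5
X, Y = np.meshgrid(xs, xs, indexing="ij")
rho = np.hypot(X - src[0], Y - src[1])
print("radial reflectance per voxel (the diffuse halo the camera sees):")
for lo in (0.5, 1.5, 3.0, 6.0):
    ring = (rho >= lo) & (rho < lo + 0.5)
    print(f"  rho {lo:.1f}-{lo + 0.5:.1f} mm: {result.reflectance_map[ring].mean():.3e}")
# The halo drops ~4 decades over 6 mm: that dynamic range is why the
# acquisition uses an HDR exposure ladder.

on_feature = run_mc(phantom, SourceSpec((15.25, 15.25)), n_photons=50_000,
                    seed=7)
print(f"illuminating the pigmented cap instead: reflected "
      f"{on_feature.reflected_total:.4f} vs {result.reflected_total:.4f} "
      f"on dermis — the melanin-level absorption quenches the halo, "
      f"which is the contrast the method reconstructs")
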