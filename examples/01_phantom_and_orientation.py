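"""Generate a synthetic LV, render an imaging volume, and recover the fibres.

Builds an annular phantom with the normal transmural helical-angle law
(+90° endocardium → −50° epicardium), renders an HREM-like striated texture,
runs the structure tensor and reports how well the known fibre axes are
recovered.
"""

import numpy as np
from scipy import ndimage

from myoarch import PhantomSpec, make_vector_phantom, render_intensity, structure_tensor

spec = PhantomSpec(
    inner_radius_um=300, outer_radius_um=500, lv_length_um=800,
    voxel_um=10.0, stripe_period_um=30.0,
    ha_endo_deg=90.0, ha_epi_deg=-50.0, ia_base_deg=0.0, ia_apex_deg=0.0,
    geometry="annulus", seed=1,
)
gt = make_vector_phantom(spec)
vol = render_intensity(gt)
print(f"phantom volume {vol.shape} at {vol.spacing_um[0]:.2f} um/voxel, "
      f"{gt.mask.n_voxels()} myocardial voxels")

st = structure_tensor(vol, gt.mask, window_voxels=5, gradient_sigma_um=7.0)
interior = ndimage.binary_erosion(gt.mask.data, iterations=3)
m = interior & st.valid & gt.frames.valid
dots = np.abs(np.sum(st.v3 * gt.fiber_field, axis=-1))[m]
err = np.degrees(np.arccos(np.clip(dots, 0, 1)))
print(f"angular error between estimated and true fibre axes: "
      f"median {np.median(err):.2f} deg, 90th percentile {np.percentile(err, 90):.2f} deg")
# A median of a few degrees means the tensor's smallest-eigenvalue eigenvector
# tracks the myocyte long axis faithfully at this voxel size and texture scale.
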