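"""Detect and localise a planted region of myoarchitectural disarray.

Compares a clean annular phantom against the same phantom with a spherical
lesion of randomly oriented fibres, and shows that the disarray index (MDI)
drops only in the lesion's host segment.
"""

import dataclasses
import warnings

import numpy as np

from myoarch import (
    GRID45,
    LesionSpec,
    PhantomSpec,
    assign_segments,
    make_vector_phantom,
    mdi,
    orientation_from_vectors,
    summarize_mdi,
)

spec = PhantomSpec(
    inner_radius_um=300, outer_radius_um=500, lv_length_um=800,
    voxel_um=10.0, stripe_period_um=30.0, geometry="annulus",
    ha_endo_deg=90.0, ha_epi_deg=-50.0, ia_base_deg=0.0, ia_apex_deg=0.0, seed=8,
)
lesioned = dataclasses.replace(spec, lesions=(LesionSpec((94, 54, 40), 80.0),))

gt_clean = make_vector_phantom(spec)
gt_les = make_vector_phantom(lesioned)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    segments = assign_segments(gt_clean.mask, gt_clean.axis, GRID45, frames=gt_clean.frames)

for label, gt in (("clean", gt_clean), ("lesioned", gt_les)):
    orient = orientation_from_vectors(gt.fiber_field.copy(), gt.frames.valid)
    dmap = mdi(orient, gt.mask)  # 9×9×9 neighbourhood = 90 um at this voxel size
    summary = summarize_mdi(dmap, segments)
    worst = summary.by_segment.nsmallest(3, "mean_mdi")
    print(f"{label}: global mean MDI {np.nanmean(dmap.mdi):.3f}; lowest segments:")
    for row in worst.itertuples():
        print(f"   level {row.level} sector {row.sector}: mean MDI {row.mean_mdi:.3f} "
              f"({100 * row.frac_low:.0f}% of voxels below 0.5)")
# The clean phantom sits at MDI ≈ 1 everywhere; the lesion pulls its host
# segment's mean down sharply and fills it with sub-0.5 (focal-disarray)
# voxels while all other segments are untouched.
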