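"""Compare disarray between two phantom cohorts, as in a mutant-vs-wild-type study.

Builds two seeded six-specimen cohorts — one clean, one carrying disarray
lesions — measures each specimen's mean MDI, and runs the normality-gated
group test plus the two-sample Kolmogorov-Smirnov comparison.
"""

import dataclasses

import numpy as np

from myoarch import (
    LesionSpec,
    PhantomSpec,
    compare_groups,
    make_vector_phantom,
    mdi,
    orientation_from_vectors,
)

BASE = PhantomSpec(
    inner_radius_um=300, outer_radius_um=500, lv_length_um=400,
    voxel_um=10.0, stripe_period_um=30.0, geometry="annulus",
    ha_endo_deg=90.0, ha_epi_deg=-50.0, ia_base_deg=0.0, ia_apex_deg=0.0,
)
LESIONS = (
    LesionSpec((94, 54, 20), 90.0, seed_offset=1),
    LesionSpec((13, 54, 20), 90.0, seed_offset=2),
)


def specimen_mean_mdi(seed: int, lesioned: bool) -> float:
    spec = dataclasses.replace(BASE, seed=seed, lesions=LESIONS if lesioned else ())
    gt = make_vector_phantom(spec)
    rng = np.random.default_rng(seed + 500)  # per-specimen biological variability
    fib = gt.fiber_field + 0.06 * rng.standard_normal(gt.fiber_field.shape)
    fib /= np.maximum(np.linalg.norm(fib, axis=-1, keepdims=True), 1e-12)
    orient = orientation_from_vectors(fib.astype(np.float32), gt.frames.valid)
    return float(np.nanmean(mdi(orient, gt.mask).mdi))


clean = [specimen_mean_mdi(s, False) for s in range(6)]
lesioned = [specimen_mean_mdi(100 + s, True) for s in range(6)]
res = compare_groups({"clean": clean, "lesioned": lesioned}, metric="mean MDI")

for g in res.groups:
    print(f"{g}: mean MDI {res.means[g]:.3f} ± {res.sds[g]:.3f} (n=6)")
print(f"test: {res.test}, statistic {res.statistic:.2f}, p = {res.p:.2g}")
print(res.ks.to_string(index=False))
# The lesioned cohort's mean MDI sits measurably below the clean cohort's and
# the KS p-value falls under 0.05: the disarray burden separates the groups.
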