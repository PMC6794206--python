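# myoarch

Quantification of three-dimensional cardiac myoarchitecture from
micro-resolution image volumes (high-resolution episcopic microscopy,
micro-CT and comparable modalities).

Cardiomyocytes in a healthy ventricle form a smoothly rotating helical
lattice: fibres run right-handed (+90° helical angle) at the endocardium,
circumferentially (0°) in the mid-wall, and left-handed (≈ −50°) at the
epicardium. Hypertrophic cardiomyopathy disturbs this order — myocyte
*disarray* — before any wall thickening is measurable. `myoarch` turns a
grayscale ventricular volume into quantitative maps of that architecture:

- **Orientation** — the 3D structure tensor J = ⟨∇I ∇Iᵀ⟩ per voxel; its
  smallest-eigenvalue eigenvector **v₃** (defined up to sign) is the myocyte
  long axis.
- **Angles** — in prolate spheroidal local frames (g₁ transmural, g₂
  longitudinal, g₃ circumferential): helical angle α_H = arcsin(v₃·g₂) and
  intrusion angle α_I = arcsin(v₃·g₁), with per-ray phase unwrapping that
  expands the α_H range from [−90°, +90°] to [−90°, +150°).
- **Transmural profiles** — per-segment linear fits y = β₁x + β₀ of α_H
  against wall depth in μm; β₁ (°/μm) and R² summarise the helix gradient and
  its linearity.
- **Disarray index (MDI)** — mean |v₃(c)·v₃(n)| over a 9×9×9-voxel
  neighbourhood (49.3 μm at 5.48 μm voxels): 1 for parallel myocytes, 0.5 for
  random axes, ≪ 1 in disarray.
- **Segment models** — AHA 16-segment and a finer 45-segment model (5 levels ×
  9 sectors, each split into four transmural layers), wall thickness by nine
  radial caliper spokes per level, bullseye plots, and MDI–wall-thickness
  correlation.
- **Tractography** — midpoint (RK2) streamlines through the sign-ambiguous v₃
  field, exported as VTK polylines.
- **Phantoms** — synthetic left ventricles (cylindrical annulus or half
  prolate spheroid) with prescribed angle laws, striated texture and planted
  disarray lesions, so every stage is validated against known ground truth.

## Worked example

```python
import warnings
from myoarch import PhantomSpec, run_pipeline

spec = PhantomSpec(seed=42).scaled_to_grid(96)   # mouse-scale LV in a 96³ grid
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    bundle = run_pipeline({"phantom_spec": spec}, out_dir="out")

print(bundle["axis"].lv_length_um)               # 2300
seg = bundle["mdi_summary"].by_segment
print(round(seg.mean_mdi.mean(), 3))             # 0.896
good = [p for p in bundle["profiles"] if not p.insufficient]
print(round(sum(p.beta1 for p in good) / len(good), 3))   # -0.291
```

The phantom is a healthy-pattern ventricle (helical angle +90° → −50°
transmurally, wall ≈ 500 μm). The pipeline recovers a mean helix gradient of
−0.29 °/μm — the analytic −140°/500 μm — with mean R² 0.94, and a mean MDI of
0.90 (ordered myocardium; an isotropically disordered region would sit near
0.5). The bundle directory holds the α_H/α_I/MDI maps (NIfTI), per-segment
CSV tables, bullseye plots, fibre tracks (VTK) and a JSON manifest; rerunning
the same configuration reproduces the CSVs byte for byte.

The `examples/` scripts walk through each capability: phantom + orientation
recovery (`01`), the full pipeline (`02`), lesion detection with MDI (`03`),
tractography (`04`) and cohort comparison (`05`). A thin CLI wraps the same
functions: `myoarch phantom | preprocess | run | compare`.

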