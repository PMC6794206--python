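# Methods

This note records the models, conventions and numerical choices behind
`myoarch`, and what its phantom-based validation does and does not show.

## Coordinate conventions

Volumes are indexed `[x, y, z]` with `z` the stack axis; the ventricular base
sits at low `z` and the apex at high `z`. Voxel indices are 0-based; the
physical position of a voxel centre is `origin + index · spacing`, all
lengths in micrometres. Analysis requires isotropic voxels; anisotropic
stacks are trilinearly resampled so the section axis matches the in-plane
pixel edge (e.g. 30.03 μm² pixels with 3 μm sections become 5.48 μm cubic
voxels). Masks use nearest-neighbour resampling to avoid label bleeding.

## Segmentation

"Automatic segmentation" is implemented as Otsu thresholding, retention of
the largest connected component (plus any component above a configurable
voxel count), a 1-voxel-radius morphological closing, and 3D hole filling.
The volume is edge-padded around the closing so structures touching the
volume border (the open base) are not eroded, and 3D filling leaves the
ventricular cavity — which reaches the border through the base — open. All
three parameters are recorded in the mask's provenance string.

## Local frames and transmural depth

The LV long axis comes either from user landmarks (base and apex points) or
from the principal axis of the mask voxel cloud, oriented by the
base-at-low-z convention. The principal-axis fit assumes the long axis
dominates the cloud's spread; squat geometries (height below the diameter)
need landmarks.

Local frames are the normalised coordinate basis of a prolate spheroid
aligned with the axis and centred on the base plane: g₁ = ∂x/∂λ (transmural,
outward), g₂ = ∂x/∂μ (longitudinal, apex→base), g₃ = g₁ × g₂
(circumferential; the triad is right-handed by construction). The semi-foci
distance is estimated as f = √(L² − R²) from LV length L and the basal
epicardial radius R (99th percentile of in-mask radii in the basal 15% of the
axis) unless supplied; it is recorded in the pipeline manifest. A cylindrical
frame variant (g₁ radial, g₂ = −axis) is exact for annular test phantoms.
Voxels on the axis, where the circumferential direction is undefined, are
flagged invalid.

Normalised transmural depth is geometric rather than a function of λ:
`depth = d_endo / (d_endo + d_epi)`, with the two distances taken from
Euclidean distance transforms of the cavity and exterior background
components (the cavity is identified by flood fill seeded on the long axis).
This keeps depth in [0, 1] even where the spheroid fit is imperfect. The sum
`d_endo + d_epi` also serves as the local wall thickness used to convert
depth to physical μm in profile fits; it carries a positive bias of roughly
one voxel (distances are measured between voxel centres), about 2–4% for the
walls considered here.

## Segment models, layers, wall thickness

Levels split the long-axis span of the mask into equal bands — basal/mid/
apical (6/6/4 sectors, apical cap not analysed) for the AHA-16 model, five
levels of nine sectors for the 45-segment model. Sector 1 is centred on a
configurable reference angle (anatomical registration of the anterior sector
is study-specific). The four transmural layers (inner, mid-inner, mid-outer,
outer) are per-segment quartiles of the depth distribution, so each layer
holds a quarter of its segment's voxels; equal-thickness shells would
systematically over-populate outer layers because voxel count grows with
radius. An optional truncation parameter excludes the basal- and apical-most
fraction of the span from labelling (default 0, so segment labels partition
the mask).

Wall thickness is measured by nine radial caliper spokes at each of five
levels: rays cast from the slab's cavity centroid at the sector-centre
angles, thickness being the distance between the endocardial and epicardial
crossings (quarter-voxel sampling), also reported normalised to LV length.
Rays that miss the myocardium yield NaN entries and a warning.

## Structure tensor

Gradients are Gaussian derivatives at scale one voxel (configurable); their
outer products are averaged over a cubic window (default 3³ — the voxel and
its 26 neighbours) and eigen-decomposed with `numpy.linalg.eigh`. Eigenvalues
are reported descending; v₃, the smallest-eigenvalue eigenvector, is the
direction of least intensity variation, i.e. the myocyte long axis, defined
up to sign. Voxels whose leading eigenvalue falls below 10⁻⁶ of the volume
maximum carry no orientation signal and are flagged invalid.

A window must span more than one texture correlation length to constrain the
tensor: with striations at ~3 voxels, a 3³ box sees essentially one gradient
patch, the averaged tensor is near rank-1, and v₃ floats in its null plane
(≈ 3° median error even for ideal textures). The validation protocol
therefore uses a 5³ window with gradient scale 0.7 voxel; with it, the
estimator recovers phantom fibres with ≈ 2.6° median error noise-free and
≈ 4° at 10% added noise on 5.48 μm voxels.

## Angles, unwrapping, profiles

With the sign of v₃ resolved toward +g₃ (toward +g₂ where v₃ ⊥ g₃), the
helical angle is arcsin(v₃·g₂) and the intrusion angle arcsin(v₃·g₁);
positive helical angle is a right-handed endocardial helix, positive
intrusion points toward the epicardium. Raw helical angle wraps at ±90°
where fibres pass through the longitudinal direction; voxels are grouped
into thin transmural rays (3° circumferential × 2-voxel longitudinal bins),
ordered endo→epi, and shifted by 180° wherever consecutive samples jump by
more than 90°. Because the continuity pass anchors on the ray's first
sample — adjacent to the +90° pole, where raw values are least reliable —
each ray is then re-anchored by the global multiple of 180° that brings the
most samples into the [−90°, +150°) dynamic range before clipping to it.

Transmural profiles are per-segment means of unwrapped helical angle in 20
equal depth bins, mapped to physical μm through the segment's mean wall
thickness, and fit by ordinary least squares; the slope β₁ is reported in
°/μm. R² is defined as 0 for a zero-variance response. Segments with fewer
than five populated bins are flagged insufficient. The circumferential
fraction counts voxels with −10° < α_H < +10° (strict) among valid voxels.
Angle histograms use 5° bins and normalise to unit mass; distributions are
compared with the two-sample Kolmogorov–Smirnov test.

## Disarray index

MDI at a voxel is the mean of |v₃(centre)·v₃(neighbour)| over the valid
in-mask neighbours in a cube of side 9 voxels, excluding the centre itself
(its self-term is identically 1 and would inflate the index; a flag restores
it for sensitivity analyses). The kernel is pluggable — the absolute-cosine
mean is the minimal statistic with the required properties (range [0, 1],
1 for collinear fields, 0 for orthogonal neighbours, invariance to the
eigenvector sign) — and the neighbourhood is clipped at the mask boundary
with a ≥ 50% valid-neighbour rule so boundary voxels do not report inflated
noise. For uniformly random 3D axes E|cos θ| = 1/2, so a fully disordered
region sits at 0.5. Means are aggregated per segment and per segment-layer,
together with the fraction of focal-disarray voxels (MDI < 0.5). Per-layer
Pearson correlations against normalised wall thickness are reported with raw
two-sided p-values (no multiplicity correction).

## Tractography

Streamlines integrate the v₃ field with the midpoint (2nd-order Runge–Kutta)
rule, bidirectionally from each seed (default: a regular in-mask grid),
default step half a voxel edge. The field is axial, so sign is carried along
the path: sampled vectors, and each trilinear-interpolation corner vector,
are flipped to within 90° of the incoming direction before blending. Tracks
terminate on mask exit, invalid voxels, or a length cap. On an analytic
circular field the loop-closure error scales as step² (measured log-log
slope ≈ 1.9 over steps C/128 … C/1024). Tracks are written as legacy ASCII
VTK polydata with a per-point scalar (fibre z-component or a supplied
array); the writer is ~30 lines of text output and a matching reader backs
the round-trip tests.

## Group statistics

Cohort metrics are compared with a Shapiro–Wilk normality gate (all groups
at the 0.05 level) selecting one-way ANOVA with Tukey's post-hoc test, or
the Kruskal–Wallis test otherwise; distributions are compared pairwise by
two-sample Kolmogorov–Smirnov. Significance is two-sided at 0.05; no
correction is applied beyond Tukey. Groups of size one yield descriptive
statistics only.

## Synthetic phantoms

Two shell geometries: a cylindrical annulus (cylindrical frames exact —
every unit test has a closed form) and a half prolate spheroid (epicardial
half-ellipsoid with equatorial radius R_out and polar extent L; endocardial
semi-axes reduced by the wall; transmural depth solved per voxel by
bisection on the interpolated-ellipsoid family). The fibre at depth d and
normalised long-axis position t is
`cos IA · (cos HA · g₃ + sin HA · g₂) + sin IA · g₁` with HA(d) linear from
ha_endo to ha_epi and IA(t) linear from base to apex; stored angle maps are
re-measured from the constructed vectors, so field and maps agree under the
frame definitions by construction (exactly, when the other law is zero).
Spherical lesions overwrite fibres with uniformly random axes or a fixed
rotation about g₁. Defaults mirror the targeted acquisitions: 5.48 μm
voxels, LV length 2300 μm, wall 500 μm, helical law +90° → −50°, intrusion
+10° → −10°, striation period 16.4 μm (≈ 3 voxels, the myocyte width scale).
One integer seed drives named generators (texture, noise, per-lesion) via
fixed offsets; identical specifications give bit-identical outputs.

**Texture model.** No forward image model exists for this modality, and a
global sinusoidal phase orthogonal to a spatially varying fibre field is not
integrable (no seam-free phase function exists on an annulus). The renderer
instead band-passes white noise at the striation period (difference of
Gaussians, σ = T/8 and T/4) and smears it along fibre streamlines with a
Gaussian-weighted line-integral convolution (path-length scale 2T, truncated
at 2.5 σ, 0.5-voxel steps, sign carried along the path). The result is
near-constant along each fibre and oscillates at the stripe scale across it
— precisely the property that makes the structure tensor's smallest-
variation direction the fibre axis — and it is valid for arbitrary fields,
including lesions and nonzero intrusion angles. Foreground is normalised to
[0.2, 1], background set to 0.05, optional Gaussian noise added last on the
[0, 1] intensity scale.

**What the phantoms do not emulate:** trabeculations and papillary muscles,
vessels, the right ventricle, intensity inhomogeneity across the specimen,
and anisotropic point-spread functions. Passing phantom tests therefore
demonstrates correctness of the estimators and aggregation under the stated
laws and texture, not robustness to every feature of real acquisitions.

## Validation problem sizes

The orientation-recovery and angle-law checks run on an annulus at the
acquisition voxel size (5.48 μm) filling a ~128³ grid (wall 240 μm ≈ 44
voxels); unit tests use a coarser 10 μm annulus where each property has a
closed form; the cohort positive control uses twelve 400 μm-long annuli with
per-specimen angular jitter (sd 0.06 rad) and, in one cohort, planted
lesions, evaluated on ground-truth fibre fields to isolate the MDI contrast
from estimator noise. The realistic half-prolate phantom used in the worked
example is rescaled into a 96³ grid.

## Known limitations

- Angle definitions ignore epicardial curvature at apex and base; frames
  from a single prolate spheroid degrade near the apical cap.
- The helix-gradient fit assumes an approximately linear transmural law;
  strongly non-monotone profiles lower R² but are summarised by the same
  two parameters.
- The sheet/sheetlet (E3) angle is out of scope, as is any histology-level
  feature below the voxel scale.
- MDI conflates orientation dispersion with estimator noise; at high image
  noise the index drops even in ordered tissue (the validity mask and the
  ≥ 50% neighbour rule mitigate, not remove, this).
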