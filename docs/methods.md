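# Methods

## Coordinate and direction conventions

Everything is computed in the DICOM patient coordinate system (LPS):
+x toward the patient's left, +y posterior, +z superior, millimetres.
Grids are strictly axis-aligned — a point is `origin + index * spacing` —
and files carrying a non-identity direction-cosine matrix are rejected
rather than silently reinterpreted. This is a deliberate limitation: the
QA workflows this package targets operate on axially acquired clinical
volumes, and a silent axis permutation is precisely the class of error
the toolkit exists to surface.

A DICOM spatial registration object stores a transform mapping
*target-frame* points into the *moving* frame — the opposite of the
direction a user registers in. Every `HomogeneousTransform` therefore
carries a direction tag, and `translation_errors` refuses to difference a
transform tagged with the wrong direction instead of producing silently
sign-flipped errors. Deformation vector fields follow the same contract:
they displace target-frame points toward the moving frame.

## Rigid transform construction

The nominal (ground-truth) transform for a phantom case is built from the
known rotations and the known shift, rotations applied first:
`M = [R | t]` with `t` the shift in LPS mm and `R = Rz(θz)·Ry(θy)·Rx(θx)`.
Two conventions here are fixed by the worked example the whole chain is
anchored to, and both are unusual enough to deserve a note:

* **Composition order** is z-first (as a product, `Rz·Ry·Rx`). The
  alternative x-first order does not reproduce the reference matrices;
  an `order` argument exposes the other permutations for sensitivity
  checks.
* **The y-axis matrix layout** places `−sin` at row 1, column 3 — the
  transpose of the textbook single-axis matrix (equivalently, `Ry(−θ)` in
  the textbook convention). `rotation_about_axis` implements exactly this
  layout. The cross-check test reconciles the composite against an
  independent intrinsic z-y-x Euler construction with the y angle
  negated.

Inversion uses the rigid closed form `(Rᵀ, −Rᵀt)` when the rotation block
is orthonormal to 1e-9, and a general 4×4 inverse otherwise (file-read
matrices are often rounded to 3–4 decimals; a warning is emitted above
1e-3 deviation from orthonormality).

## Rotation-axis misalignment

Since a 3-D angular error cannot be uniquely decomposed into per-axis
components, overall rotational misalignment is quantified by the axis of
the composite rotation: the real eigenvector of `R` with eigenvalue +1.
Numerical eigensolvers return an arbitrary sign, so the axis sign is
canonicalized (largest-magnitude component positive) and axes are
compared sign-blind, `arccos |u·v|`, giving an angle in [0°, 90°].
The rotation angle is recovered from the trace; below 1e-7° the rotation
is treated as the identity, whose axis is undefined — the result carries
an explicit `degenerate` flag and contributes 0° misalignment with a
warning, because an identity registration of an identity ground truth is
a perfect result, not a failure.

## Half-voxel tolerance

Per-axis translation errors pass when `|error_i| ≤ voxel_i / 2`,
boundary inclusive: the half-voxel figure is an aspiration, and an error
of exactly half a voxel should not fail a commissioning test on a tie.

## DVF sampling and TRE

Vector Grid Data stores one (Δx, Δy, Δz) float32 triplet per voxel
centre, x-index fastest. Between centres the field is interpolated
trilinearly — exact at centres and for componentwise-affine fields,
second-order accurate otherwise; nearest-neighbour is available for
sensitivity checks. Points outside the voxel-centre hull raise by
default; an explicit clamp policy snaps them to the hull boundary (never
extrapolating beyond stored values) with a warning. These defaults are
conservative on purpose: silent clamping hides export bugs.

TRE statistics use the sample (n−1) standard deviation by default, with
`sd_ddof` configurable since published "±1SD" figures do not always state
the denominator. The tolerance check is strict (`mean < 2 mm`,
`max < 5 mm`), matching the wording of the recommendation, and both
thresholds are configurable per run but always recorded in the report.

## Dice and volumes

Dice is computed two ways — from voxelwise mask intersection, and from a
(deformed, target, common) volume triple as read off any planning system —
and the mask path feeds its own three volumes through the volume formula,
so the two are identical by construction. Masks must share a grid
exactly; there is no implicit resampling, because any resampling policy
would silently change the DSC. Two empty structures raise an
undefined-metric error rather than returning 0. DSC values are reported
to 3 decimals; band labels are `fail` below 0.8, `acceptable` in
[0.8, 0.9], `good` above. Surface-distance metrics (mean distance to
agreement, Hausdorff) are out of scope by design; DSC plus structure
volume is used as the practical contour-agreement surface.

## Synthetic fixtures

The generators stand in for the public phantom/clinical datasets and are
pure functions of their seed (one `numpy` Generator per bundle; DICOM
instance UIDs are derived from the seed so files are byte-reproducible).

* **Rigid cases** default to the rotation-phantom scenario (shift
  5 mm Lt / 15 mm Ant / 20 mm Sup of the stationary set, rotations
  −5°/8°/10°). Translation errors are injected additively on the reported
  translation; rotation errors are injected by tilting the rotation axis
  by an exact angle while preserving the rotation angle, so the expected
  misalignment is the injected tilt to machine precision.
* **DVF cases** sample an analytic field (affine, Gaussian bump of
  amplitude 8 mm and σ 30 mm, or sinusoid) onto a grid with vendor-like
  spacing (2 mm in-plane, 5 mm slice). Landmark targets come from the
  analytic field, so the only discrepancy a TRE run can see is
  interpolation error, bounded in the manifest by the conservative
  worst-case `√3/8 · Σᵢ hᵢ² · max|d″|` (zero for affine fields).
* **Mask cases** rasterize sphere or box pairs by the voxel-centre-inside
  rule, with a half-voxel grid offset so no centre lies exactly on a
  surface. Equal unit spheres one radius apart have the closed-form lens
  overlap `π(4r+d)(2r−d)²/12`, hence Dice exactly 5/16; commensurate
  boxes rasterize exactly.

What the fixtures do **not** emulate: image intensities (registration
itself is out of scope), realistic anatomical deformation fields,
observer variability in contouring, or DVF export quirks of any specific
vendor beyond the standard object layout. Passing tests therefore
demonstrate that the *measurement chain* is correct, not that any
particular registration algorithm is accurate.

## File formats and precision

* Rigid matrices are written as shortest-round-trip decimal strings, so
  write/read is bit-exact; a few values exceed the 16-byte DS length
  limit, a deliberate trade of strict VR conformance (on our own fixture
  files) for exactness. The raw text-scan parser accepts both `/` and `\`
  separators, since the in-file multivalue delimiter is a backslash.
* Displacements are float32, the standard Vector Grid Data precision;
  deformable round-trips are exact at float32 (~1e-7 relative).
* Landmark dialects (mm vs voxel index, 0- vs 1-based) are never
  auto-detected — the caller must declare them, because a silent
  unit/base error is the central hazard in landmark QA.
* Masks go through NRRD (SimpleITK), exact for binary data.

## Problem sizes

Default test problem sizes — 100 landmarks per DVF case, grids of order
40×40×13, sphere masks at 0.02 mm voxels (~3M voxels) and round-trip
sweeps over 100 seeds — were chosen so the full suite characterizes every
pathway in well under a minute while keeping voxelization error an order
of magnitude below the tolerances being checked.

## Known limitations

* No direction-cosine support, no resampling, no DVF inversion or
  Jacobian analysis, no dose warping.
* No DICOM RT Structure Set polygon handling: masks are the contract.
* General Euler-angle decomposition of a measured rotation is
  deliberately absent (it is degenerate); only the axis/angle summary is
  provided.
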