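# Methods

This note records the conventions, defaults and numerical choices behind
`lesiontrack`, and what the synthetic tests do and do not demonstrate.

## Coordinate conventions

Voxel indices are `(i, j, k)` = (column, row, slice), 0-based, referring
to voxel *centres*.  The patient-frame map is

    p(i, j, k) = origin + i·Δc·r̂ + j·Δr·ĉ + k·Δs·ŝ

with `r̂` the direction of increasing column index (first DICOM
orientation triplet), `ĉ` the direction of increasing row index (second
triplet) and `ŝ = r̂ × ĉ`.  `origin` is the position of the first
voxel's centre (the DICOM position tag of the first slice).  Direction
cosines must be unit-norm and mutually orthogonal to 1e-6; tilted
(non-axial) series are accepted as long as the triad is orthonormal.
`patient_to_voxel` inverts the affine exactly (a 3×3 solve; rejected if
the direction matrix is singular).

Slice spacing is derived from consecutive slice positions, not from the
thickness tag: spacing governs geometry; the thickness tag is kept and
used only when a series has a single slice, where no gap exists.  When
gaps are non-uniform beyond 1 % of their mean, a warning is recorded
and the mean gap is used.

## Masks, compression, contours

Masks are strict 0/1 grids shaped `(n_slices, n_rows, n_cols)` and are
persisted as DEFLATE (zlib) streams of the raw slice-major, one-byte-
per-voxel serialization.  Simplicity and a bit-exact round trip were
preferred over packing density; compressed payloads are bound to their
geometry by a checksum over dimensions, spacing, origin and orientation,
and decompression validates stream integrity, voxel count and binarity.

Contours are *crack boundaries*: closed rectilinear polygons on pixel
corners, traced from the directed edges between foreground and
background.  Outer contours are wound counter-clockwise in (col, row)
axes, holes clockwise, so the signed shoelace area over a slice's
contours equals its foreground pixel count exactly — the identity the
test suite asserts, and the reason a 1-pixel lesion has a square contour
of side 1 and a diagonal "diameter" of √2·pixel.  Foreground is
4-connected and background 8-connected in-plane: diagonally touching
pixels trace as separate polygons, and at an ambiguous corner the tracer
takes the turn that keeps the enclosed region on the inside.  A single
4-connected region pinched at a corner legitimately passes through that
corner twice; self-intersection is therefore defined as re-walking a
crack edge, not revisiting a vertex.  Rasterization fills by winding
number at pixel centres (outers +1, holes −1), which is the exact
inverse of tracing.  3-D connected components are 26-connected
(`scipy.ndimage.label`), returned largest-first.

## Measurements

* **Unidimensional (mm)** — the maximal in-plane Feret diameter over
  all slices, never a 3-D chord.  Per slice, contour vertices are
  scaled to mm (handling anisotropic pixels) and the maximum pairwise
  distance is computed by convex hull (monotone chain, collinear points
  dropped) plus rotating calipers; the tests require exact agreement
  with the O(n²) all-pairs maximum.  Ties between slices resolve to the
  lowest slice index.
* **Perpendicular width (mm)** — the Feret width perpendicular to the
  diameter direction on the diameter slice: the extent of the projected
  vertices, not the longest perpendicular chord.  This is well defined,
  convex-hull computable, and standard in automated RECIST/WHO tools.
* **Bidimensional (mm²)** — long axis × perpendicular width.
* **Volume (mm³)** — foreground voxel count × `Δc·Δr·Δs`.

Pixel-corner vertices bias diameters upward by at most one pixel
diagonal, so products carry roughly twice that relative bias; measured
disc diameters are asserted within 2 pixel diagonals of the analytic
value, and ellipsoid volumes within 1.5 % at 0.5 mm voxels.

Lymph nodes measure by the long axis by default; an opt-in
`nodal_short_axis` switch reports the perpendicular width as the nodal
unidimensional measure instead (modern nodal practice).  In that mode
the bidimensional product remains long × perpendicular, so it is no
longer uni × perpendicular by construction.

## Target-lesion matching

Lesion positions are summarized by the centroid of foreground voxel
centres in the patient frame (the affine makes "map the mean index" and
"mean of mapped voxels" identical).  Both timepoints' centroid sets are
mean-centred — cancelling any global couch translation exactly — and a
one-to-one assignment minimizing total squared distance is computed
(`scipy.optimize.linear_sum_assignment`).  Pairs with residual above a
threshold are demoted to unmatched.  The threshold defaults to 50 mm:
larger than typical repositioning residue, smaller than typical
inter-lesion spacing.  Rotation between timepoints is not corrected
(CT patients are supine; the threshold absorbs small rotations), and no
deformable registration is attempted.  QA passes iff every *non-empty*
lesion on both sides is matched; a lesion whose follow-up mask is empty
has vanished (complete response of that lesion), which is a resolved
outcome rather than a matching failure — otherwise every complete
response would be unassessable.  Assessment refuses to run while QA
fails.

## Response classification

Each follow-up is classified independently (no confirmation-visit
logic): CR when the burden is zero; otherwise PD against the **nadir**
(the minimum over baseline and all *earlier* follow-ups); otherwise PR
against baseline; otherwise SD.  RECIST uses 1.1 semantics — PD needs
both ≥ +20 % from nadir and ≥ 5 mm absolute increase; setting the guard
to 0 gives 1.0 behaviour.  WHO: −50 %/+25 % on the SPD.  Volumetric
cutoffs default to the cubed RECIST diameter ratios, −65.7 %/+72.8 %,
the change a sphere shows when its diameter crosses the RECIST
boundaries; they are configuration, not a claim about optimal cutoffs.
Best overall response is the best category across follow-ups under
CR > PR > SD > PD.  Classification is scale-invariant except for the
deliberate 5 mm absolute guard.

## Relational store

A single-file SQLite database mirrors the five-table design: patient,
study, series (with its geometry serialized as JSON), user, lesion.
Identifiers are the DICOM UIDs; ingestion is idempotent, and a UID
already registered under a different parent is rejected as a collision.
Lesion rows are unique on (series, user, label): re-saving replaces the
row and bumps the modified timestamp (last write wins); distinct readers
never interact, which is what multi-reader studies need.  Measurements
are denormalized onto the lesion row.  `integrity_check` verifies
foreign keys, payload decompressibility and uniqueness.  A server
deployment would swap the connection string, not the schema.

## Phantom generator

The generator emulates the input side of the workflow: per timepoint a
DICOM CT series (explicit VR little endian, signed 16-bit HU) plus
noise-free truth masks and analytic truth tables.  Lesions are
axis-aligned ellipsoids rasterized on voxel centres with no
partial-volume anti-aliasing — deliberately, so the analytic in-plane
diameter (2·max(a,b)), width (2·min(a,b)) and volume (4/3·π·abc) are
exact references.  Defaults: background −70 HU, lesion contrast tens of
HU above background, additive Gaussian noise of 10 HU, 0.8 mm in-plane
and 2.5 mm slice spacing — typical contrast-enhanced chest/abdomen CT
values.  Per-timepoint isotropic scale factors set each lesion's course
(0 = vanished) and a global shift simulates repositioning.  Overlapping
lesions are rejected to keep per-lesion truth unambiguous.  All
randomness derives from a recorded seed; the same spec reproduces
byte-identical studies.

What the phantom does **not** emulate: organ anatomy and texture,
partial-volume edges, respiratory motion, contrast-phase differences,
scanner artifacts, or segmentation error (truth masks are perfect).
Passing the end-to-end tests therefore shows the *pipeline* is correct
— geometry, storage, measurement, matching and classification compose
without bias — not that any segmentation algorithm is accurate on real
scans.  Segmentation itself is out of scope; masks are inputs.

## Problem sizes and determinism in the verification suite

The property suite uses grids of 32–64 voxels per axis: large enough
that blobs have nontrivial topology and ellipsoids span dozens of
slices, small enough that the full suite runs in well under a minute.
The end-to-end check runs 20 longitudinal cases (48×48×16 at 1.0/3.0 mm,
two lesions, two follow-ups) through the actual CLI commands, cycling
through scale regimes (stable, shrink, regrow, vanish, shrink-then-
regrow) whose analytic percent changes sit comfortably inside their
category bands, so rasterization granularity cannot flip a category.
All random draws in tests and in `scripts/acceptance.py` come from
seeded generators; the acceptance script threads its `--seed` into
every generator it uses.

## Known limitations

* New-lesion detection and non-target lesion rules are not implemented;
  overall response here is target-lesion response.
* Matching assumes rigid translation; large rotations or deformations
  would need registration upstream.
* The contour tracer and rasterizer assume rectilinear crack polygons;
  arbitrary (smoothed) polygons are rejected rather than approximated.
* The NIfTI mask affine is written from the DICOM-frame map directly;
  masks are validated against the series grid by shape and geometry
  digest, not by resampling.
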