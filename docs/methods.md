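# Methods

This note documents the models, conventions and numerical choices behind
`fract3d`, and what the synthetic validation does and does not demonstrate.

## Displacement model

All quantities live in millimetres in a right-handed world frame; voxel data
are converted to world coordinates through the NIfTI affine at load time.

A fracture is described by per-fragment rigid transforms `T` mapping the
*reduced* (anatomically restored) pose to the displaced pose of a given
state (preoperative or postoperative). Measurement is **transform-based**:
fracture lines are polylines in the reduced pose, and the displacement at a
line point `p` is

* interior line (two fragments meet): `d(p) = T_own(p) − T_adj(p)` — the
  relative inter-fragment displacement;
* peripheral line (no opposing fragment): `d(p) = T_own(p) − p` — motion
  with respect to the reduced pose.

This exact correspondence is available because virtual reduction recovers
the transforms; a nearest-neighbour fallback would conflate displacement
with line-parameterization error. The decomposition against the articular
unit normal `n(p)` gives `step_off = |d·n|`, `gap = ‖d − (d·n)n‖`, closing
the Pythagorean identity to 1e-9. Step-off is reported unsigned (a signed
variant, positive along the outward articular normal, is stored alongside);
medians and maxima of a magnitude are the clinically reported quantities
and no sign convention exists in the field for the alternative.

The articular normal is taken from a **fitted articular model** of the
intact template — a least-squares sphere for the acetabular cup (fitted
robustly: iterative inlier re-selection keeping vertices whose surface
normal faces the current centre estimate, i.e. the concave side), or an
explicit plane for flat test facets. A fitted model is the smoothest
consistent estimate of the articular surface; it avoids mesh discretization
noise entirely, which is why it is preferred over smoothed vertex normals.
Displaced-fragment normals are never used: the metric must not depend on
the displacement it measures.

## Virtual reduction (registration)

The intact contralateral side is reflected across the midsagittal plane
(landmark-defined when available). Each fragment is registered to the
mirrored template by point-to-plane ICP:

* 5 000 uniform surface samples per fragment; the target is represented by
  60 000 seeded surface samples with their face normals in a k-d tree, so a
  correspondence contributes the residual `(Rp + t − q)·n_q` — exact for
  polyhedral targets and second-order accurate on smooth ones.
* **Phase 1** iterates on *all* correspondences with capped updates
  (≤ 0.2 rad, ≤ 5 mm per step) so that sparse distinctive geometry — the
  extra-articular bone a real fragment carries — can steer the pose from
  starts 20 mm away without Gauss–Newton overshoot.
* **Phase 2** trims correspondences beyond `max(3×median, 1 mm)`: fracture
  (cut) surfaces have no counterpart on the intact template and would bias
  the fit.
* **Phase 3** polishes with IRLS (Tukey biweight on the point-to-plane
  residual, scale = max(4.685·MAD, 0.05 mm)), suppressing the residual
  influence of occluded edges; this is what brings transform recovery from
  ~0.02 mm to ~0.002 mm on the phantom.

The reported RMS is the robust point-to-plane residual, insensitive to the
discretization of the target sample. Registrations with RMS > 2 mm are
flagged (`unreduced` / `unmatched`) rather than silently reported: that
threshold separates template-explainable geometry from foreign bone or
severe comminution. The best-so-far pose is tracked, so the reported RMS
sequence is non-increasing. All sampling is seeded from one configuration
value; the pipeline is deterministic end to end.

Postoperative fragment positions are recovered by registering the
preoperative fragments into the (single, fused) postoperative model,
initialized at the reduction transforms, since the surgical result is near
the reduced pose.

## Fracture lines

The articular region of a fragment is the set of faces whose vertices lie
within a band (default 2.5 mm) of the fitted articular model and whose
normals face its concave side. Fracture lines are the boundary edges of
that region, chained into polylines and resampled at ≤ 0.5 mm — *minus the
intact joint margin*: the template's own articular boundary (the acetabular
rim) exists before any fracture, so fragment boundary points that lie on it
(< 1.5 mm) **and run along it** (tangent within 45°) are margin, not
fracture. The tangency test keeps fracture-line endpoints, which meet the
rim roughly perpendicular; without it the first ~1.5 mm of every line would
be clipped, and an unfractured cup would still be handled correctly (its
entire boundary is margin, so no lines are produced).

Adjacency is assigned per point to the nearest other fragment within 2 mm
(distance to a dense surface sample, not just vertices — coarse meshes such
as boxes have arbitrarily sparse vertices); runs of constant adjacency
become separate lines, so a chain passing through the cup apex splits
correctly in three-fragment configurations. Interior lines exist once per
fragment (twice per pair); summaries and areas keep the copy owned by the
smaller fragment id to avoid double counting.

Summaries: maxima over all points of all lines; means weighted by each
line's point spacing (arc-length-uniform pooling across lines of different
lengths).

## Total gap area

The standardized view is the plane through the three required landmarks,
with its normal oriented from a midline hint toward the landmark centroid
(a reproducible lateral view). Projection is orthographic — the natural
reading of viewing the acetabulum "perpendicular to the plane". Each
interior line's two displaced copies are projected; the polygon bounded by
one copy and the reverse of the other is the line's gap ribbon, and the
**union** of all ribbons (shapely) is the total gap area, so junction
overlap is counted once. Invalid (self-intersecting) ribbons are repaired
with `make_valid`; if polygon cleaning ever fails the area is rasterized at
0.1 mm (area error bound 2·step·total-line-length, ≪ 1 mm² at clinical line
lengths). Displacement purely along the view direction projects to zero
width: the metric is deliberately a *gap* metric, blind to pure step-off.
Peripheral lines are excluded by default (`include_peripheral` flips this);
the projected region between fracture lines is well defined only where two
displaced copies exist.

## 2D slice emulation

The conventional reading is emulated by binning line points into parallel
slices (default thickness 2 mm, the maximum clinical CT slice thickness)
along the axial, coronal or sagittal axis and projecting the step and gap
*component vectors* into the slice plane before measuring:
`step_2D = step_3D·‖Pn‖`, `gap_2D = gap_3D·‖Pt‖` with `P` the in-plane
projector and `t` the tangential unit direction. Because a projection
cannot lengthen a vector, the 2D values are bounded by the 3D values at
every single point — the underestimation direction holds exactly, not
merely statistically.

## Grading

Matta's printed integer bins (0–1 / 2–3 / > 3 mm) leave real values in
(1, 2) undefined; bins are closed at their upper bounds (≤ 1 / ≤ 3 / > 3),
preserving every printed boundary while making the function total. The same
closure applies to the CT-based three-tier criteria (≤ 2 / ≤ 5 mm,
≤ 1 / ≤ 3 mm, ≤ 100 / ≤ 200 mm²). The final three-tier grade is the
category nearest the mean ordinal score (perfect = 1 … moderate = 3), with
exact ties rounded to the worse grade — conservative clinical reporting.
Residual percentage is `100·post/pre` (0 % ⇔ anatomical reduction, > 100 %
⇔ displacement increased); it is computed on the *average* step-off, gap
and the total gap area, and their mean is the overall reduction. A fracture
with zero preoperative displacement has an undefined percentage and is
flagged, not divided.

## Statistics

Wilcoxon signed-rank: zero differences discarded before mid-ranking
(Wilcoxon's original treatment; Pratt's behind a flag); for n ≤ 25 the
two-sided p is exact — the null distribution of the rank sum over all 2^n
sign assignments is built by convolution on a doubled-rank integer lattice
(mid-ranks can be half-integral), and both tails of the symmetric
distribution are summed. Above n = 25 a normal approximation with tie
correction (Σr²/4 variance) and continuity correction is used. Spearman's ρ
is the Pearson correlation of mid-ranks. ICC(A,1) follows the McGraw–Wong
two-way ANOVA form — single measurements, absolute agreement —
`(MS_R − MS_E) / (MS_R + (k−1)MS_E + (k/n)(MS_C − MS_E))`, reported with
the absolute mean difference between raters. All three are cross-checked in
the test suite against independent implementations and literal enumeration.

## Segmentation

Bone is thresholded at ≥ 226 HU by default — the de-facto preset for
cortical bone in clinical segmentation software; it is configuration, not a
constant. Fragments are 26-connected components (face-only connectivity
would split fragments across thin cortical bridges), largest first, with
islands under 50 voxels discarded. Surfaces are extracted per label by
marching cubes at the 0.5 iso-level after anti-aliasing the binary mask
with a Gaussian of 0.8 voxels: contouring the raw 0/1 field produces a
staircase surface whose area overestimates a smooth bone surface by ~10 %,
while the softened field recovers the partial-volume iso-surface (area
within 0.5 %, mean surface distance ~0.08 voxel on an r = 20 mm sphere).
This is mask-level partial-volume recovery, not mesh smoothing; the
measured geometry is never smoothed, and `antialias_sigma=0` restores the
raw surface.

## The phantom, and what the validation shows

The generator builds a hemispherical shell "cup" (articular radius 27 mm ≈
an adult acetabulum, shell thickness 4 mm) fractured by vertical planar
cuts through the apex into 2–3 wedge fragments, each displaced by a seeded
rigid transform whose translation has a controlled component along the
articular normal (2–8 mm) and tangential to it (2–20 mm). The intact
contralateral side is the exact mirror image; three landmarks sit on the
rim plane, so the standardized view axis is known by construction. Because
the articular surface is an exact sphere, ground truth is analytic at every
fracture-line point.

A perfect hemisphere is rotationally symmetric about its own axis, so a
wedge fragment's azimuthal position would be unobservable by surface
registration — a degeneracy real anatomy does not have, since fragments
carry large extra-articular bone (iliac wing, rami). Each phantom fragment
therefore carries a radial "wing" slab (26–30 mm, per-fragment dimensions,
mirrored on the intact side) that anchors registration the way
peri-acetabular bone does. A planar-facet phantom (two slabs sharing a
straight edge) exists because on a curved cup a purely tangential
translation induces a small nonzero step-off as the normal tilts along the
line; exact decomposition tests need the flat patch, where the analytic
ribbon area (length × in-plane perpendicular separation) is also available.

What the phantom does **not** emulate: real bone shape and its bilateral
asymmetry, comminution and fragment surface damage, cartilage thickness,
segmentation errors from metal artefact or low dose, and manual fracture
line annotation variability. Passing the validation therefore demonstrates
the *measurement chain* — mirroring, registration, line extraction,
decomposition, projection — is accurate when its assumptions hold, not that
those assumptions hold on any particular clinical scan.

Problem sizes: phantoms are meshed at 0.5 mm target edge length (~150 k
faces per side); the validation study runs 10 phantoms end to end (~2 s
each on one CPU), the 2D-vs-3D property suite runs 20 at 1 mm edge length,
and voxel-path tests use 1–1.5 mm spacing volumes.

## Known limitations

* Gap distances are chordal (3D), not geodesic along the curved articular
  surface; for clinical displacement scales the difference is second order.
* The cut surfaces of wedge fragments slightly perturb the untrimmed phase
  of registration; the trimmed and robust phases remove the bias, but
  pathological cases with mostly-fracture-surface fragments would rely
  entirely on the `rms_max` flag.
* Fragment splitting of *touching* fragments (interdigitated fractures) is
  out of scope for the segmentation path; fragments must be separable by
  connectivity, as in the mesh-input path used clinically.
* The final three-tier grade averages ordinal categories; this mirrors the
  proposed clinical rule, but ordinal means are a convention, not a
  statistic with distributional guarantees.
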